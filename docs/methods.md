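# Methods

## Sizing model

Particles are modelled as spheres undergoing free Brownian diffusion in a
Newtonian medium. The Stokes–Einstein relation in diameter form,
d = k_B·T/(3πη·D), links the diffusion coefficient D (µm²/s) to the
hydrodynamic diameter d (nm); k_B = 1.380649×10⁻²³ J/K (SI exact). The
default medium is water at 25 °C (T = 298.15 K, η = 0.89 mPa·s); both
values are configurable, and no temperature-dependent viscosity model is
applied.

Per-track diffusion coefficients use the lag-1 mean-squared-displacement
estimator, D̂ = MSD(1)/(4Δt), over the track's consecutive-frame 2D
displacements. For pure Brownian motion without localisation noise this
estimator is unbiased at every track length and avoids the correlated-lag
weighting problems of multi-lag MSD fits. Localisation noise is not
modelled, so no noise-offset correction is included; on real data with
appreciable localisation error the lag-1 estimator would be biased upward
in D (downward in d). Tracks shorter than `min_steps` (default 10 steps)
are excluded; 10 steps bounds the single-track relative error of D̂
(≈ √(2/N)) at a usable ~45%. Finite-track-length deconvolution of the
resulting estimate broadening is deliberately not implemented; all
distributions here are "raw" in that sense.

Drift correction (subtracting the per-frame ensemble-mean displacement) is
available but off by default: it targets residual advective flow shared by
co-temporal tracks and is a no-op for a single track.

## Distributions and box statistics

Diameters are binned into half-open bins [5k, 5(k+1)) nm — centres at
5k + 2.5 nm, so one bin is centred at 82.5 nm — and counts are divided by
the observed volume (ml) to give concentrations. The bin width (5 nm) and
the 7-point centred moving-average display smoothing are configurable;
smoothing truncates its window at the distribution edges and is *never*
applied before computing statistics. Modes and box statistics always come
from raw binned data: display smoothing of a skewed peak visibly drags the
argmax, which is exactly the artefact the raw-data rule avoids.

Box statistics: the mode is the centre of the maximum-concentration bin
(ties break deterministically to the smallest centre). Each box boundary is
the diameter that encloses, between itself and the mode bin's edge, half of
the concentration mass lying strictly outside the mode bin on that side.
The boundary is located by piecewise-linear interpolation on the outward
cumulative concentration; without interpolation, 5-nm granularity would
make boundaries jump a whole bin under infinitesimal changes in mass. A
side with no mass collapses its boundary onto the mode.

The hidden-fraction correction factor CF = (Fluo − Diff)/Diff is computed
per bin from paired scatter/fluorescence recordings of a fully fluorescent
calibration sample; bins with zero scatter concentration are flagged
invalid and pass through uncorrected (with a logged count) when the curve
is applied. Two distributions are considered compatible when they share bin
width and grid phase; differing support ranges are unioned with zero fill,
since trimmed distributions of the same sample rarely share exact support.
The correction is meant for scatter-mode recordings of 50-nm-extruded
preparations, where the hidden fraction is largest, and is an explicit
opt-in in the CLI rather than an automatic step.

## Replicate statistics

The unit of statistical analysis is one summary value (the mode) per
experimental replicate, never per-particle counts: a single run sizes
thousands of particles, and per-particle tests would declare trivially
small differences significant. One-way ANOVA uses the textbook
between/within mean squares with (k−1, N−k) degrees of freedom,
implemented directly so that zero-within-variance designs (common when
modes are 5-nm-quantised) resolve deterministically: identical group means
give F = 0, p = 1; differing means give F = ∞, p = 0. Pairwise post-hoc
tests are two-sided pooled-variance t-tests using the ANOVA within-group
mean square with N−k degrees of freedom, Bonferroni-adjusted
(p_adj = min(1, m·p)) over the number of requested comparisons.

A curvature-preference call requires both an effect size and significance:
|mean mode shift| ≥ `min_shift` (default 5 nm, one bin — the resolution of
the mode) *and* adjusted p < α (default 0.05). Otherwise the call is
"none". The assay itself provides no numeric rule separating preference
from no preference, so this decision rule is this package's construction;
both thresholds are configurable.

Vesiculation is summarised per dose by the concentration in the bin
centred at 82.5 nm (the marker of newly formed small vesicles), the
concentration-weighted mean size, and the total concentration. Efficiency
comparisons between two proteins use a two-sided t-test on replicate-level
marker metrics at a chosen dose. No EC50 or Hill-curve fitting is
performed on measured dose-response curves.

## Simulator

The simulator generates data with the statistical structure the assay
relies on, not photorealistic recordings:

* **Populations.** Extruded liposome preparations are lognormal mixtures
  (median diameter, geometric SD, weight per component) hard-truncated at
  the filter pore diameter by rejection resampling — extrusion imposes an
  upper size limit while passing smaller vesicles. Default: single
  component, median 200 nm, GSD 1.6, 800-nm cutoff, 4×10⁸ particles/ml
  (mid-range of the recommended (2–8)×10⁸/ml working concentration).
* **Binding.** Labelling probability is logistic in log-diameter between
  `baseline_prob` and `max_prob`, inflecting at `midpoint` (nm):
  decreasing for high-curvature binders, increasing for low-curvature
  binders, flat for insensitive ones. A logistic in diameter rather than in
  curvature 1/d keeps parameters interpretable on the distribution axis.
  Protein concentration is not modelled kinetically — the assay runs at a
  fixed ~2 nM — so `max_prob` is its proxy.
* **Detection.** Scatter-mode detectability is logistic in log-diameter
  (Rayleigh scattering ∝ d⁶ motivates a roughly constant log-width
  turn-on), default midpoint 90 nm and steepness 6, chosen so that a
  50-nm-extruded population exhibits a pronounced hidden fraction.
  Fluorescence detection keeps labelled particles with a size-independent
  probability (default 0.95). No instrument publishes its detection
  efficiency curve, so these are stand-ins, exposed in the config.
* **Tracks.** Per-axis steps are i.i.d. Gaussian with variance 2DΔt at the
  camera frame rate (default 25 fps, 120-s movies). Track lengths are
  geometric (particles diffuse out of the illuminated volume), mean 50
  frames by default, capped at the movie length.
* **Vesiculation.** Each particle is processed with Hill probability
  max_fraction·doseʰ/(doseʰ + half_doseʰ); a processed parent is replaced
  by daughters drawn from a lognormal (default median 80 nm, GSD 1.3)
  until its membrane area (∝ d²) is exhausted. The final daughter takes
  the exact residual area; a residual below `min_daughter` (default 20 nm,
  roughly the smallest stable liposome) folds into the previous daughter,
  so Σd² is conserved to machine precision for every seed. Parents the
  daughter distribution cannot subdivide pass through with a logged count.
* **Reproducibility.** Every operation takes a seed or Generator; composite
  pipelines split a single master seed into fixed per-stage substreams
  (`numpy.random.SeedSequence`), so repeated runs are byte-identical and
  individual stages are independently reproducible.

What the simulator does **not** emulate: localisation noise, photo-
bleaching, 3D-to-2D projection corrections, particle collisions or
aggregation, flow-profile heterogeneity, frame-level spot detection, and
membrane tubulation (only vesiculation is modelled). Passing tests
therefore validate the analysis chain under ideal single-particle
statistics; they do not certify performance on recordings whose dominant
errors are optical.

## Validation scenarios and problem sizes

Calibration-bead recovery simulates 3000 tracks of 200 steps per bead
(100 nm and 216 nm) — a few seconds of compute — and requires the
recovered 5-nm-binned mode within one bin of nominal. Note the recovered
continuous distribution of d̂ = d·2N/χ²₂ₙ is slightly right-skewed with
its peak at d·N/(N+1); at 200 steps this skew is comfortably inside one
bin.

Curvature-preference validation runs the full pipeline at a typical
experimental scale: 6000 particles per replicate, mean track length 100
frames, three replicates per condition, on a median-250-nm GSD-1.45
population extruded at 800 nm. The high-curvature scenario uses binding
midpoint 150 nm; the low-curvature (I-BAR-like) scenario uses 350 nm,
above the population mode — a binder whose midpoint sits far below the
mode labels essentially everything and is indistinguishable from an
insensitive one, which is a property of the assay, not of the
implementation.

## Known limitations

* No localisation-noise model, hence no noise-corrected estimator; real
  NTA data would need one or a multi-lag fit.
* The instrument's effective observed volume (the concentration
  calibration) is treated as a config input, not estimated.
* Binned-mode statistics are coarse (5-nm quantisation); replicate counts
  of 3 give marginal power for shifts near `min_shift`.
* The CF correction assumes the calibration and measurement samples share
  a detection-efficiency curve; it cannot correct bins the scatter channel
  never sees (zero-concentration bins).
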
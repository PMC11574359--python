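# liponta

Single-particle hydrodynamic sizing of liposomes, for researchers studying
how proteins sense and remodel membrane curvature.

Nanoparticle tracking analysis (NTA) films sub-micron particles diffusing
in solution, tracks them one at a time, and converts each trajectory into a
hydrodynamic diameter. Applied to liposomes incubated with a fluorescently
labelled protein, two recordings of the same sample — scatter mode (all
liposomes) and fluorescence mode (only protein-bound liposomes) — reveal
*which sizes* the protein binds: a shift of the bound-population mode
toward smaller diameters means a preference for high membrane curvature,
toward larger diameters a preference for low curvature. The same sizing
readout also quantifies membrane vesiculation: proteins that fragment
liposomes shrink the mean size and raise the particle count.

`liponta` implements the complete analysis chain, plus a physics simulator
that stands in for the tracking instrument so the whole method can be
exercised and tested in silico.

## The model

A sphere of hydrodynamic diameter *d* in a medium of viscosity η at
temperature *T* diffuses with coefficient

    D = k_B T / (3 π η d)        (Stokes–Einstein, diameter form)

A 2D-projected Brownian trajectory sampled at frame interval Δt has mean
squared displacement MSD(τ) = 4Dτ, so the lag-1 estimator

    D̂ = ⟨|r(t+Δt) − r(t)|²⟩ / (4 Δt)

is unbiased for pure Brownian motion, and d̂ = k_B T / (3 π η D̂).
Per-track diameters are binned in 5-nm bins ([5k, 5(k+1)) nm; one bin is
centred at 82.5 nm) and divided by the observed volume to give a
concentration-weighted size distribution.

Two assay-specific constructions sit on top:

* **Hidden-fraction correction.** Small liposomes diffract weakly and are
  under-counted in scatter mode. A per-bin correction factor
  CF = (Fluo − Diff)/Diff, estimated once from a fully fluorescent
  calibration sample, rescales scatter-mode distributions
  (corrected = Diff · (1 + CF)).
* **Replicate statistics.** Distributions are summarised by mode-centred
  box statistics (mode, plus boundaries enclosing 50% of the concentration
  mass on each side). One mode per experimental replicate is the unit of
  analysis; one-way ANOVA with Bonferroni-corrected pooled-variance
  pairwise t-tests decides significance.

## Worked example: calling a curvature preference

```python
from liponta import (
    PopulationSpec, BindingModel, DetectionModel, AcquisitionConfig,
    simulate_experiment, size_tracks, bin_sizes, box_stats, classify_preference,
)

population = PopulationSpec(components=((250.0, 1.45, 1.0),), extrusion_cutoff=800.0)
binding = BindingModel(kind="high_curvature", midpoint=150.0, steepness=5.0,
                       max_prob=0.9, baseline_prob=0.05)
acq = AcquisitionConfig(mean_track_length=100.0)

total, bound = [], []
for seed in (1, 2, 3):                      # three experimental replicates
    diff_tracks, fluo_tracks, _ = simulate_experiment(
        population, binding, DetectionModel(), acq=acq, n_particles=6000, seed=seed)
    volume = 6000 / population.concentration
    total.append(box_stats(bin_sizes(size_tracks(diff_tracks), volume)))
    bound.append(box_stats(bin_sizes(size_tracks(fluo_tracks), volume)))

call = classify_preference(total, bound)
print("total modes (nm):", [b.mode for b in total])
print("bound modes (nm):", [b.mode for b in bound])
print(f"mode shift: {call.mode_shift:+.1f} nm, adjusted p = {call.p_adjusted:.4f}")
print("classification:", call.label)
```

Output:

```
total modes (nm): [222.5, 237.5, 222.5]
bound modes (nm): [127.5, 147.5, 157.5]
mode shift: -83.3 nm, adjusted p = 0.0012
classification: smaller
```

The simulated protein binds preferentially below ~150 nm, so the
fluorescent (bound) subpopulation modes sit ~83 nm below the
whole-population modes; the shift is significant at the replicate level and
the protein is classified as preferring **smaller** liposomes (higher
curvature).

The same pipeline is available from the shell — `liponta simulate`,
`liponta size`, `liponta curvature`, `liponta vesiculation`,
`liponta stats` — driven by a flat INI configuration (`liponta --help`).

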
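"""Physics simulator for single-particle liposome sizing experiments.

Generates the statistical structure the assay assumes, end to end:

* extruded liposome populations — lognormal mixtures hard-truncated at the
  filter pore size (extrusion imposes an upper size limit while letting
  smaller vesicles through);
* curvature-dependent fluorescent labelling — a logistic in log-diameter,
  decreasing (high-curvature binders), increasing (low-curvature binders)
  or flat (curvature-insensitive binders);
* size-dependent detectability — small liposomes diffract weakly and are
  under-detected in scatter mode (the "hidden fraction"), while fluorescence
  detection is size-independent;
* 2D-projected Brownian tracks at the camera frame rate, with geometric
  track lengths (particles diffuse out of the illuminated volume);
* area-conserving vesiculation — membrane-remodelling proteins fragment a
  parent liposome into smaller daughters of equal total membrane area.

All randomness flows from an integer seed (or a ``numpy.random.Generator``);
composite operations split a master seed into deterministic per-stage
substreams via ``numpy.random.SeedSequence``.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .physics import (
    CHANNELS,
    DIFFRACTION,
    FLUORESCENCE,
    MediumConditions,
    Track,
    WATER_25C,
    diameter_to_diffusion,
)

log = logging.getLogger(__name__)

HIGH_CURVATURE = "high_curvature"
INSENSITIVE = "insensitive"
LOW_CURVATURE = "low_curvature"
BINDING_KINDS = (HIGH_CURVATURE, INSENSITIVE, LOW_CURVATURE)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PopulationSpec:
    """Lognormal mixture of liposome sizes with an optional extrusion cutoff.

    ``components`` is a sequence of (median diameter nm, geometric SD,
    weight) triples; weights must sum to 1. ``extrusion_cutoff`` is the
    filter pore diameter: sampled diameters above it are rejected and
    redrawn. ``concentration`` is the physical particle concentration the
    sample represents (particles/ml); instruments work best in the
    (2-8)x10^8 /ml range, hence the default.
    """

    components: tuple[tuple[float, float, float], ...] = ((200.0, 1.6, 1.0),)
    extrusion_cutoff: float | None = 800.0
    concentration: float = 4e8  # particles/ml

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("at least one mixture component required")
        weights = [w for _, _, w in self.components]
        if any(w < 0 for w in weights) or not math.isclose(sum(weights), 1.0, rel_tol=1e-9):
            raise ValueError("component weights must be >= 0 and sum to 1")
        for median, gsd, _ in self.components:
            if not (median > 0):
                raise ValueError("component median diameter must be > 0 nm")
            if not (gsd > 1):
                raise ValueError("geometric SD must be > 1")
        if self.extrusion_cutoff is not None and not (self.extrusion_cutoff > 0):
            raise ValueError("extrusion cutoff must be > 0 nm if given")
        if not (self.concentration > 0):
            raise ValueError("concentration must be > 0 /ml")


@dataclass(frozen=True)
class BindingModel:
    """Probability that a fluorescent protein labels a liposome of given size.

    A logistic in log-diameter running between ``max_prob`` and
    ``baseline_prob`` with inflection at ``midpoint``; ``kind`` picks the
    direction (decreasing for high-curvature binders, increasing for
    low-curvature binders, flat at ``max_prob`` for insensitive binders).
    Protein concentration is not modelled kinetically; ``max_prob`` is its
    proxy at the assay's fixed ~2 nM working concentration.
    """

    kind: str = HIGH_CURVATURE
    midpoint: float = 150.0  # nm
    steepness: float = 4.0
    max_prob: float = 0.9
    baseline_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in BINDING_KINDS:
            raise ValueError(f"kind must be one of {BINDING_KINDS}, got {self.kind!r}")
        if not (0 <= self.baseline_prob <= self.max_prob <= 1):
            raise ValueError("need 0 <= baseline_prob <= max_prob <= 1")
        if not (self.midpoint > 0):
            raise ValueError("midpoint must be > 0 nm")
        if not (self.steepness > 0):
            raise ValueError("steepness must be > 0")


@dataclass(frozen=True)
class DetectionModel:
    """Per-channel detection efficiency.

    Diffraction detectability is a logistic in log-diameter (Rayleigh
    scattering scales as d^6, so detectability turns on over a roughly
    constant log-width): particles well above ``diffraction_midpoint`` are
    almost always seen, small ones mostly missed — the hidden fraction.
    Fluorescence detection keeps labelled particles with a size-independent
    probability.
    """

    diffraction_midpoint: float = 90.0  # nm
    diffraction_steepness: float = 6.0
    fluorescence_prob: float = 0.95

    def __post_init__(self) -> None:
        if not (self.diffraction_midpoint > 0):
            raise ValueError("diffraction_midpoint must be > 0 nm")
        if not (self.diffraction_steepness > 0):
            raise ValueError("diffraction_steepness must be > 0")
        if not (0 <= self.fluorescence_prob <= 1):
            raise ValueError("fluorescence_prob must be in [0, 1]")


@dataclass(frozen=True)
class VesiculationModel:
    """Dose-dependent fragmentation of liposomes into smaller daughters.

    A parent is processed with Hill probability
    ``max_fraction * dose^h / (dose^h + half_dose^h)``; processed parents are
    replaced by daughters drawn lognormal(``daughter_median``,
    ``daughter_gsd``) until the parent's membrane area (proportional to d^2)
    is exhausted, conserving total area exactly. A residual daughter smaller
    than ``min_daughter`` folds its area into the previous daughter.
    """

    dose: float = 0.0  # uM
    max_fraction: float = 0.8
    half_dose: float = 1.0  # uM
    hill: float = 1.5
    daughter_median: float = 80.0  # nm
    daughter_gsd: float = 1.3
    min_daughter: float = 20.0  # nm

    def __post_init__(self) -> None:
        if not (0 <= self.max_fraction <= 1):
            raise ValueError("max_fraction must be in [0, 1]")
        if not (self.half_dose > 0):
            raise ValueError("half_dose must be > 0 uM")
        if not (self.daughter_median > 0):
            raise ValueError("daughter_median must be > 0 nm")
        if not (self.daughter_gsd >= 1):
            raise ValueError("daughter_gsd must be >= 1")
        if self.dose < 0:
            raise ValueError("dose must be >= 0 uM")

    @property
    def processed_probability(self) -> float:
        if self.dose == 0:
            return 0.0
        dh = self.dose**self.hill
        return self.max_fraction * dh / (dh + self.half_dose**self.hill)


@dataclass
class SimulatedSample:
    """A bag of particles (diameter, labelled flag) in a known volume."""

    diameters: np.ndarray  # nm
    labelled: np.ndarray  # bool
    volume: float  # ml
    seed: int | None = None

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.labelled = np.asarray(self.labelled, dtype=bool)
        if self.diameters.shape != self.labelled.shape:
            raise ValueError("diameters and labelled must have the same shape")
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be > 0 nm")
        if not (self.volume > 0):
            raise ValueError("volume must be > 0 ml")

    @property
    def membrane_area(self) -> float:
        """Total membrane area proxy, sum of d^2 (nm^2)."""
        return float(np.sum(self.diameters**2))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera and field-of-view parameters of a recording."""

    frame_rate: float = 25.0  # Hz
    duration: float = 120.0  # s
    mean_track_length: float = 50.0  # frames
    observed_volume: float = 1e-7  # ml

    def __post_init__(self) -> None:
        for name in ("frame_rate", "duration", "mean_track_length", "observed_volume"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")

    @property
    def max_frames(self) -> int:
        return max(2, int(self.duration * self.frame_rate))


def sample_population(spec: PopulationSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` diameters (nm) from the truncated lognormal mixture."""
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = _rng(seed)
    medians = np.array([c[0] for c in spec.components])
    sigmas = np.log([c[1] for c in spec.components])
    weights = np.array([c[2] for c in spec.components])
    idx = rng.choice(len(medians), size=n, p=weights)
    d = rng.lognormal(np.log(medians[idx]), sigmas[idx])
    if spec.extrusion_cutoff is not None:
        for _ in range(1000):
            bad = d > spec.extrusion_cutoff
            if not bad.any():
                break
            i = rng.choice(len(medians), size=int(bad.sum()), p=weights)
            d[bad] = rng.lognormal(np.log(medians[i]), sigmas[i])
        else:
            raise RuntimeError("extrusion cutoff rejects essentially all of the mixture")
    return d


def binding_probability(diameter, model: BindingModel):
    """Labelling probability for particles of ``diameter`` nm (vectorised)."""
    d = np.asarray(diameter, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be > 0 nm")
    if model.kind == INSENSITIVE:
        p = np.full_like(d, model.max_prob)
    else:
        sign = -1.0 if model.kind == HIGH_CURVATURE else 1.0
        logistic = expit(sign * model.steepness * np.log(d / model.midpoint))
        p = model.baseline_prob + (model.max_prob - model.baseline_prob) * logistic
    return p if p.ndim else float(p)


def label_by_binding(diameters, model: BindingModel, seed) -> np.ndarray:
    """Bernoulli labelling flags, one per diameter."""
    rng = _rng(seed)
    d = np.asarray(diameters, dtype=float)
    return rng.random(d.shape) < binding_probability(d, model)


def apply_detection(diameters, labelled, model: DetectionModel, channel: str, seed) -> np.ndarray:
    """Boolean mask of particles observed in ``channel``.

    Diffraction keeps a particle with logistic-in-log-diameter probability;
    fluorescence keeps labelled particles with ``fluorescence_prob`` and
    never sees unlabelled ones.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    rng = _rng(seed)
    d = np.asarray(diameters, dtype=float)
    lab = np.asarray(labelled, dtype=bool)
    if channel == DIFFRACTION:
        p = expit(model.diffraction_steepness * np.log(d / model.diffraction_midpoint))
        return rng.random(d.shape) < p
    return lab & (rng.random(d.shape) < model.fluorescence_prob)


def _draw_track_lengths(n: int, acq: AcquisitionConfig, rng: np.random.Generator) -> np.ndarray:
    """Geometric step counts with mean ``mean_track_length``, in [1, max_frames-1]."""
    steps = rng.geometric(1.0 / acq.mean_track_length, size=n)
    return np.clip(steps, 1, acq.max_frames - 1)


def simulate_track(
    diameter: float,
    medium: MediumConditions = WATER_25C,
    acq: AcquisitionConfig = AcquisitionConfig(),
    seed=None,
    n_steps: int | None = None,
    track_id: str = "sim",
    channel: str = DIFFRACTION,
) -> Track:
    """Simulate one 2D-projected Brownian track for a sphere of ``diameter`` nm.

    Per-axis steps are i.i.d. Gaussian with variance ``2 D dt``. If
    ``n_steps`` is not given, the step count is geometric with mean
    ``acq.mean_track_length``, capped at the movie length.
    """
    if not (diameter > 0):
        raise ValueError("diameter must be > 0 nm")
    rng = _rng(seed)
    dt = 1.0 / acq.frame_rate
    if n_steps is None:
        n_steps = int(_draw_track_lengths(1, acq, rng)[0])
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    sigma = math.sqrt(2.0 * diameter_to_diffusion(diameter, medium) * dt)
    steps = rng.normal(0.0, sigma, size=(n_steps, 2))
    positions = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    return Track(track_id=track_id, frame_interval=dt, positions=positions, channel=channel)


def simulate_tracks(
    diameters: Sequence[float],
    medium: MediumConditions = WATER_25C,
    acq: AcquisitionConfig = AcquisitionConfig(),
    seed=None,
    n_steps: int | None = None,
    channel: str = DIFFRACTION,
    id_prefix: str = "t",
) -> list[Track]:
    """Vectorised batch of :func:`simulate_track` (one shared random stream)."""
    rng = _rng(seed)
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        return []
    if np.any(d <= 0):
        raise ValueError("diameters must be > 0 nm")
    dt = 1.0 / acq.frame_rate
    if n_steps is None:
        lengths = _draw_track_lengths(d.size, acq, rng)
    else:
        lengths = np.full(d.size, int(n_steps))
    sigmas = np.sqrt(2.0 * np.array([diameter_to_diffusion(x, medium) for x in d]) * dt)
    raw = rng.normal(0.0, 1.0, size=(int(lengths.sum()), 2))
    tracks: list[Track] = []
    offset = 0
    width = len(str(d.size))
    for i, (length, sigma) in enumerate(zip(lengths, sigmas)):
        steps = raw[offset : offset + length] * sigma
        offset += length
        positions = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        tracks.append(
            Track(
                track_id=f"{id_prefix}{i:0{width}d}",
                frame_interval=dt,
                positions=positions,
                channel=channel,
            )
        )
    return tracks


def vesiculate(sample: SimulatedSample, model: VesiculationModel, seed) -> SimulatedSample:
    """Fragment a dose-dependent fraction of particles into smaller daughters.

    Total membrane area (sum of d^2) is conserved exactly for every seed and
    model. Daughters inherit the parent's labelled flag. Parents the daughter
    distribution cannot subdivide (daughter median at or above the parent
    size) pass through unchanged with a logged count.
    """
    rng = _rng(seed)
    p = model.processed_probability
    out_d: list[float] = []
    out_lab: list[bool] = []
    n_passed = 0
    for d, lab in zip(sample.diameters, sample.labelled):
        if p == 0.0 or rng.random() >= p:
            out_d.append(d)
            out_lab.append(bool(lab))
            continue
        if model.daughter_median >= d:
            n_passed += 1
            out_d.append(d)
            out_lab.append(bool(lab))
            continue
        daughters: list[float] = []
        remaining = d * d
        while True:
            cand = rng.lognormal(math.log(model.daughter_median), math.log(max(model.daughter_gsd, 1.0 + 1e-12)))
            if cand * cand >= remaining:
                residual = math.sqrt(remaining)
                if residual >= model.min_daughter or not daughters:
                    daughters.append(residual)
                else:
                    prev = daughters[-1]
                    daughters[-1] = math.sqrt(prev * prev + remaining)
                break
            daughters.append(cand)
            remaining -= cand * cand
        out_d.extend(daughters)
        out_lab.extend([bool(lab)] * len(daughters))
    if n_passed:
        log.info("vesiculate: %d parents at/below daughter median passed through", n_passed)
    return SimulatedSample(
        diameters=np.array(out_d),
        labelled=np.array(out_lab, dtype=bool),
        volume=sample.volume,
        seed=sample.seed,
    )


def simulate_experiment(
    spec: PopulationSpec,
    binding: BindingModel,
    detection: DetectionModel,
    medium: MediumConditions = WATER_25C,
    acq: AcquisitionConfig = AcquisitionConfig(),
    n_particles: int = 3000,
    seed: int = 0,
) -> tuple[list[Track], list[Track], pd.DataFrame]:
    """Full in-silico sizing experiment.

    Pipeline: sample the population, label by curvature-dependent binding,
    apply per-channel detection, simulate one Brownian track per observed
    particle. Returns (diffraction tracks, fluorescence tracks, ground truth)
    where ground truth is a DataFrame with columns ``diameter_nm``,
    ``labelled``, ``seen_diffraction``, ``seen_fluorescence``.

    The master ``seed`` is split into fixed per-stage substreams, so each
    stage is independently reproducible.
    """
    ss = np.random.SeedSequence(seed)
    s_pop, s_label, s_det_d, s_det_f, s_trk_d, s_trk_f = ss.spawn(6)
    diameters = sample_population(spec, n_particles, np.random.default_rng(s_pop))
    labelled = label_by_binding(diameters, binding, np.random.default_rng(s_label))
    seen_d = apply_detection(diameters, labelled, detection, DIFFRACTION, np.random.default_rng(s_det_d))
    seen_f = apply_detection(diameters, labelled, detection, FLUORESCENCE, np.random.default_rng(s_det_f))
    diff_tracks = simulate_tracks(
        diameters[seen_d], medium, acq, np.random.default_rng(s_trk_d), channel=DIFFRACTION, id_prefix="d"
    )
    fluo_tracks = simulate_tracks(
        diameters[seen_f], medium, acq, np.random.default_rng(s_trk_f), channel=FLUORESCENCE, id_prefix="f"
    )
    truth = pd.DataFrame(
        {
            "diameter_nm": diameters,
            "labelled": labelled,
            "seen_diffraction": seen_d,
            "seen_fluorescence": seen_f,
        }
    )
    return diff_tracks, fluo_tracks, truth


def sample_volume(spec: PopulationSpec, n_particles: int) -> float:
    """Volume (ml) that ``n_particles`` occupy at the spec's concentration."""
    return n_particles / spec.concentration
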
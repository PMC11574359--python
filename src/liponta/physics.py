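"""Hydrodynamic sizing of single particles from their Brownian motion.

A freely diffusing sphere of hydrodynamic diameter ``d`` has diffusion
coefficient ``D = k_B T / (3 pi eta d)`` (Stokes-Einstein, diameter form).
Tracking a particle through a sequence of frames yields 2D-projected
displacements whose mean square grows as ``4 D dt`` per frame, so the
lag-1 mean squared displacement gives an unbiased per-track estimate of
``D`` and hence of ``d``.

Units are the field's working units throughout: positions in micrometres,
diffusion coefficients in um^2/s, diameters in nanometres, temperature in
kelvin, viscosity in pascal-seconds.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: Boltzmann constant, J/K (SI exact).
BOLTZMANN = 1.380649e-23

DIFFRACTION = "diffraction"
FLUORESCENCE = "fluorescence"
CHANNELS = (DIFFRACTION, FLUORESCENCE)


@dataclass(frozen=True)
class MediumConditions:
    """Temperature and dynamic viscosity of the suspending medium.

    Defaults are water at 25 degC (298.15 K, 0.89 mPa s), the conditions
    under which calibration beads are routinely measured.
    """

    temperature: float = 298.15  # K
    viscosity: float = 8.9e-4  # Pa s

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if not (self.viscosity > 0):
            raise ValueError(f"viscosity must be > 0 Pa s, got {self.viscosity}")


WATER_25C = MediumConditions()


@dataclass
class Track:
    """One particle's consecutive-frame 2D positions in one channel.

    ``positions`` is an (n, 2) array in micrometres; frames are implicitly
    consecutive starting at ``start_frame``.
    """

    track_id: str
    frame_interval: float  # s
    positions: np.ndarray  # (n, 2), um
    channel: str = DIFFRACTION
    start_frame: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array of x/y in um")
        if len(self.positions) < 2:
            raise ValueError(f"track {self.track_id!r} needs >= 2 positions")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be > 0 s")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")

    @property
    def n_steps(self) -> int:
        return len(self.positions) - 1

    @property
    def frames(self) -> np.ndarray:
        return self.start_frame + np.arange(len(self.positions))


@dataclass(frozen=True)
class SizeEstimate:
    """Per-track diffusion coefficient and hydrodynamic diameter."""

    track_id: str
    diffusion_coeff: float  # um^2/s
    diameter: float  # nm
    n_steps: int
    channel: str


def _se_constant(medium: MediumConditions) -> float:
    # k_B T / (3 pi eta) in m^3/s; symmetric kernel of the d <-> D relation
    return BOLTZMANN * medium.temperature / (3.0 * math.pi * medium.viscosity)


def stokes_einstein_diameter(diffusion_coeff: float, medium: MediumConditions = WATER_25C) -> float:
    """Hydrodynamic diameter (nm) of a sphere diffusing at ``diffusion_coeff`` (um^2/s).

    ``d = k_B T / (3 pi eta D)``; strictly decreasing in D and the exact
    algebraic inverse of :func:`diameter_to_diffusion`.
    """
    if not (diffusion_coeff > 0):
        raise ValueError(f"diffusion coefficient must be > 0, got {diffusion_coeff}")
    d_m = _se_constant(medium) / (diffusion_coeff * 1e-12)
    return d_m * 1e9


def diameter_to_diffusion(diameter: float, medium: MediumConditions = WATER_25C) -> float:
    """Diffusion coefficient (um^2/s) of a sphere of hydrodynamic ``diameter`` (nm)."""
    if not (diameter > 0):
        raise ValueError(f"diameter must be > 0, got {diameter}")
    d_m2s = _se_constant(medium) / (diameter * 1e-9)
    return d_m2s * 1e12


def diffusion_from_track(track: Track) -> float:
    """Lag-1 MSD estimate of the diffusion coefficient, um^2/s.

    ``D = <|r(t+dt) - r(t)|^2> / (4 dt)`` over the track's consecutive-frame
    2D displacements. Unbiased for pure Brownian motion; no localisation-noise
    correction is applied.
    """
    steps = np.diff(track.positions, axis=0)
    msd = float(np.mean(np.sum(steps**2, axis=1)))
    return msd / (4.0 * track.frame_interval)


def drift_correct(tracks: Sequence[Track]) -> list[Track]:
    """Subtract the per-frame ensemble-mean displacement from every step.

    Removes a common advective component (e.g. residual syringe-pump flow)
    shared by co-temporal tracks. The ensemble-mean step of the output is
    zero at every frame with at least one observed step. A single track is
    returned unchanged (nothing to average against).
    """
    tracks = list(tracks)
    if len(tracks) < 2:
        if tracks:
            log.warning("drift_correct: only one track given; returning it unchanged")
        return tracks

    first = min(t.start_frame for t in tracks)
    last = max(t.start_frame + t.n_steps for t in tracks)
    sums = np.zeros((last - first, 2))
    counts = np.zeros(last - first, dtype=int)
    for t in tracks:
        steps = np.diff(t.positions, axis=0)
        lo = t.start_frame - first
        sums[lo : lo + len(steps)] += steps
        counts[lo : lo + len(steps)] += 1
    mean_step = np.where(counts[:, None] > 0, sums / np.maximum(counts, 1)[:, None], 0.0)

    out = []
    for t in tracks:
        steps = np.diff(t.positions, axis=0)
        lo = t.start_frame - first
        corrected = steps - mean_step[lo : lo + len(steps)]
        positions = np.vstack([t.positions[:1], t.positions[0] + np.cumsum(corrected, axis=0)])
        out.append(replace(t, positions=positions))
    return out


def size_tracks(
    tracks: Iterable[Track],
    medium: MediumConditions = WATER_25C,
    min_steps: int = 10,
) -> list[SizeEstimate]:
    """Convert tracks to per-particle size estimates.

    Tracks shorter than ``min_steps`` steps are skipped; tracks whose MSD is
    exactly zero (stuck particles) cannot be sized and are dropped with a
    logged count.
    """
    estimates: list[SizeEstimate] = []
    n_short = n_zero = 0
    for t in tracks:
        if t.n_steps < min_steps:
            n_short += 1
            continue
        d_coeff = diffusion_from_track(t)
        if d_coeff <= 0:
            n_zero += 1
            continue
        estimates.append(
            SizeEstimate(
                track_id=t.track_id,
                diffusion_coeff=d_coeff,
                diameter=stokes_einstein_diameter(d_coeff, medium),
                n_steps=t.n_steps,
                channel=t.channel,
            )
        )
    if n_short:
        log.debug("size_tracks: %d tracks below min_steps=%d", n_short, min_steps)
    if n_zero:
        log.info("size_tracks: dropped %d zero-displacement tracks", n_zero)
    return estimates
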
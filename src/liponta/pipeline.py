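"""End-to-end convenience pipelines built on the lower-level modules."""
from __future__ import annotations

import numpy as np

from .distributions import SizeDistribution, bin_sizes
from .physics import DIFFRACTION, MediumConditions, WATER_25C, size_tracks
from .simulate import AcquisitionConfig, simulate_tracks


def size_monodisperse(
    diameter: float,
    n_tracks: int = 3000,
    n_steps: int = 100,
    medium: MediumConditions = WATER_25C,
    frame_rate: float = 25.0,
    observed_volume: float = 1e-6,
    bin_width: float = 5.0,
    seed: int = 0,
) -> SizeDistribution:
    """Simulate and size a monodisperse sphere population (e.g. NIST beads).

    Generates ``n_tracks`` Brownian tracks of ``n_steps`` steps at the given
    frame rate, runs lag-1 MSD sizing and returns the binned distribution.
    Used to validate size recovery against calibration-bead standards.
    """
    acq = AcquisitionConfig(frame_rate=frame_rate, duration=max(120.0, (n_steps + 1) / frame_rate))
    tracks = simulate_tracks(
        np.full(n_tracks, float(diameter)),
        medium=medium,
        acq=acq,
        seed=seed,
        n_steps=n_steps,
        channel=DIFFRACTION,
        id_prefix="bead",
    )
    estimates = size_tracks(tracks, medium, min_steps=min(10, n_steps))
    return bin_sizes(estimates, observed_volume, bin_width=bin_width, label=f"{diameter:g} nm beads")


def local_maxima(dist: SizeDistribution, min_separation_bins: int = 2) -> np.ndarray:
    """Bin centres of strict local maxima of a distribution, highest first."""
    c = dist.concentration
    if len(c) < 3:
        return dist.bin_centres[np.argsort(c)[::-1]] if len(c) else np.array([])
    is_max = np.zeros(len(c), dtype=bool)
    is_max[1:-1] = (c[1:-1] > c[:-2]) & (c[1:-1] >= c[2:])
    is_max[0] = c[0] > c[1]
    is_max[-1] = c[-1] > c[-2]
    idx = np.flatnonzero(is_max)
    idx = idx[np.argsort(c[idx])[::-1]]
    kept: list[int] = []
    for i in idx:
        if all(abs(i - j) >= min_separation_bins for j in kept):
            kept.append(int(i))
    return dist.bin_centres[kept]
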
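"""5-nm-binned size distributions, hidden-fraction correction, box statistics.

Per-particle diameters are binned into half-open 5-nm bins ``[5k, 5(k+1))``
(centres at ``5k + 2.5`` nm, so one bin is centred at 82.5 nm) and divided
by the observed volume to give particle concentrations per ml.

Because small liposomes diffract weakly, scatter-mode recordings miss a
size-dependent "hidden fraction" that fluorescence recordings of the same
sample see. The per-bin correction factor ``CF = (Fluo - Diff) / Diff``,
estimated from a fully fluorescent calibration sample, rescales a
diffraction distribution to recover it: ``corrected = Diff * (1 + CF)``.

Distributions are summarised by mode-centred box statistics: the mode bin
centre, and boundaries enclosing 50% of the concentration mass on each side
of the mode.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .physics import SizeEstimate

log = logging.getLogger(__name__)

_PHASE_TOL = 1e-9


@dataclass
class SizeDistribution:
    """Binned particle concentration vs hydrodynamic diameter.

    ``bin_centres`` (nm) lie on the grid ``k*bin_width + bin_width/2`` with
    constant spacing ``bin_width``; ``concentration`` is particles/ml per bin.
    """

    bin_centres: np.ndarray
    concentration: np.ndarray
    bin_width: float = 5.0
    channel: str | None = None
    n_particles: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.bin_centres = np.asarray(self.bin_centres, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.bin_centres.shape != self.concentration.shape or self.bin_centres.ndim != 1:
            raise ValueError("bin_centres and concentration must be equal-length 1D arrays")
        if not (self.bin_width > 0):
            raise ValueError("bin_width must be > 0 nm")
        if len(self.bin_centres) > 0:
            spacing = np.diff(self.bin_centres)
            if len(spacing) and not np.allclose(spacing, self.bin_width, atol=1e-9):
                raise ValueError("bin_centres must increase with constant spacing = bin_width")
            phase = (self.bin_centres - self.bin_width / 2.0) / self.bin_width
            if not np.allclose(phase, np.round(phase), atol=_PHASE_TOL):
                raise ValueError(
                    f"bin_centres must lie on the k*{self.bin_width} + {self.bin_width / 2} grid"
                )
            if np.any(self.concentration < 0):
                raise ValueError("concentrations must be >= 0")

    def __len__(self) -> int:
        return len(self.bin_centres)

    @property
    def is_empty(self) -> bool:
        return len(self.bin_centres) == 0

    @property
    def lower_edges(self) -> np.ndarray:
        return self.bin_centres - self.bin_width / 2.0

    def _key(self) -> np.ndarray:
        """Integer bin indices k such that centre = (k + 0.5) * bin_width."""
        return np.round(self.bin_centres / self.bin_width - 0.5).astype(int)


@dataclass(frozen=True)
class CorrectionFactorCurve:
    """Per-bin hidden-fraction correction, CF = (Fluo - Diff) / Diff."""

    bin_centres: np.ndarray
    cf: np.ndarray
    valid: np.ndarray
    bin_width: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_centres", np.asarray(self.bin_centres, dtype=float))
        object.__setattr__(self, "cf", np.asarray(self.cf, dtype=float))
        object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))
        if not (self.bin_centres.shape == self.cf.shape == self.valid.shape):
            raise ValueError("bin_centres, cf and valid must have equal shapes")
        if np.any(self.cf[self.valid] < -1):
            raise ValueError("CF must be >= -1 where valid")


@dataclass(frozen=True)
class BoxStats:
    """Mode and mode-centred 50%/50% boundaries of a size distribution."""

    mode: float  # nm
    lower: float  # nm
    upper: float  # nm

    def __post_init__(self) -> None:
        if not (self.lower <= self.mode <= self.upper):
            raise ValueError("need lower <= mode <= upper")


def bin_diameters(
    diameters: Sequence[float],
    observed_volume: float,
    bin_width: float = 5.0,
    channel: str | None = None,
    label: str = "",
) -> SizeDistribution:
    """Bin raw diameters (nm) into a concentration distribution.

    Bins are half-open ``[k*w, (k+1)*w)``; leading/trailing empty bins are
    trimmed. Counts divided by ``observed_volume`` (ml) give particles/ml.
    """
    if not (observed_volume > 0):
        raise ValueError("observed_volume must be > 0 ml")
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        return SizeDistribution(
            np.array([]), np.array([]), bin_width=bin_width, channel=channel, n_particles=0, label=label
        )
    k = np.floor(d / bin_width).astype(int)
    kmin, kmax = int(k.min()), int(k.max())
    counts = np.bincount(k - kmin, minlength=kmax - kmin + 1)
    centres = (np.arange(kmin, kmax + 1) + 0.5) * bin_width
    return SizeDistribution(
        bin_centres=centres,
        concentration=counts / observed_volume,
        bin_width=bin_width,
        channel=channel,
        n_particles=int(d.size),
        label=label,
    )


def bin_sizes(
    estimates: Iterable[SizeEstimate],
    observed_volume: float,
    bin_width: float = 5.0,
    label: str = "",
) -> SizeDistribution:
    """Bin per-track size estimates into a concentration distribution."""
    estimates = list(estimates)
    channels = {e.channel for e in estimates}
    channel = channels.pop() if len(channels) == 1 else None
    return bin_diameters(
        [e.diameter for e in estimates], observed_volume, bin_width=bin_width, channel=channel, label=label
    )


def smooth_distribution(dist: SizeDistribution, window: int = 7) -> SizeDistribution:
    """Centred moving average for display; the window truncates at the edges.

    Raw distributions carry the statistics (modes, box stats are computed on
    raw bins); smoothing only tames bin-to-bin shot noise in plots.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if dist.is_empty or window == 1:
        return replace(dist)
    smoothed = (
        pd.Series(dist.concentration).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return replace(dist, concentration=smoothed)


def _align_grids(a: SizeDistribution | CorrectionFactorCurve, b: SizeDistribution | CorrectionFactorCurve):
    """Union bin grid of two objects sharing bin_width and phase."""
    if not np.isclose(a.bin_width, b.bin_width):
        raise ValueError(f"mismatched binning: widths {a.bin_width} vs {b.bin_width}")
    wa = a.bin_width

    def key(obj):
        k = obj.bin_centres / wa - 0.5
        kr = np.round(k).astype(int)
        if not np.allclose(k, kr, atol=1e-6):
            raise ValueError("mismatched binning: grids have different phase")
        return kr

    ka, kb = key(a), key(b)
    if len(ka) == 0 and len(kb) == 0:
        return np.array([], dtype=int)
    lo = min([*ka[:1], *kb[:1]])
    hi = max([*ka[-1:], *kb[-1:]])
    return np.arange(lo, hi + 1)


def _on_grid(values: np.ndarray, keys: np.ndarray, grid: np.ndarray, fill=0.0) -> np.ndarray:
    out = np.full(grid.shape, fill, dtype=float)
    out[keys - grid[0]] = values
    return out


def compute_cf(fluo: SizeDistribution, diff: SizeDistribution) -> CorrectionFactorCurve:
    """Per-bin correction factor CF = (Fluo - Diff) / Diff.

    Estimated from paired recordings of a fully fluorescent calibration
    sample. Bins where the diffraction concentration is zero carry no
    information and are flagged invalid.
    """
    grid = _align_grids(fluo, diff)
    w = fluo.bin_width
    f = _on_grid(fluo.concentration, fluo._key(), grid)
    d = _on_grid(diff.concentration, diff._key(), grid)
    valid = d > 0
    cf = np.full(grid.shape, np.nan)
    cf[valid] = (f[valid] - d[valid]) / d[valid]
    return CorrectionFactorCurve(bin_centres=(grid + 0.5) * w, cf=cf, valid=valid, bin_width=w)


def apply_cf(diff: SizeDistribution, cf: CorrectionFactorCurve) -> SizeDistribution:
    """Rescale a diffraction distribution by the hidden-fraction correction.

    ``corrected = Diff * (1 + CF)`` on valid bins; bins with no valid CF pass
    through unchanged (logged). Intended for scatter-mode recordings of
    50-nm-extruded samples, where the hidden fraction is largest.
    """
    grid = _align_grids(diff, cf)
    w = diff.bin_width
    d = _on_grid(diff.concentration, diff._key(), grid)
    cf_full = _on_grid(np.nan_to_num(cf.cf, nan=0.0), np.round(cf.bin_centres / w - 0.5).astype(int), grid)
    valid = _on_grid(cf.valid.astype(float), np.round(cf.bin_centres / w - 0.5).astype(int), grid) > 0
    corrected = np.where(valid, d * (1.0 + cf_full), d)
    n_passthrough = int(np.sum(~valid & (d > 0)))
    if n_passthrough:
        log.info("apply_cf: %d occupied bins had no valid CF and pass through uncorrected", n_passthrough)
    keep = diff._key() - grid[0]
    return replace(diff, concentration=corrected[keep], label=(diff.label + " (CF-corrected)").strip())


def box_stats(dist: SizeDistribution) -> BoxStats:
    """Mode-centred box statistics of a distribution.

    The mode is the centre of the maximum-concentration bin (ties break to
    the smallest centre). Each boundary is the diameter enclosing, between
    itself and the mode bin's edge, half of the concentration mass lying
    strictly outside the mode bin on that side, located by linear
    interpolation on the outward cumulative curve. A side with zero mass
    collapses its boundary onto the mode.
    """
    if dist.is_empty:
        raise ValueError("box_stats of an empty distribution")
    conc = dist.concentration
    if not np.any(conc > 0):
        raise ValueError("box_stats of an all-zero distribution")
    i_mode = int(np.argmax(conc))  # argmax returns the first (smallest-centre) maximum
    mode = float(dist.bin_centres[i_mode])
    w = dist.bin_width

    def outward_boundary(indices: np.ndarray, start_edge: float, direction: float) -> float:
        mass = conc[indices]
        total = float(mass.sum())
        if total <= 0:
            return mode
        target = total / 2.0
        cum = 0.0
        pos = start_edge
        for c in mass:
            if cum + c >= target:
                frac = (target - cum) / c if c > 0 else 0.0
                return pos + direction * frac * w
            cum += c
            pos += direction * w
        return pos  # not reached: target <= total by construction

    lower = outward_boundary(np.arange(i_mode - 1, -1, -1), mode - w / 2.0, -1.0)
    upper = outward_boundary(np.arange(i_mode + 1, len(conc)), mode + w / 2.0, +1.0)
    return BoxStats(mode=mode, lower=lower, upper=upper)


def mean_size(dist: SizeDistribution) -> float:
    """Concentration-weighted mean of the bin centres, nm."""
    if dist.is_empty or not np.any(dist.concentration > 0):
        raise ValueError("mean_size of an empty distribution")
    return float(np.average(dist.bin_centres, weights=dist.concentration))


def total_concentration(dist: SizeDistribution) -> float:
    """Total particle concentration, particles/ml."""
    return float(np.sum(dist.concentration))


def bin_concentration_at(dist: SizeDistribution, centre: float) -> float:
    """Concentration in the bin centred at ``centre`` nm (0 if outside range).

    ``centre`` must lie on the distribution's bin grid.
    """
    k = centre / dist.bin_width - 0.5
    if abs(k - round(k)) > 1e-6:
        raise ValueError(f"centre {centre} nm is not on the {dist.bin_width}-nm bin grid")
    if dist.is_empty:
        return 0.0
    match = np.isclose(dist.bin_centres, centre)
    if not match.any():
        return 0.0
    return float(dist.concentration[match][0])
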
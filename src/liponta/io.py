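"""CSV input/output mirroring instrument-software exports.

Two plain-text schemas:

* **Track CSV** — one row per localisation with columns ``track_id, frame,
  x_um, y_um, channel``; frames must be consecutive integers within a track.
* **Distribution CSV** — two columns ``bin_centre_nm,
  concentration_per_ml`` preceded by optional ``# key=value`` metadata
  lines (channel, label, particle count, seed, config hash).

Both round-trip losslessly; malformed input is rejected with the offending
track and line number named.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .distributions import SizeDistribution
from .physics import CHANNELS, Track

log = logging.getLogger(__name__)

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um", "channel"]


def write_tracks(tracks: Iterable[Track], path: str | Path, metadata: Mapping[str, str] | None = None) -> None:
    """Write tracks in the one-row-per-localisation CSV schema."""
    rows = []
    for t in tracks:
        frames = t.frames
        for f, (x, y) in zip(frames, t.positions):
            rows.append((t.track_id, int(f), x, y, t.channel))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_tracks(path: str | Path, frame_interval: float = 0.04) -> list[Track]:
    """Read tracks from CSV; ``frame_interval`` (s) is metadata the file lacks.

    A ``# frame_interval_s=...`` metadata line in the file overrides the
    argument. Frames must be consecutive within each track.
    """
    path = Path(path)
    meta = read_metadata(path)
    if "frame_interval_s" in meta:
        frame_interval = float(meta["frame_interval_s"])
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    if df.empty:
        return []
    # data line numbers for error messages: header + metadata lines precede
    n_meta = len(meta)
    df["_line"] = np.arange(len(df)) + n_meta + 2
    tracks: list[Track] = []
    for tid, grp in df.groupby("track_id", sort=False):
        frames = grp["frame"].to_numpy()
        gaps = np.flatnonzero(np.diff(frames) != 1)
        if gaps.size:
            line = int(grp["_line"].iloc[gaps[0] + 1])
            raise ValueError(
                f"{path.name}: track {tid!r} has a frame gap at line {line} "
                f"(frame {frames[gaps[0]]} -> {frames[gaps[0] + 1]})"
            )
        channels = grp["channel"].unique()
        if len(channels) != 1 or channels[0] not in CHANNELS:
            raise ValueError(f"{path.name}: track {tid!r} has invalid channel(s) {list(channels)}")
        tracks.append(
            Track(
                track_id=str(tid),
                frame_interval=frame_interval,
                positions=grp[["x_um", "y_um"]].to_numpy(),
                channel=str(channels[0]),
                start_frame=int(frames[0]),
            )
        )
    return tracks


def read_metadata(path: str | Path) -> dict[str, str]:
    """Parse leading ``# key=value`` lines of a CSV file."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def write_distribution(dist: SizeDistribution, path: str | Path, metadata: Mapping[str, str] | None = None) -> None:
    """Write a size distribution in the instrument-export-like CSV format."""
    meta = {
        "bin_width_nm": f"{dist.bin_width:g}",
        "n_particles": str(dist.n_particles),
    }
    if dist.channel:
        meta["channel"] = dist.channel
    if dist.label:
        meta["label"] = dist.label
    meta.update(metadata or {})
    df = pd.DataFrame({"bin_centre_nm": dist.bin_centres, "concentration_per_ml": dist.concentration})
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_distribution(path: str | Path) -> SizeDistribution:
    """Read a two-column distribution CSV, validating the bin grid."""
    path = Path(path)
    meta = read_metadata(path)
    df = pd.read_csv(path, comment="#")
    for col in ("bin_centre_nm", "concentration_per_ml"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    bin_width = float(meta.get("bin_width_nm", 5.0))
    try:
        return SizeDistribution(
            bin_centres=df["bin_centre_nm"].to_numpy(),
            concentration=df["concentration_per_ml"].to_numpy(),
            bin_width=bin_width,
            channel=meta.get("channel"),
            n_particles=int(meta.get("n_particles", 0)),
            label=meta.get("label", ""),
        )
    except ValueError as exc:
        raise ValueError(f"{path.name}: {exc}") from exc
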
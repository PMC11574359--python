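"""Flat INI run configuration.

One file carries everything a run needs: medium conditions, acquisition
parameters, analysis settings and the simulator parameter blocks. Defaults
follow routine practice for this assay: 120 s movies at 25 fps, 5-nm bins,
7-point display smoothing, alpha 0.05, and water at 25 degC.
"""
from __future__ import annotations

import configparser
import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path

from .physics import MediumConditions
from .simulate import (
    AcquisitionConfig,
    BindingModel,
    DetectionModel,
    PopulationSpec,
    VesiculationModel,
)


@dataclass(frozen=True)
class AnalysisConfig:
    bin_width: float = 5.0  # nm
    smooth_window: int = 7
    min_steps: int = 10
    alpha: float = 0.05
    min_shift: float = 5.0  # nm


@dataclass(frozen=True)
class RunConfig:
    medium: MediumConditions = MediumConditions()
    acquisition: AcquisitionConfig = AcquisitionConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    population: PopulationSpec = PopulationSpec()
    binding: BindingModel = BindingModel()
    detection: DetectionModel = DetectionModel()
    vesiculation: VesiculationModel = VesiculationModel()
    seed: int = 0
    n_particles: int = 3000


def _parse_components(text: str) -> tuple[tuple[float, float, float], ...]:
    # "median:gsd:weight; median:gsd:weight; ..."
    out = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(":")
        if len(parts) != 3:
            raise ValueError(f"bad population component {chunk!r}; expected median:gsd:weight")
        out.append(tuple(float(p) for p in parts))
    if not out:
        raise ValueError("population components must not be empty")
    return tuple(out)


def _format_components(components) -> str:
    return "; ".join(f"{m:g}:{g:g}:{w:g}" for m, g, w in components)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from an INI file; absent keys keep their defaults."""
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)

    def get(section, key, conv, default):
        if parser.has_option(section, key):
            return conv(parser.get(section, key))
        return default

    dflt = RunConfig()
    medium = MediumConditions(
        temperature=get("medium", "temperature_k", float, dflt.medium.temperature),
        viscosity=get("medium", "viscosity_pa_s", float, dflt.medium.viscosity),
    )
    acq = AcquisitionConfig(
        frame_rate=get("acquisition", "frame_rate_hz", float, dflt.acquisition.frame_rate),
        duration=get("acquisition", "duration_s", float, dflt.acquisition.duration),
        mean_track_length=get("acquisition", "mean_track_length", float, dflt.acquisition.mean_track_length),
        observed_volume=get("acquisition", "observed_volume_ml", float, dflt.acquisition.observed_volume),
    )
    ana = AnalysisConfig(
        bin_width=get("analysis", "bin_width_nm", float, dflt.analysis.bin_width),
        smooth_window=get("analysis", "smooth_window", int, dflt.analysis.smooth_window),
        min_steps=get("analysis", "min_steps", int, dflt.analysis.min_steps),
        alpha=get("analysis", "alpha", float, dflt.analysis.alpha),
        min_shift=get("analysis", "min_shift_nm", float, dflt.analysis.min_shift),
    )
    cutoff = get("population", "extrusion_cutoff_nm", str, None)
    pop = PopulationSpec(
        components=get("population", "components", _parse_components, dflt.population.components),
        extrusion_cutoff=(
            dflt.population.extrusion_cutoff
            if cutoff is None
            else (None if cutoff.strip().lower() in {"none", ""} else float(cutoff))
        ),
        concentration=get("population", "concentration_per_ml", float, dflt.population.concentration),
    )
    binding = BindingModel(
        kind=get("binding", "kind", str, dflt.binding.kind),
        midpoint=get("binding", "midpoint_nm", float, dflt.binding.midpoint),
        steepness=get("binding", "steepness", float, dflt.binding.steepness),
        max_prob=get("binding", "max_prob", float, dflt.binding.max_prob),
        baseline_prob=get("binding", "baseline_prob", float, dflt.binding.baseline_prob),
    )
    detection = DetectionModel(
        diffraction_midpoint=get("detection", "diffraction_midpoint_nm", float, dflt.detection.diffraction_midpoint),
        diffraction_steepness=get("detection", "diffraction_steepness", float, dflt.detection.diffraction_steepness),
        fluorescence_prob=get("detection", "fluorescence_prob", float, dflt.detection.fluorescence_prob),
    )
    ves = VesiculationModel(
        dose=get("vesiculation", "dose_um", float, dflt.vesiculation.dose),
        max_fraction=get("vesiculation", "max_fraction", float, dflt.vesiculation.max_fraction),
        half_dose=get("vesiculation", "half_dose_um", float, dflt.vesiculation.half_dose),
        hill=get("vesiculation", "hill", float, dflt.vesiculation.hill),
        daughter_median=get("vesiculation", "daughter_median_nm", float, dflt.vesiculation.daughter_median),
        daughter_gsd=get("vesiculation", "daughter_gsd", float, dflt.vesiculation.daughter_gsd),
        min_daughter=get("vesiculation", "min_daughter_nm", float, dflt.vesiculation.min_daughter),
    )
    return RunConfig(
        medium=medium,
        acquisition=acq,
        analysis=ana,
        population=pop,
        binding=binding,
        detection=detection,
        vesiculation=ves,
        seed=get("run", "seed", int, dflt.seed),
        n_particles=get("run", "n_particles", int, dflt.n_particles),
    )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a RunConfig as a diff-able INI file."""
    parser = configparser.ConfigParser()
    parser["medium"] = {
        "temperature_k": repr(cfg.medium.temperature),
        "viscosity_pa_s": repr(cfg.medium.viscosity),
    }
    parser["acquisition"] = {
        "frame_rate_hz": repr(cfg.acquisition.frame_rate),
        "duration_s": repr(cfg.acquisition.duration),
        "mean_track_length": repr(cfg.acquisition.mean_track_length),
        "observed_volume_ml": repr(cfg.acquisition.observed_volume),
    }
    parser["analysis"] = {
        "bin_width_nm": repr(cfg.analysis.bin_width),
        "smooth_window": str(cfg.analysis.smooth_window),
        "min_steps": str(cfg.analysis.min_steps),
        "alpha": repr(cfg.analysis.alpha),
        "min_shift_nm": repr(cfg.analysis.min_shift),
    }
    parser["population"] = {
        "components": _format_components(cfg.population.components),
        "extrusion_cutoff_nm": "none" if cfg.population.extrusion_cutoff is None else repr(cfg.population.extrusion_cutoff),
        "concentration_per_ml": repr(cfg.population.concentration),
    }
    parser["binding"] = {
        "kind": cfg.binding.kind,
        "midpoint_nm": repr(cfg.binding.midpoint),
        "steepness": repr(cfg.binding.steepness),
        "max_prob": repr(cfg.binding.max_prob),
        "baseline_prob": repr(cfg.binding.baseline_prob),
    }
    parser["detection"] = {
        "diffraction_midpoint_nm": repr(cfg.detection.diffraction_midpoint),
        "diffraction_steepness": repr(cfg.detection.diffraction_steepness),
        "fluorescence_prob": repr(cfg.detection.fluorescence_prob),
    }
    parser["vesiculation"] = {
        "dose_um": repr(cfg.vesiculation.dose),
        "max_fraction": repr(cfg.vesiculation.max_fraction),
        "half_dose_um": repr(cfg.vesiculation.half_dose),
        "hill": repr(cfg.vesiculation.hill),
        "daughter_median_nm": repr(cfg.vesiculation.daughter_median),
        "daughter_gsd": repr(cfg.vesiculation.daughter_gsd),
        "min_daughter_nm": repr(cfg.vesiculation.min_daughter),
    }
    parser["run"] = {"seed": str(cfg.seed), "n_particles": str(cfg.n_particles)}
    with open(path, "w") as fh:
        parser.write(fh)


def config_hash(path: str | Path) -> str:
    """Short content hash identifying the exact configuration used."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]
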
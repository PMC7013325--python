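"""Pipeline orchestration: phantom -> fluence -> dose -> outcome.

A :class:`RunConfig` fully specifies a run (phantom, diffuser plan,
photophysics, photon budget, seed, threshold); it is serializable to YAML
and archived next to the outputs, so an output directory regenerates
itself bit-exactly from its own ``config.yaml`` and seed.

Randomness is controlled by one global seed expanded into counter-derived
substreams (one per diffuser); see ``transport.substream_seed``.

Parameter scans over the photophysical quantities (c0, beta, threshold)
reuse a single cached fluence map: the dose model separates transport from
photophysics, so the Monte Carlo stage only depends on the geometry and
the optical properties.  Scans over transport parameters
(linear_power_density, interfiber_distance) rerun transport per value.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .dose import PhotophysicalParams, dose_map
from .outcome import cell_death_mask, volume_metrics
from .phantom import (
    TissueModel,
    build_ellipsoid_phantom,
    build_uniform_phantom,
)
from .transport import DiffuserSpec, FluenceMap, place_parallel_diffusers, simulate_fluence

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "scan"]

logger = logging.getLogger("ipdtsim")

SCAN_PARAMETERS = ("c0", "beta", "threshold", "linear_power_density", "interfiber_distance")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}': {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Complete, serializable description of one simulation run."""

    phantom: dict = field(default_factory=lambda: {
        "kind": "uniform", "dims": [64, 64, 64], "spacing_cm": [0.01, 0.01, 0.01],
        "c0_mol_per_L": 5.8e-6,
    })
    diffusers: list[dict] = field(default_factory=lambda: [{
        "position_cm": [0.32, 0.32, 0.12],
        "axis": [0.0, 0.0, 1.0],
        "radiation_length_cm": 0.4,
        "outer_diameter_cm": 0.11,
        "linear_power_density_mw_per_cm": 200.0,
        "time_s": 3600.0,
    }])
    photophysics: dict = field(default_factory=dict)  # PhotophysicalParams overrides
    n_photons: int = 1_000_000
    seed: int = 0
    threshold_mol_per_L: float = 5.6e-4
    output_dir: str = "ipdtsim_run"

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    # -- stage builders -----------------------------------------------------

    def build_model(self) -> TissueModel:
        spec = dict(self.phantom)
        kind = spec.get("kind", "uniform")
        try:
            if kind == "uniform":
                return build_uniform_phantom(
                    dims=spec["dims"],
                    spacing=spec["spacing_cm"],
                    c0=spec.get("c0_mol_per_L", 5.8e-6),
                )
            if kind == "ellipsoid":
                return build_ellipsoid_phantom(
                    dims=spec["dims"],
                    spacing=spec["spacing_cm"],
                    center=spec["center_cm"],
                    semi_axes=spec["semi_axes_cm"],
                    c0_tumor=spec.get("c0_mol_per_L", 5.8e-6),
                    tn_ratio=spec.get("tn_ratio", 95.0),
                )
            if kind == "labelmap":
                return _io.read_labelmap(spec["path"])
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("phantom", f"{exc} (phantom spec: {spec})") from exc
        raise PipelineError("phantom", f"unknown phantom kind {kind!r}")

    def build_diffusers(self) -> list[DiffuserSpec]:
        try:
            out = []
            for e in self.diffusers:
                out.append(DiffuserSpec(
                    tip_position=tuple(e["position_cm"]),
                    axis=tuple(e.get("axis", (0.0, 0.0, 1.0))),
                    radiation_length=float(e.get("radiation_length_cm", 4.0)),
                    outer_diameter=float(e.get("outer_diameter_cm", 0.11)),
                    linear_power_density=float(e.get("linear_power_density_mw_per_cm", 200.0)),
                    irradiation_time=float(e.get("time_s", 3600.0)),
                ))
            return out
        except Exception as exc:
            raise PipelineError("diffusers", str(exc)) from exc

    def build_params(self) -> PhotophysicalParams:
        try:
            return PhotophysicalParams(**self.photophysics)
        except Exception as exc:
            raise PipelineError("photophysics", str(exc)) from exc

    @property
    def irradiation_time(self) -> float:
        times = {float(e.get("time_s", 3600.0)) for e in self.diffusers}
        if len(times) > 1:
            raise PipelineError("diffusers", f"mixed irradiation times {sorted(times)}")
        return times.pop() if times else 3600.0


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Run phantom -> fluence -> dose -> outcome; write the output bundle.

    Writes ``config.yaml``, ``fluence.nii.gz`` (+ ``ledger.json``),
    ``dose_mM.nii.gz``, ``mask.nii.gz``, ``report.json`` and ``run.log``
    into ``config.output_dir``.  Returns a dict with the in-memory stage
    products (model, fluence, dose, mask, report, elapsed_s).
    """
    t0 = _time.perf_counter()
    out_dir = Path(config.output_dir)
    handler = None
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)

    try:
        model = config.build_model()
        diffusers = config.build_diffusers()
        params = config.build_params()
        logger.info("seed=%d n_photons=%d threshold=%g mol/L",
                    config.seed, config.n_photons, config.threshold_mol_per_L)

        try:
            fluence = simulate_fluence(model, diffusers, config.n_photons, config.seed)
        except Exception as exc:
            raise PipelineError("transport", str(exc)) from exc
        logger.info("transport ledger: %s (closure %.2e)", fluence.ledger,
                    fluence.ledger_closure())

        try:
            dmap = dose_map(fluence, config.irradiation_time, model, params)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("dose", str(exc)) from exc

        try:
            mask = cell_death_mask(dmap, config.threshold_mol_per_L)
            report = volume_metrics(mask, model, config.threshold_mol_per_L)
        except Exception as exc:
            raise PipelineError("outcome", str(exc)) from exc

        elapsed = _time.perf_counter() - t0
        logger.info("outcome: tv=%.4g cm^3 dv=%.4g cm^3 tc=%s (%.1f s)",
                    report.tv, report.dv, report.tc, elapsed)

        if write_outputs:
            config.to_yaml(out_dir / "config.yaml")
            _io.write_fluence(fluence, out_dir / "fluence.nii.gz", out_dir / "ledger.json")
            _io.write_dose(dmap, out_dir / "dose_mM.nii.gz")
            _io.write_scalar_volume(mask.astype(np.uint8), model.grid, out_dir / "mask.nii.gz")
            payload = report.to_dict()
            payload.update({"seed": config.seed, "n_photons": config.n_photons,
                            "elapsed_s": elapsed, "ledger": fluence.ledger})
            (out_dir / "report.json").write_text(json.dumps(payload, indent=1))

        return {
            "model": model,
            "fluence": fluence,
            "dose": dmap,
            "mask": mask,
            "report": report,
            "elapsed_s": elapsed,
        }
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()


def scan(parameter: str, values, config: RunConfig) -> pd.DataFrame:
    """Sweep one parameter, tabulating TV / DV / TC per value.

    ``parameter`` is one of ``c0``, ``beta``, ``threshold`` (closed-form
    fast path reusing one cached fluence map), ``linear_power_density`` or
    ``interfiber_distance`` (transport rerun per value).  Units: mol/L for
    c0 and threshold, J/cm^2 for beta, mW/cm for linear power density, cm
    for interfiber distance.
    """
    if parameter not in SCAN_PARAMETERS:
        raise ValueError(
            f"unknown scan parameter {parameter!r}; expected one of {SCAN_PARAMETERS}"
        )
    values = list(values)
    rows = []
    if parameter in ("c0", "beta", "threshold"):
        model = config.build_model()
        diffusers = config.build_diffusers()
        base_params = config.build_params()
        fluence = simulate_fluence(model, diffusers, config.n_photons, config.seed)
        for v in values:
            params = base_params
            mdl = model
            threshold = config.threshold_mol_per_L
            if parameter == "beta":
                params = base_params.with_(beta=float(v))
            elif parameter == "threshold":
                threshold = float(v)
            else:  # c0: rescale the concentration field
                base_c0 = config.phantom.get("c0_mol_per_L", 5.8e-6)
                scale = float(v) / base_c0 if base_c0 > 0 else 0.0
                mdl = dataclasses.replace(model, c0_field=model.c0_field * scale)
            dmap = dose_map(fluence, config.irradiation_time, mdl, params)
            rep = volume_metrics(cell_death_mask(dmap, threshold), mdl, threshold)
            rows.append({parameter: v, **_report_row(rep)})
    else:
        for v in values:
            cfg = dataclasses.replace(config)
            if parameter == "linear_power_density":
                cfg.diffusers = [
                    {**e, "linear_power_density_mw_per_cm": float(v)}
                    for e in config.diffusers
                ]
            else:  # interfiber_distance: re-place the bundle around the first tip
                n = len(config.diffusers)
                anchor = config.diffusers[0]["position_cm"]
                base = config.diffusers[0]
                placed = place_parallel_diffusers(
                    n, float(v),
                    axis=tuple(base.get("axis", (0, 0, 1))),
                    anchor=tuple(anchor),
                    radiation_length=float(base.get("radiation_length_cm", 4.0)),
                    outer_diameter=float(base.get("outer_diameter_cm", 0.11)),
                    linear_power_density=float(base.get("linear_power_density_mw_per_cm", 200.0)),
                    irradiation_time=float(base.get("time_s", 3600.0)),
                )
                cfg.diffusers = [
                    {
                        "position_cm": list(d.tip_position),
                        "axis": list(d.axis),
                        "radiation_length_cm": d.radiation_length,
                        "outer_diameter_cm": d.outer_diameter,
                        "linear_power_density_mw_per_cm": d.linear_power_density,
                        "time_s": d.irradiation_time,
                    }
                    for d in placed
                ]
            result = run_pipeline(cfg, write_outputs=False)
            rows.append({parameter: v, **_report_row(result["report"])})
    return pd.DataFrame(rows)


def _report_row(report) -> dict:
    return {
        "tv_cm3": report.tv,
        "dv_cm3": report.dv,
        "tc": report.tc if report.tc is not None else math.nan,
        "tumor_volume_cm3": report.tumor_volume,
    }
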
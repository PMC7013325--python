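"""File formats: NIfTI volumes with JSON sidecars, raw+JSON, YAML configs.

Tissue models are written as a NIfTI label volume (or a raw little-endian
binary) plus a JSON sidecar carrying the exact grid geometry, the tissue
property table and the PpIX field.  The sidecar is authoritative for
``spacing_cm``/``origin_cm`` so that round trips are bit-exact even when
the NIfTI affine (stored in mm) would round.

Schema of the sidecar::

    {"dims": [nx, ny, nz], "spacing_cm": [...], "origin_cm": [...],
     "labels": {"1": "normal", "2": "tumor"},
     "properties": {"2": {"mu_a_per_cm": ..., "mu_s_per_cm": ..., "g": ...}},
     "c0_file": "<stem>_c0.nii.gz" | null}
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .dose import DoseMap, PhotophysicalParams
from .grid import VoxelGrid
from .phantom import LABEL_NORMAL, LABEL_TUMOR, LABEL_VOID, OpticalProperties, TissueModel
from .transport import DiffuserSpec, FluenceMap

__all__ = [
    "write_model",
    "read_labelmap",
    "write_scalar_volume",
    "read_scalar_volume",
    "write_fluence",
    "write_dose",
    "load_diffuser_plan",
    "dump_diffuser_plan",
    "load_photophysical_params",
    "dump_photophysical_params",
    "load_tissue_properties",
]

_LABEL_NAMES = {LABEL_VOID: "void", LABEL_NORMAL: "normal", LABEL_TUMOR: "tumor"}


def _affine_mm(grid: VoxelGrid) -> np.ndarray:
    """NIfTI affine in mm (NIfTI convention) from a cm grid."""
    aff = np.diag([grid.spacing[0] * 10, grid.spacing[1] * 10, grid.spacing[2] * 10, 1.0])
    aff[:3, 3] = np.asarray(grid.origin) * 10
    return aff


def write_scalar_volume(data: np.ndarray, grid: VoxelGrid, path) -> None:
    """Write a per-voxel scalar field as NIfTI (spatial units: mm)."""
    img = nib.Nifti1Image(np.asarray(data), _affine_mm(grid))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_scalar_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def _sidecar_path(path: Path) -> Path:
    stem = path.name
    for suffix in (".nii.gz", ".nii", ".raw"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.with_name(stem + ".json")


def write_model(model: TissueModel, path) -> None:
    """Write a tissue model: labels (NIfTI or raw), c0 volume, JSON sidecar.

    ``path`` selects the label format by extension: ``.nii``/``.nii.gz``
    for NIfTI, anything else (canonically ``.raw``) for raw int32
    little-endian in C order.
    """
    path = Path(path)
    grid = model.grid
    is_nifti = path.name.endswith((".nii", ".nii.gz"))
    if is_nifti:
        write_scalar_volume(model.labels.astype(np.int16), grid, path)
        c0_name = path.name.replace(".nii", "_c0.nii", 1)
    else:
        model.labels.astype("<i4").tofile(path)
        c0_name = path.name + "_c0.nii.gz" if not path.name.endswith(".raw") else path.name[:-4] + "_c0.nii.gz"
    c0_path = path.with_name(c0_name)
    write_scalar_volume(model.c0_field, grid, c0_path)

    sidecar = {
        "dims": list(grid.dims),
        "spacing_cm": list(grid.spacing),
        "origin_cm": list(grid.origin),
        "labels": {
            str(int(lab)): _LABEL_NAMES.get(int(lab), f"tissue_{int(lab)}")
            for lab in np.unique(model.labels)
        },
        "properties": {
            str(lab): {"mu_a_per_cm": p.mu_a, "mu_s_per_cm": p.mu_s, "g": p.g}
            for lab, p in model.properties.items()
        },
        "label_format": "nifti" if is_nifti else "raw_int32_le",
        "c0_file": c0_path.name,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_labelmap(path) -> TissueModel:
    """Read a tissue model written by :func:`write_model`.

    Raises ``KeyError`` naming the offending label if the volume contains
    a nonzero label with no optical-properties entry in the sidecar.
    """
    path = Path(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    grid = VoxelGrid(
        tuple(sidecar["dims"]),
        tuple(sidecar["spacing_cm"]),
        tuple(sidecar.get("origin_cm", (0.0, 0.0, 0.0))),
    )
    if sidecar.get("label_format") == "raw_int32_le":
        labels = np.fromfile(path, dtype="<i4").reshape(grid.dims)
    else:
        labels = np.asarray(nib.load(str(path)).dataobj).astype(np.int32)
    properties = {
        int(lab): OpticalProperties(
            mu_a=entry["mu_a_per_cm"], mu_s=entry["mu_s_per_cm"], g=entry["g"]
        )
        for lab, entry in sidecar.get("properties", {}).items()
    }
    c0_file = sidecar.get("c0_file")
    if c0_file:
        c0_field = read_scalar_volume(path.with_name(c0_file)).astype(float)
    else:
        c0_field = np.zeros(grid.dims)
    # TissueModel.__post_init__ raises KeyError naming any unmapped label
    return TissueModel(grid, labels, properties, c0_field)


def write_fluence(fmap: FluenceMap, volume_path, ledger_path=None) -> None:
    """Fluence map as NIfTI (mW/cm^2) plus a JSON energy ledger."""
    write_scalar_volume(fmap.phi, fmap.grid, volume_path)
    if ledger_path is not None:
        payload = {
            "n_photons": fmap.n_photons,
            "seed": fmap.seed,
            "ledger": fmap.ledger,
            "units": "mW/cm^2",
        }
        Path(ledger_path).write_text(json.dumps(payload, indent=1))


def write_dose(dmap: DoseMap, path) -> None:
    """Dose map as NIfTI in mM."""
    write_scalar_volume(dmap.d_so_mM, dmap.grid, path)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_diffuser_plan(path) -> list[DiffuserSpec]:
    """Diffuser plan from YAML: a list of diffuser entries.

    Each entry: ``{position_cm, axis, radiation_length_cm,
    outer_diameter_cm, linear_power_density_mw_per_cm, time_s}``; all but
    ``position_cm`` optional.
    """
    doc = yaml.safe_load(Path(path).read_text())
    entries = doc["diffusers"] if isinstance(doc, dict) else doc
    out = []
    for e in entries:
        out.append(
            DiffuserSpec(
                tip_position=tuple(e["position_cm"]),
                axis=tuple(e.get("axis", (0.0, 0.0, 1.0))),
                radiation_length=float(e.get("radiation_length_cm", 4.0)),
                outer_diameter=float(e.get("outer_diameter_cm", 0.11)),
                linear_power_density=float(e.get("linear_power_density_mw_per_cm", 200.0)),
                irradiation_time=float(e.get("time_s", 3600.0)),
            )
        )
    return out


def dump_diffuser_plan(diffusers, path) -> None:
    entries = [
        {
            "position_cm": list(d.tip_position),
            "axis": list(d.axis),
            "radiation_length_cm": d.radiation_length,
            "outer_diameter_cm": d.outer_diameter,
            "linear_power_density_mw_per_cm": d.linear_power_density,
            "time_s": d.irradiation_time,
        }
        for d in diffusers
    ]
    Path(path).write_text(yaml.safe_dump({"diffusers": entries}, sort_keys=False))


def load_photophysical_params(path) -> PhotophysicalParams:
    """Photophysical parameters from YAML with units embedded in key names."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    mapping = {
        "epsilon_per_cm_M": "epsilon",
        "wavelength_nm": "wavelength",
        "phi_quantum": "phi_quantum",
        "beta_J_per_cm2": "beta",
        "bleaching_enabled": "bleaching_enabled",
    }
    for key, attr in mapping.items():
        if key in doc:
            val = doc[key]
            if key == "wavelength_nm":
                val = float(val) * 1e-7  # nm -> cm
            kwargs[attr] = val
    return PhotophysicalParams(**kwargs)


def dump_photophysical_params(params: PhotophysicalParams, path) -> None:
    doc = {
        "epsilon_per_cm_M": params.epsilon,
        "wavelength_nm": params.wavelength * 1e7,
        "phi_quantum": params.phi_quantum,
        "beta_J_per_cm2": params.beta,
        "bleaching_enabled": params.bleaching_enabled,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_tissue_properties(path) -> dict[int, OpticalProperties]:
    """Tissue property table from YAML: ``{label: {mu_a_per_cm, mu_s_per_cm, g}}``."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return {
        int(lab): OpticalProperties(
            mu_a=entry["mu_a_per_cm"], mu_s=entry["mu_s_per_cm"], g=entry["g"]
        )
        for lab, entry in doc.items()
    }
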
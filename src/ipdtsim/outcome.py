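"""Threshold cell-death model and treated-volume metrics.

Cell death is assumed wherever the accumulated singlet-oxygen
concentration reaches the cytotoxicity threshold D_SO(th) (default
0.56 mM = 5.6e-4 mol/L).  The same threshold is applied to tumor and
normal tissue — a deliberately conservative choice for normal tissue.

Metrics:

* TV, treated volume — killed tumor tissue, cm^3;
* DV, damaged volume — killed normal tissue, cm^3;
* TC, tumor coverage — TV / total tumor volume.

The threshold comparison is inclusive (>=): a voxel driven exactly to the
threshold — e.g. by irradiating at the fluence returned by
``required_fluence`` — counts as treated, keeping the inversion identity
exact under floating point.  Pass ``strict=True`` for a strict (>)
comparison.  Voxels are counted whole; no partial-volume weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose import DoseMap
from .phantom import TissueModel
from .transport import DiffuserSpec

__all__ = [
    "OutcomeReport",
    "cell_death_mask",
    "volume_metrics",
    "radial_dose_profile",
]


@dataclass
class OutcomeReport:
    """Treatment-outcome summary for one dose map.

    Volumes in cm^3; ``tc`` is dimensionless in [0, 1] and ``None`` when
    the model contains no tumor (undefined ratio).
    """

    threshold: float          # mol/L
    mask: np.ndarray          # boolean cell-death indicator
    tv: float                 # treated (killed tumor) volume, cm^3
    dv: float                 # damaged (killed normal) volume, cm^3
    tc: float | None          # tumor coverage TV / tumor volume
    tumor_volume: float       # cm^3
    n_masked_voxels: int

    def to_dict(self) -> dict:
        return {
            "threshold_mM": self.threshold * 1e3,
            "tv_cm3": self.tv,
            "dv_cm3": self.dv,
            "tc": self.tc,
            "tumor_volume_cm3": self.tumor_volume,
            "n_masked_voxels": self.n_masked_voxels,
        }


def cell_death_mask(dose: DoseMap, threshold: float, strict: bool = False) -> np.ndarray:
    """Boolean field: where the dose reaches the cell-death threshold.

    ``threshold`` in mol/L.  Inclusive comparison by default (ties count
    as death); ``strict=True`` switches to >.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if strict:
        return dose.d_so > threshold
    return dose.d_so >= threshold


def volume_metrics(
    mask: np.ndarray,
    model: TissueModel,
    threshold: float = 5.6e-4,
) -> OutcomeReport:
    """TV / DV / TC from a cell-death mask and the tissue segmentation."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != model.grid.dims:
        raise ValueError("mask shape does not match the model grid")
    vv = model.grid.voxel_volume
    tv = float(np.count_nonzero(mask & model.tumor_mask)) * vv
    dv = float(np.count_nonzero(mask & model.normal_mask)) * vv
    tumor_volume = model.tumor_volume
    tc = tv / tumor_volume if tumor_volume > 0 else None
    return OutcomeReport(
        threshold=threshold,
        mask=mask,
        tv=tv,
        dv=dv,
        tc=tc,
        tumor_volume=tumor_volume,
        n_masked_voxels=int(np.count_nonzero(mask)),
    )


def radial_dose_profile(
    dose: DoseMap,
    diffuser: DiffuserSpec,
    n_bins: int = 30,
) -> pd.DataFrame:
    """Mean dose vs cylindrical radius around the diffuser axis.

    Voxel centers whose axial coordinate falls within the radiation-length
    extent of the diffuser are binned by distance from the axis, from the
    diffuser surface out to the largest radius present in the grid.
    Returns a DataFrame with columns ``radius_cm`` (bin center),
    ``mean_dose_mM``, ``stderr_mM`` and ``n_voxels``; empty bins carry NaN
    means, not zeros.
    """
    grid = dose.grid
    cx = grid.voxel_centers(0)
    cy = grid.voxel_centers(1)
    cz = grid.voxel_centers(2)
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    tip = np.asarray(diffuser.tip_position)
    ax = np.asarray(diffuser.axis)
    dx = X - tip[0]
    dy = Y - tip[1]
    dz = Z - tip[2]
    axial = dx * ax[0] + dy * ax[1] + dz * ax[2]
    r2 = dx * dx + dy * dy + dz * dz - axial * axial
    radial = np.sqrt(np.maximum(r2, 0.0))

    in_extent = (axial >= 0.0) & (axial <= diffuser.radiation_length)
    if not in_extent.any():
        raise ValueError("diffuser radiation section does not overlap the grid")

    r = radial[in_extent]
    d = dose.d_so[in_extent] * 1e3  # mM
    r_max = float(r.max())
    edges = np.linspace(diffuser.radius, r_max, n_bins + 1)
    idx = np.digitize(r, edges) - 1

    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(np.count_nonzero(sel))
        if n == 0:
            mean = math.nan
            stderr = math.nan
        else:
            vals = d[sel]
            mean = float(vals.mean())
            stderr = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        rows.append(
            {
                "radius_cm": 0.5 * (edges[b] + edges[b + 1]),
                "mean_dose_mM": mean,
                "stderr_mM": stderr,
                "n_voxels": n,
            }
        )
    return pd.DataFrame(rows)
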
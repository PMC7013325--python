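"""Voxelized tissue models for interstitial PDT simulation.

A :class:`TissueModel` couples a voxel grid with a per-voxel tissue label,
a tissue-class -> optical-properties table, and a per-voxel initial
photosensitizer (PpIX) concentration field C0(x, y, z) in mol/L.

Two parametric phantom generators stand in for patient imaging:

* a uniform tumor block (the standard setting for photobleaching and
  concentration sensitivity analyses), and
* an ellipsoidal tumor embedded in normal white matter, with the normal
  tissue PpIX set by the tumor-to-normal (TN) uptake ratio.

Default optical properties at 635 nm: tumor mu_a = 1.7 /cm, mu_s = 365 /cm,
g = 0.9; white matter mu_a = 0.7 /cm, mu_s = 951 /cm, g = 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid

__all__ = [
    "OpticalProperties",
    "TissueModel",
    "build_uniform_phantom",
    "build_ellipsoid_phantom",
    "tissue_volumes",
    "LABEL_VOID",
    "LABEL_NORMAL",
    "LABEL_TUMOR",
    "TUMOR_PROPS_635NM",
    "WHITE_MATTER_PROPS_635NM",
]

# Tissue label convention: 0 is outside/void (absorbs nothing, terminates
# photons), 1 is normal tissue (white matter), 2 is tumor.
LABEL_VOID = 0
LABEL_NORMAL = 1
LABEL_TUMOR = 2


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption mu_a (/cm), scattering mu_s (/cm), anisotropy g."""

    mu_a: float
    mu_s: float
    g: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"g must lie in (-1, 1), got {self.g}")
        if self.mu_a + self.mu_s <= 0:
            raise ValueError("mu_a + mu_s must be > 0 for traversable tissue")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, /cm."""
        return self.mu_a + self.mu_s

    @property
    def mu_s_reduced(self) -> float:
        """Reduced scattering coefficient mu_s' = mu_s (1 - g), /cm."""
        return self.mu_s * (1.0 - self.g)


# Malignant brain tumor and white matter at 635 nm.
TUMOR_PROPS_635NM = OpticalProperties(mu_a=1.7, mu_s=365.0, g=0.9)
WHITE_MATTER_PROPS_635NM = OpticalProperties(mu_a=0.7, mu_s=951.0, g=0.9)


@dataclass
class TissueModel:
    """Voxel grid + tissue labels + optical properties + PpIX field.

    Attributes
    ----------
    grid
        The voxel lattice.
    labels
        int array, shape ``grid.dims``; 0 = void, other values index
        ``properties``.
    properties
        Mapping tissue label -> :class:`OpticalProperties`; every nonzero
        label present in ``labels`` must have an entry.
    c0_field
        Initial PpIX concentration per voxel, mol/L; zero in void voxels.
    """

    grid: VoxelGrid
    labels: np.ndarray
    properties: dict[int, OpticalProperties]
    c0_field: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int32)
        self.c0_field = np.ascontiguousarray(self.c0_field, dtype=np.float64)
        if self.labels.shape != self.grid.dims:
            raise ValueError(
                f"labels shape {self.labels.shape} != grid dims {self.grid.dims}"
            )
        if self.c0_field.shape != self.grid.dims:
            raise ValueError(
                f"c0_field shape {self.c0_field.shape} != grid dims {self.grid.dims}"
            )
        present = np.unique(self.labels)
        for lab in present:
            lab = int(lab)
            if lab != LABEL_VOID and lab not in self.properties:
                raise KeyError(
                    f"tissue label {lab} has no optical-properties entry"
                )
        if np.any(self.c0_field < 0):
            raise ValueError("c0_field must be >= 0 everywhere")
        if np.any(self.c0_field[self.labels == LABEL_VOID] != 0):
            raise ValueError("c0_field must be 0 in void voxels")

    # -- lookup tables used by the transport kernel -------------------------

    def property_tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-label (mu_a, mu_s, g) arrays indexed by tissue label.

        Label 0 (void) gets zeros; the transport kernel terminates photons
        there regardless.
        """
        max_label = int(self.labels.max(initial=0))
        mu_a = np.zeros(max_label + 1)
        mu_s = np.zeros(max_label + 1)
        g = np.zeros(max_label + 1)
        for lab, props in self.properties.items():
            if lab <= max_label:
                mu_a[lab] = props.mu_a
                mu_s[lab] = props.mu_s
                g[lab] = props.g
        return mu_a, mu_s, g

    def mu_a_field(self) -> np.ndarray:
        """Per-voxel absorption coefficient, /cm (0 in void)."""
        mu_a, _, _ = self.property_tables()
        return mu_a[self.labels]

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels == LABEL_TUMOR

    @property
    def normal_mask(self) -> np.ndarray:
        return self.labels == LABEL_NORMAL

    @property
    def tumor_volume(self) -> float:
        """Total tumor volume, cm^3."""
        return float(np.count_nonzero(self.tumor_mask)) * self.grid.voxel_volume


def tissue_volumes(model: TissueModel) -> dict[str, float]:
    """Tumor / normal / void volumes in cm^3; they sum to the grid volume."""
    vv = model.grid.voxel_volume
    n_tumor = int(np.count_nonzero(model.labels == LABEL_TUMOR))
    n_normal = int(np.count_nonzero(model.labels == LABEL_NORMAL))
    n_void = model.grid.n_voxels - n_tumor - n_normal
    return {
        "tumor_cm3": n_tumor * vv,
        "normal_cm3": n_normal * vv,
        "void_cm3": n_void * vv,
        "total_cm3": model.grid.n_voxels * vv,
    }


def build_uniform_phantom(
    dims,
    spacing,
    props: OpticalProperties = TUMOR_PROPS_635NM,
    c0: float = 5.8e-6,
    origin=(0.0, 0.0, 0.0),
) -> TissueModel:
    """Uniform tumor-only phantom.

    Every voxel is labeled tumor with identical optical properties and
    initial PpIX concentration ``c0`` (mol/L).  The default c0 of 5.8 uM is
    the typical ALA-induced PpIX level measured in malignant brain tumors.
    """
    grid = VoxelGrid(tuple(dims), tuple(spacing), tuple(origin))
    if c0 < 0:
        raise ValueError(f"c0 must be >= 0, got {c0}")
    labels = np.full(grid.dims, LABEL_TUMOR, dtype=np.int32)
    c0_field = np.full(grid.dims, float(c0))
    return TissueModel(grid, labels, {LABEL_TUMOR: props}, c0_field)


def build_ellipsoid_phantom(
    dims,
    spacing,
    center,
    semi_axes,
    tumor_props: OpticalProperties = TUMOR_PROPS_635NM,
    normal_props: OpticalProperties = WHITE_MATTER_PROPS_635NM,
    c0_tumor: float = 5.8e-6,
    tn_ratio: float = 95.0,
    origin=(0.0, 0.0, 0.0),
) -> TissueModel:
    """Ellipsoidal tumor embedded in normal white matter.

    A voxel is tumor when its *center* lies inside the ellipsoid
    ``sum(((x_a - center_a)/semi_axes_a)^2) <= 1``.  Tumor voxels get
    ``c0_tumor``; normal voxels get ``c0_tumor / tn_ratio``, where
    ``tn_ratio`` is the tumor-to-normal photosensitizer uptake ratio
    (reported values for ALA-PpIX in brain span roughly 12 to 95 depending
    on the reference normal tissue).

    Raises
    ------
    ValueError
        If the ellipsoid contains no voxel center (empty tumor).
    """
    grid = VoxelGrid(tuple(dims), tuple(spacing), tuple(origin))
    semi_axes = tuple(float(a) for a in semi_axes)
    if any(a <= 0 for a in semi_axes):
        raise ValueError(f"semi_axes must be > 0, got {semi_axes}")
    if tn_ratio <= 0:
        raise ValueError(f"tn_ratio must be > 0, got {tn_ratio}")
    if c0_tumor < 0:
        raise ValueError(f"c0_tumor must be >= 0, got {c0_tumor}")

    cx = grid.voxel_centers(0)
    cy = grid.voxel_centers(1)
    cz = grid.voxel_centers(2)
    fx = ((cx - center[0]) / semi_axes[0]) ** 2
    fy = ((cy - center[1]) / semi_axes[1]) ** 2
    fz = ((cz - center[2]) / semi_axes[2]) ** 2
    inside = (
        fx[:, None, None] + fy[None, :, None] + fz[None, None, :]
    ) <= 1.0
    if not inside.any():
        raise ValueError("ellipsoid contains no voxel center (empty tumor)")

    labels = np.where(inside, LABEL_TUMOR, LABEL_NORMAL).astype(np.int32)
    c0_field = np.where(inside, float(c0_tumor), float(c0_tumor) / float(tn_ratio))
    props = {LABEL_TUMOR: tumor_props, LABEL_NORMAL: normal_props}
    return TissueModel(grid, labels, props, c0_field)
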
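"""Voxelwise MR g-ratio mapping and the Rushton conduction-velocity model.

The MR g-ratio is the area-weighted ensemble average of the per-axon
g-ratio g = d/D (inner axon diameter over outer fibre diameter) estimated
per voxel from two MRI-derived volume fractions::

    MVF = alpha * MTsat                 (myelin volume fraction)
    AWF = (1 - nu_iso) * nu_icvf        (axonal water fraction, NODDI)
    AVF = (1 - MVF) * AWF               (axonal volume fraction)
    g   = sqrt(AVF / (AVF + MVF))

Conduction velocity is modelled ordinally by Rushton's relation
``v = d * sqrt(-ln g)`` with the proportionality constant fixed at 1, so
all velocities are an index, not m/s.  The iso-velocity simulation maps
which (d, g) combinations share a velocity index, which supports the
microstructural scenario logic in :func:`classify_scenario`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

logger = logging.getLogger("tractvelocity")

#: Default MTsat -> MVF calibration factor (g-ratio based calibration).
DEFAULT_ALPHA = 0.1683

#: MVF is clipped into [0, 1 - MVF_CLIP_EPS] so AVF/(AVF+MVF) stays defined.
MVF_CLIP_EPS = 1e-9

#: Tolerance on affine agreement (mm) when two maps must share a grid.
AFFINE_TOL = 1e-4


class DomainError(ValueError):
    """A scalar argument is outside its physical domain."""


class GridMismatchError(ValueError):
    """Two voxel maps do not share shape and affine."""


# ---------------------------------------------------------------------------
# VoxelMap
# ---------------------------------------------------------------------------

@dataclass
class VoxelMap:
    """A 3D scalar lattice with grid metadata.

    Non-finite values are permitted and propagate through all arithmetic.
    """

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    units_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.isfinite(np.linalg.det(self.affine)) or np.linalg.det(self.affine) == 0:
            raise ValueError("affine must be invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_grid(self, other: "VoxelMap", tol: float = AFFINE_TOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )

    def require_same_grid(self, other: "VoxelMap") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: shape {self.shape} vs {other.shape} "
                "or affines disagree beyond tolerance"
            )

    def with_values(self, values: np.ndarray, units_label: str = "") -> "VoxelMap":
        """New map on this grid with replaced data."""
        return VoxelMap(np.asarray(values, dtype=float), self.affine.copy(), units_label)

    @classmethod
    def from_nifti(cls, path, units_label: str = "") -> "VoxelMap":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        data = np.squeeze(data)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a single 3D volume, got shape {data.shape}")
        return cls(data, np.asarray(img.affine, dtype=float), units_label)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine), str(path))


# ---------------------------------------------------------------------------
# Axon geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxonGeometry:
    """Consistent (d, D, t, g) description of a myelinated axon.

    d : inner axon diameter (um), > 0
    D : outer fibre diameter (um), >= d
    t : myelin sheath thickness (um), t = (D - d) / 2
    g : g-ratio d / D in (0, 1]
    """

    d: float
    D: float
    t: float
    g: float

    @classmethod
    def from_d_D(cls, d: float, D: float) -> "AxonGeometry":
        g = gratio_from_geometry(d, D)
        return cls(d=d, D=D, t=(D - d) / 2.0, g=g)

    @classmethod
    def from_d_g(cls, d: float, g: float) -> "AxonGeometry":
        t = myelin_thickness(d, g)
        return cls(d=d, D=d + 2.0 * t, t=t, g=g)


def gratio_from_geometry(d: float, D: float) -> float:
    """g = d / D for inner diameter d and outer fibre diameter D (um)."""
    if not (np.isfinite(d) and np.isfinite(D)):
        raise DomainError("d and D must be finite")
    if d <= 0:
        raise DomainError(f"inner diameter must be positive, got d={d}")
    if D < d:
        raise DomainError(f"outer diameter must be >= inner diameter (d={d}, D={D})")
    return d / D


def myelin_thickness(d, g):
    """Myelin sheath thickness t = d (1 - g) / (2 g) in um.

    Accepts scalars or arrays; d > 0 and g in (0, 1] elementwise.
    """
    d = np.asarray(d, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(d <= 0):
        raise DomainError("inner diameter must be positive")
    if np.any((g <= 0) | (g > 1)):
        raise DomainError("g-ratio must lie in (0, 1]")
    t = d * (1.0 - g) / (2.0 * g)
    return float(t) if t.ndim == 0 else t


def conduction_velocity_index(d, g):
    """Rushton velocity index v = d * sqrt(-ln g) (arbitrary units).

    v = 0 iff d = 0 or g = 1. The proportionality constant is fixed at 1.
    """
    d = np.asarray(d, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(d < 0):
        raise DomainError("diameter must be non-negative")
    if np.any((g <= 0) | (g > 1)):
        raise DomainError("g-ratio must lie in (0, 1]")
    v = d * np.sqrt(-np.log(g))
    return float(v) if v.ndim == 0 else v


# ---------------------------------------------------------------------------
# Voxelwise g-ratio chain
# ---------------------------------------------------------------------------

def calibrate_mvf(mtsat: VoxelMap, alpha: float = DEFAULT_ALPHA) -> VoxelMap:
    """Calibrate an MTsat map to a myelin volume fraction map, MVF = alpha * MTsat.

    Negative MTsat values are clipped to 0 (count logged); the result is
    clipped into [0, 1) because a volume fraction must be physical.
    Non-finite voxels stay non-finite.
    """
    if not np.isfinite(alpha) or alpha <= 0:
        raise DomainError(f"calibration alpha must be finite and positive, got {alpha}")
    vals = mtsat.values
    n_neg = int(np.sum(vals < 0))
    if n_neg:
        logger.warning("calibrate_mvf: clipped %d negative MTsat voxels to 0", n_neg)
    mvf = np.clip(alpha * vals, 0.0, 1.0 - MVF_CLIP_EPS)
    n_nan = int(np.sum(~np.isfinite(vals)))
    if n_nan:
        logger.info("calibrate_mvf: %d non-finite voxels propagated", n_nan)
    return mtsat.with_values(mvf, "MVF")


def compute_awf(nu_icvf: VoxelMap, nu_iso: VoxelMap) -> VoxelMap:
    """Axonal water fraction AWF = (1 - nu_iso) * nu_icvf (NODDI maps)."""
    nu_icvf.require_same_grid(nu_iso)
    awf = (1.0 - nu_iso.values) * nu_icvf.values
    return nu_icvf.with_values(awf, "AWF")


def compute_avf(mvf: VoxelMap, awf: VoxelMap) -> VoxelMap:
    """Axonal volume fraction AVF = (1 - MVF) * AWF."""
    mvf.require_same_grid(awf)
    avf = (1.0 - mvf.values) * awf.values
    return mvf.with_values(avf, "AVF")


def compute_gratio(mvf: VoxelMap, avf: VoxelMap) -> VoxelMap:
    """MR g-ratio map g = sqrt(AVF / (AVF + MVF)).

    Voxels where MVF + AVF = 0 and voxels with a negative volume fraction
    become NaN (negative-input count logged as a warning).
    """
    mvf.require_same_grid(avf)
    m, a = mvf.values, avf.values
    neg = (m < 0) | (a < 0)
    n_neg = int(np.sum(neg))
    if n_neg:
        logger.warning("compute_gratio: %d voxels with negative volume fractions -> NaN", n_neg)
    denom = m + a
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.sqrt(np.where(denom > 0, a / np.where(denom > 0, denom, 1.0), np.nan))
    g = np.where(neg, np.nan, g)
    n_nan = int(np.sum(~np.isfinite(g)))
    if n_nan:
        logger.info("compute_gratio: %d non-finite voxels in output", n_nan)
    return mvf.with_values(g, "g-ratio")


def gratio_map_from_inputs(
    mtsat: VoxelMap,
    nu_icvf: VoxelMap,
    nu_iso: VoxelMap,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, VoxelMap]:
    """Run the full voxelwise chain; returns MVF, AWF, AVF and g maps."""
    mvf = calibrate_mvf(mtsat, alpha)
    awf = compute_awf(nu_icvf, nu_iso)
    avf = compute_avf(mvf, awf)
    g = compute_gratio(mvf, avf)
    return {"mvf": mvf, "awf": awf, "avf": avf, "g_ratio": g}


# ---------------------------------------------------------------------------
# Iso-velocity simulation
# ---------------------------------------------------------------------------

@dataclass
class IsoVelocityGrid:
    """(d, g) lattice with velocity index, myelin thickness and contours.

    ``contours`` maps each requested velocity level to a list of polylines,
    each polyline an (m, 2) array of (d, g) points along which the velocity
    index equals the level to within ``tolerance``.
    """

    d_axis: np.ndarray
    g_axis: np.ndarray
    v: np.ndarray
    t: np.ndarray
    contours: dict[float, list[np.ndarray]]
    tolerance: float


def iso_velocity_surface(
    d_range: tuple[float, float] = (0.1, 3.0),
    g_range: tuple[float, float] = (0.4, 0.95),
    resolution: tuple[int, int] = (200, 200),
    levels: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0),
    tolerance: float | None = None,
) -> IsoVelocityGrid:
    """Evaluate the velocity index on a (d, g) lattice and extract iso-velocity contours.

    Myelin thickness is evaluated at every node too, reproducing the
    gradient with thickest myelin at the small-g / large-d corner.  A level
    above the lattice maximum yields an empty contour with a warning.
    """
    d_lo, d_hi = d_range
    g_lo, g_hi = g_range
    if not (d_hi > d_lo >= 0):
        raise DomainError(f"degenerate d range {d_range}")
    if not (0 < g_lo < g_hi <= 1):
        raise DomainError(f"g range {g_range} must be a non-degenerate subset of (0, 1]")
    nd, ng = resolution
    if nd < 2 or ng < 2:
        raise DomainError(f"grid resolution {resolution} too coarse")
    if any(lv < 0 for lv in levels):
        raise DomainError("velocity levels must be non-negative")

    d_axis = np.linspace(d_lo, d_hi, nd)
    g_axis = np.linspace(g_lo, g_hi, ng)
    dd, gg = np.meshgrid(d_axis, g_axis, indexing="ij")
    v = conduction_velocity_index(dd, gg)
    t = myelin_thickness(np.maximum(dd, np.finfo(float).tiny), gg)

    if tolerance is None:
        # linear-interpolation error bound ~ h^2 * |f''| / 8 on a smooth field
        tolerance = max(1e-6, 0.5 * _max_cell_variation(v))

    from skimage.measure import find_contours

    contours: dict[float, list[np.ndarray]] = {}
    vmax = float(np.nanmax(v))
    for level in levels:
        level = float(level)
        if level > vmax:
            warnings.warn(
                f"iso-velocity level {level} exceeds grid maximum {vmax:.4g}; empty contour",
                stacklevel=2,
            )
            contours[level] = []
            continue
        polys = []
        for c in find_contours(v, level):
            # fractional indices -> (d, g) coordinates
            d_pts = np.interp(c[:, 0], np.arange(nd), d_axis)
            g_pts = np.interp(c[:, 1], np.arange(ng), g_axis)
            polys.append(np.column_stack([d_pts, g_pts]))
        contours[level] = polys
    return IsoVelocityGrid(d_axis, g_axis, v, t, contours, tolerance)


def _max_cell_variation(v: np.ndarray) -> float:
    """Largest value swing within any single grid cell (contour error scale)."""
    dv0 = np.abs(np.diff(v, axis=0)).max() if v.shape[0] > 1 else 0.0
    dv1 = np.abs(np.diff(v, axis=1)).max() if v.shape[1] > 1 else 0.0
    return float(dv0 + dv1)


# ---------------------------------------------------------------------------
# Scenario classification
# ---------------------------------------------------------------------------

class Association(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NULL = "null"


class Scenario(str, Enum):
    MYELIN_DOMINANT = "myelin_dominant"
    MYELIN_PLUS_AXON = "myelin_plus_axon"
    AXON_DIAMETER_DOMINANT = "axon_diameter_dominant"
    PROPORTIONAL_CHANGE = "proportional_change"
    NO_CHANGE = "no_change"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ScenarioCall:
    g_assoc: Association
    myelin_assoc: Association
    scenario: Scenario


def classify_scenario(g_assoc: str, myelin_assoc: str) -> ScenarioCall:
    """Interpret g-ratio and myelin-marker association signs microstructurally.

    Under the working assumption that a significant association reflects
    faster conduction velocity:

    - negative g-ratio association, myelin null/negative -> thicker myelin
      at constant axon diameter (myelin dominant);
    - negative g-ratio with positive myelin -> thicker myelin accompanied by
      a larger inner axon diameter;
    - positive g-ratio association (any myelin) -> predominantly larger
      inner axon diameter;
    - null g-ratio with positive myelin -> proportional growth of axon and
      sheath (g unchanged, velocity changed);
    - null/null -> no microstructural change.
    """
    try:
        ga = Association(g_assoc)
        ma = Association(myelin_assoc)
    except ValueError as exc:
        raise DomainError(f"unknown association label: {exc}") from None

    if ga is Association.NEGATIVE:
        scenario = (
            Scenario.MYELIN_PLUS_AXON
            if ma is Association.POSITIVE
            else Scenario.MYELIN_DOMINANT
        )
    elif ga is Association.POSITIVE:
        scenario = Scenario.AXON_DIAMETER_DOMINANT
    else:  # null g-ratio association
        if ma is Association.POSITIVE:
            scenario = Scenario.PROPORTIONAL_CHANGE
        elif ma is Association.NULL:
            scenario = Scenario.NO_CHANGE
        else:
            scenario = Scenario.INDETERMINATE
    return ScenarioCall(ga, ma, scenario)
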
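"""Domain types for annotated synaptonemal-complex (SC) point models.

An SC model holds the three segmented elements of the complex — the two
lateral elements (LEs) and the central element (CE) — plus the set of
transverse filament (TF) traces, together with the calibration needed to
convert reconstructed-volume pixel coordinates into nanometers.

Elements come in two representations:

* ``point_cloud`` — the raw segmented points, as exported by IMOD's
  ``model2point``; membership is defined by a distance threshold ``delta``.
* ``slab`` — an oriented box with exact boundaries. Real segmentations are
  clouds; slabs exist so that synthetic models have analytically exact
  element surfaces for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

ROLE_LE_LEFT = "LE_left"
ROLE_LE_RIGHT = "LE_right"
ROLE_CE = "CE"
ELEMENT_ROLES = (ROLE_LE_LEFT, ROLE_LE_RIGHT, ROLE_CE)

_AXES_ORTHO_TOL = 1e-9


def _as_points(points: object) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) array of points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    return pts


@dataclass
class Polyline:
    """An ordered trace of points, typically one transverse filament.

    A well-formed trace has >= 2 points and no identical consecutive points;
    degenerate traces are representable so that :func:`validate_model` can
    report them instead of the constructor refusing real-world files.
    """

    points: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if len(self.points) < 1:
            raise ValueError("a polyline needs at least 1 point")

    @property
    def is_degenerate(self) -> bool:
        if len(self.points) < 2:
            return True
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return bool(np.any(steps == 0.0))

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[0], self.points[-1]

    def reversed(self) -> "Polyline":
        return Polyline(self.points[::-1].copy(), self.label)


@dataclass
class ElementRegion:
    """One segmented SC element (LE_left / LE_right / CE).

    ``kind`` selects the active representation. A region may carry both a
    cloud and a slab (synthetic models do); geometry kernels only consult
    the fields of the active kind.
    """

    role: str
    kind: str  # "point_cloud" | "slab"
    points: np.ndarray | None = None
    delta_nm: float | None = None
    center: np.ndarray | None = None
    axes: np.ndarray | None = None  # rows are orthonormal box axes
    half_extents: np.ndarray | None = None
    _tree: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.role not in ELEMENT_ROLES:
            raise ValueError(f"unknown element role {self.role!r}")
        if self.kind not in ("point_cloud", "slab"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.points is not None:
            self.points = _as_points(self.points)
        if self.kind == "point_cloud":
            if self.points is None or len(self.points) < 4:
                raise ValueError("point_cloud region needs >= 4 points")
            if self.delta_nm is not None and self.delta_nm <= 0:
                raise ValueError("membership radius delta must be > 0")
        else:
            if self.center is None or self.axes is None or self.half_extents is None:
                raise ValueError("slab region needs center, axes and half_extents")
            self.center = np.asarray(self.center, dtype=float).reshape(3)
            self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
            self.half_extents = np.asarray(self.half_extents, dtype=float).reshape(3)
            if np.any(self.half_extents <= 0):
                raise ValueError("slab half-extents must be > 0")
            if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
                raise ValueError("slab axes must be orthonormal within 1e-9")

    @property
    def has_slab(self) -> bool:
        return self.center is not None and self.axes is not None

    @property
    def has_cloud(self) -> bool:
        return self.points is not None and len(self.points) >= 4

    def with_kind(self, kind: str) -> "ElementRegion":
        """Return a copy with the other representation made active."""
        if kind == self.kind:
            return self
        region = replace(self, kind=kind, _tree=None)
        return region

    def tree(self):
        """KD-tree over the cloud points (cached)."""
        if self._tree is None:
            from scipy.spatial import cKDTree

            if self.points is None:
                raise ValueError(f"region {self.role} has no point cloud")
            self._tree = cKDTree(self.points)
        return self._tree


@dataclass
class ScaleInfo:
    """Calibration: pixel size, nominal section thickness and the z-scale
    factor correcting for section thinning during data collection.

    The z factor is the ratio of the nominal section thickness to the
    reconstructed volume's physical z extent; models are stretched by it in z.
    """

    pixel_size_nm: float = 0.287
    section_thickness_nm: float = 250.0
    z_extent_px: float | None = None
    z_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.z_factor <= 0:
            raise ValueError("z_factor must be > 0")

    @classmethod
    def from_z_extent(
        cls,
        section_thickness_nm: float,
        z_extent_px: float,
        pixel_size_nm: float = 0.287,
    ) -> "ScaleInfo":
        factor = compute_z_factor(section_thickness_nm, z_extent_px, pixel_size_nm)
        return cls(pixel_size_nm, section_thickness_nm, z_extent_px, factor)


def compute_z_factor(
    section_thickness_nm: float, z_extent_px: float, pixel_size_nm: float
) -> float:
    """z-scale factor = nominal section thickness / reconstructed z extent (nm)."""
    for name, val in (
        ("section_thickness_nm", section_thickness_nm),
        ("z_extent_px", z_extent_px),
        ("pixel_size_nm", pixel_size_nm),
    ):
        if val <= 0:
            raise ValueError(f"{name} must be > 0, got {val}")
    return section_thickness_nm / (z_extent_px * pixel_size_nm)


@dataclass
class SCModel:
    """One tomogram's annotated SC geometry."""

    le_left: ElementRegion
    le_right: ElementRegion
    ce: ElementRegion
    tfs: list[Polyline]
    scale: ScaleInfo | None = None
    units: str = "px"  # "px" | "nm"
    source: str = ""

    def __post_init__(self) -> None:
        if self.units not in ("px", "nm"):
            raise ValueError(f"units must be 'px' or 'nm', got {self.units!r}")
        if self.le_left.role != ROLE_LE_LEFT or self.le_right.role != ROLE_LE_RIGHT:
            raise ValueError("lateral element regions carry the wrong roles")
        if self.ce.role != ROLE_CE:
            raise ValueError("central element region carries the wrong role")
        if len(self.tfs) < 1:
            raise ValueError("model must contain at least one transverse filament")

    @property
    def regions(self) -> dict[str, ElementRegion]:
        return {ROLE_LE_LEFT: self.le_left, ROLE_LE_RIGHT: self.le_right, ROLE_CE: self.ce}

    def region(self, role: str) -> ElementRegion:
        return self.regions[role]

    def with_region_kind(self, kind: str) -> "SCModel":
        """Copy of the model with every element switched to ``kind``."""
        return replace(
            self,
            le_left=self.le_left.with_kind(kind),
            le_right=self.le_right.with_kind(kind),
            ce=self.ce.with_kind(kind),
        )


def _scale_region(region: ElementRegion, pixel: float, z_factor: float) -> ElementRegion:
    factors = np.array([pixel, pixel, pixel * z_factor])
    points = region.points * factors if region.points is not None else None
    center = axes = half = None
    if region.has_slab:
        # Anisotropic scaling keeps a box a box only when its axes are grid-aligned.
        if not np.allclose(np.abs(region.axes), np.eye(3), atol=1e-9):
            raise ValueError(
                f"cannot scale slab region {region.role}: axes are not grid-aligned"
            )
        center = region.center * factors
        axes = region.axes.copy()
        half = region.half_extents * np.abs(region.axes @ factors)
    return ElementRegion(
        role=region.role,
        kind=region.kind,
        points=points,
        delta_nm=region.delta_nm,
        center=center,
        axes=axes,
        half_extents=half,
    )


def apply_scaling(model: SCModel, scale: ScaleInfo) -> SCModel:
    """Convert a pixel-space model to nanometers.

    x and y are multiplied by the pixel size; z additionally by the z-scale
    factor compensating section thinning.
    """
    if model.units != "px":
        raise ValueError("model is already scaled to nm")
    pixel, zf = scale.pixel_size_nm, scale.z_factor
    factors = np.array([pixel, pixel, pixel * zf])
    tfs = [Polyline(tf.points * factors, tf.label) for tf in model.tfs]
    return SCModel(
        le_left=_scale_region(model.le_left, pixel, zf),
        le_right=_scale_region(model.le_right, pixel, zf),
        ce=_scale_region(model.ce, pixel, zf),
        tfs=tfs,
        scale=scale,
        units="nm",
        source=model.source,
    )


@dataclass(frozen=True)
class ModelIssue:
    kind: str
    message: str
    subject: str = ""


# Heuristic: a model claiming pixel units should not span more than ~10k px
# (a 4k camera reconstruction); larger extents suggest the flag is stale.
_PX_EXTENT_WARN = 1e4


def validate_model(model: SCModel) -> list[ModelIssue]:
    """Report (never raise) suspect content: degenerate TFs, thin elements,
    filaments that never leave their lateral element, stale unit flags."""
    issues: list[ModelIssue] = []
    for role, region in model.regions.items():
        if region.has_cloud and len(region.points) < 4:
            issues.append(ModelIssue("sparse_element", f"{role} has <4 points", role))
    all_points = [tf.points for tf in model.tfs]
    for i, tf in enumerate(model.tfs):
        if tf.is_degenerate:
            issues.append(ModelIssue("degenerate_tf", f"TF {i} is degenerate", tf.label))
    # suspect traces: filaments that cannot be oriented LE -> CE
    from .metrics import UNRESOLVED, assign_tf_sides

    for i, (tf, asg) in enumerate(zip(model.tfs, assign_tf_sides(model))):
        if tf.is_degenerate:
            continue
        if asg.side == UNRESOLVED:
            issues.append(
                ModelIssue(
                    "unresolved_side",
                    f"TF {i}: endpoints do not resolve to one LE and the CE",
                    tf.label,
                )
            )
    if model.units == "px" and all_points:
        extent = float(np.max(np.abs(np.vstack(all_points))))
        if extent > _PX_EXTENT_WARN:
            issues.append(
                ModelIssue(
                    "scale_warning",
                    f"units flagged px but coordinates reach {extent:.3g} px",
                )
            )
    return issues
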
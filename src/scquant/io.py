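"""Reading and writing annotated SC point models.

Two formats are supported:

* the 5-column ``model2point -object`` text dialect
  (``object contour x y z``, whitespace-delimited), with a JSON sidecar
  carrying calibration, object roles, units and (when present) exact slab
  element definitions that the plain point dialect cannot express;
* a self-contained native JSON model.

The point dialect is deliberately fixed to five columns: 3-column exports
lose the object/contour grouping and are rejected rather than guessed.
"""

from __future__ import annotations

import json
import os
from typing import Mapping

import numpy as np

from .model import (
    ELEMENT_ROLES,
    ROLE_CE,
    ROLE_LE_LEFT,
    ROLE_LE_RIGHT,
    ElementRegion,
    Polyline,
    SCModel,
    ScaleInfo,
)

TF_ROLE = "TF"

# Default object numbering used by write_point_model.
DEFAULT_OBJECT_ROLES = {1: ROLE_LE_LEFT, 2: ROLE_LE_RIGHT, 3: ROLE_CE, 4: TF_ROLE}


class PointFileError(ValueError):
    """Malformed point file (message carries the offending line number)."""


def sidecar_path(path: str | os.PathLike) -> str:
    return str(path) + ".json"


def read_point_model(
    path: str | os.PathLike,
    role_map: Mapping[int, str] | None = None,
) -> SCModel:
    """Parse a ``model2point -object`` file into an SCModel (units = px).

    ``role_map`` maps object indices to ``LE_left``/``LE_right``/``CE``/``TF``.
    When omitted, the sidecar written by :func:`write_point_model` is
    consulted; a file without either is ambiguous and rejected.
    """
    path = str(path)
    sidecar = _load_sidecar(path)
    if role_map is None:
        if sidecar is None or "roles" not in sidecar:
            raise ValueError(f"{path}: no role_map given and no sidecar with roles found")
        role_map = {int(k): v for k, v in sidecar["roles"].items()}

    rows: list[tuple[int, int, float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 5:
                raise PointFileError(
                    f"{path}:{lineno}: expected 5 columns 'object contour x y z', "
                    f"got {len(fields)}"
                )
            try:
                obj, contour = int(fields[0]), int(fields[1])
                x, y, z = (float(v) for v in fields[2:])
            except ValueError as exc:
                raise PointFileError(f"{path}:{lineno}: {exc}") from None
            rows.append((obj, contour, x, y, z))
    if not rows:
        raise PointFileError(f"{path}: empty point file")

    objects = sorted({r[0] for r in rows})
    missing = [o for o in objects if o not in role_map]
    if missing:
        raise KeyError(f"{path}: objects {missing} missing from role_map")

    element_points: dict[str, list[np.ndarray]] = {r: [] for r in ELEMENT_ROLES}
    tf_contours: dict[tuple[int, int], list[list[float]]] = {}
    for obj, contour, x, y, z in rows:
        role = role_map[obj]
        if role == TF_ROLE:
            tf_contours.setdefault((obj, contour), []).append([x, y, z])
        elif role in ELEMENT_ROLES:
            element_points[role].append(np.array([x, y, z]))
        else:
            raise KeyError(f"{path}: unknown role {role!r} for object {obj}")

    if not tf_contours:
        raise ValueError(f"{path}: no transverse-filament objects present")
    for role in ELEMENT_ROLES:
        if not element_points[role]:
            raise ValueError(f"{path}: element {role} has no points")

    delta = None
    scale = None
    units = "px"
    slabs: dict[str, dict] = {}
    if sidecar is not None:
        units = sidecar.get("units", "px")
        delta = sidecar.get("delta_nm")
        if "scale" in sidecar and sidecar["scale"] is not None:
            scale = ScaleInfo(**sidecar["scale"])
        slabs = sidecar.get("slabs", {})

    def region(role: str) -> ElementRegion:
        slab = slabs.get(role)
        kwargs = {}
        if slab is not None:
            kwargs = dict(
                center=np.asarray(slab["center"]),
                axes=np.asarray(slab["axes"]),
                half_extents=np.asarray(slab["half_extents"]),
            )
        return ElementRegion(
            role=role,
            kind="point_cloud",
            points=np.vstack(element_points[role]),
            delta_nm=delta,
            **kwargs,
        )

    tfs = [
        Polyline(np.asarray(pts), label=f"obj{obj}_contour{contour}")
        for (obj, contour), pts in sorted(tf_contours.items())
    ]
    return SCModel(
        le_left=region(ROLE_LE_LEFT),
        le_right=region(ROLE_LE_RIGHT),
        ce=region(ROLE_CE),
        tfs=tfs,
        scale=scale,
        units=units,
        source=path,
    )


def write_point_model(model: SCModel, path: str | os.PathLike) -> None:
    """Emit the 5-column point dialect plus a JSON sidecar.

    Elements become objects 1-3 (one contour each); TFs share object 4 with
    one contour per filament. Coordinates are written with full float
    precision so read(write(model)) is bit-identical.
    """
    if not model.tfs:
        raise ValueError("refusing to write a model without transverse filaments")
    for role, region in model.regions.items():
        if not region.has_cloud:
            raise ValueError(
                f"element {role} has no point cloud; the point dialect cannot "
                "express slab-only regions"
            )
    path = str(path)
    role_objects = {v: k for k, v in DEFAULT_OBJECT_ROLES.items()}
    lines: list[str] = []
    for role in ELEMENT_ROLES:
        obj = role_objects[role]
        for x, y, z in model.regions[role].points:
            lines.append(f"{obj} 1 {float(x)!r} {float(y)!r} {float(z)!r}")
    tf_obj = role_objects[TF_ROLE]
    for contour, tf in enumerate(model.tfs, start=1):
        for x, y, z in tf.points:
            lines.append(f"{tf_obj} {contour} {float(x)!r} {float(y)!r} {float(z)!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    sidecar = {
        "units": model.units,
        "roles": {str(k): v for k, v in DEFAULT_OBJECT_ROLES.items()},
        "delta_nm": model.le_left.delta_nm,
        "scale": _scale_dict(model.scale),
        "slabs": {
            role: _slab_dict(region)
            for role, region in model.regions.items()
            if region.has_slab
        },
        "tf_labels": [tf.label for tf in model.tfs],
    }
    with open(sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def write_json_model(model: SCModel, path: str | os.PathLike) -> None:
    """Write the self-contained native JSON model."""
    payload = {
        "format": "scquant-model",
        "version": 1,
        "units": model.units,
        "source": model.source,
        "scale": _scale_dict(model.scale),
        "elements": {
            role: {
                "kind": region.kind,
                "points": None if region.points is None else region.points.tolist(),
                "delta_nm": region.delta_nm,
                "slab": _slab_dict(region) if region.has_slab else None,
            }
            for role, region in model.regions.items()
        },
        "tfs": [{"label": tf.label, "points": tf.points.tolist()} for tf in model.tfs],
    }
    with open(str(path), "w") as fh:
        json.dump(payload, fh)


def read_json_model(path: str | os.PathLike) -> SCModel:
    with open(str(path)) as fh:
        payload = json.load(fh)
    if payload.get("format") != "scquant-model":
        raise ValueError(f"{path}: not a native scquant model file")

    def region(role: str) -> ElementRegion:
        entry = payload["elements"][role]
        slab = entry.get("slab")
        kwargs = {}
        if slab is not None:
            kwargs = dict(
                center=np.asarray(slab["center"]),
                axes=np.asarray(slab["axes"]),
                half_extents=np.asarray(slab["half_extents"]),
            )
        points = entry.get("points")
        return ElementRegion(
            role=role,
            kind=entry["kind"],
            points=None if points is None else np.asarray(points),
            delta_nm=entry.get("delta_nm"),
            **kwargs,
        )

    scale = ScaleInfo(**payload["scale"]) if payload.get("scale") else None
    tfs = [Polyline(np.asarray(t["points"]), t.get("label", "")) for t in payload["tfs"]]
    return SCModel(
        le_left=region(ROLE_LE_LEFT),
        le_right=region(ROLE_LE_RIGHT),
        ce=region(ROLE_CE),
        tfs=tfs,
        scale=scale,
        units=payload.get("units", "nm"),
        source=payload.get("source", str(path)),
    )


def _scale_dict(scale: ScaleInfo | None) -> dict | None:
    if scale is None:
        return None
    return {
        "pixel_size_nm": scale.pixel_size_nm,
        "section_thickness_nm": scale.section_thickness_nm,
        "z_extent_px": scale.z_extent_px,
        "z_factor": scale.z_factor,
    }


def _slab_dict(region: ElementRegion) -> dict:
    return {
        "center": region.center.tolist(),
        "axes": region.axes.tolist(),
        "half_extents": region.half_extents.tolist(),
    }


def _load_sidecar(path: str) -> dict | None:
    sc = sidecar_path(path)
    if os.path.exists(sc):
        with open(sc) as fh:
            return json.load(fh)
    return None
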
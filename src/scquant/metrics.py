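"""Per-tomogram SC measurements.

Implements the measurement chain applied to each annotated tomogram:

1. assign every transverse filament (TF) to its nearest lateral element
   (side + orientation),
2. intersect each TF with its own-side LE and with the CE to split it into
   LE-indent, central-region midsection and CE-indent segments,
3. nearest-neighbor width samples (CR width, LE–CE distance, CE width) from
   the intersection points,
4. nearest-neighbor spacing of TF endpoints in the CE (parallel vs opposite
   side) and in the LEs,
5. pairing classification (opposite / parallel / single),
6. side asymmetry and TF densities per µm and µm² via 2D projection and a
   fitted bounding rectangle,
7. per-tomogram and cohort-pooled summaries (cohort pooling concatenates the
   underlying samples — all tomograms are treated as one data set).

All distances are nanometers; densities are per µm / µm².
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import (
    DegenerateFitError,
    PlaneFit,
    RectFit,
    bounding_rectangle,
    fit_plane,
    group_nearest_neighbors,
    point_region_distance,
    polyline_region_intersection,
    project_to_plane,
)
from .model import ROLE_CE, ROLE_LE_LEFT, ROLE_LE_RIGHT, Polyline, SCModel

log = logging.getLogger(__name__)

SIDE_LEFT = "left"
SIDE_RIGHT = "right"
UNRESOLVED = "unresolved"

PAIRING_PARALLEL = "parallel"
PAIRING_OPPOSITE = "opposite"
PAIRING_SINGLE = "single"


@dataclass
class QuantConfig:
    """Measurement constants.

    delta_nm: membership radius around element point clouds (ignored for
        slab elements, whose boundary is exact).
    pairing_threshold_nm: CE-endpoint NN distance below which two TFs count
        as a pair; sits below both reported CE NN means so only markedly
        close neighbors pair up.
    """

    delta_nm: float = 4.0
    pairing_threshold_nm: float = 15.0
    density_site: str = "CE"  # "CE" | "LE_left" | "LE_right"
    min_tf_points: int = 2

    def __post_init__(self) -> None:
        if self.delta_nm <= 0 or self.pairing_threshold_nm <= 0:
            raise ValueError("delta_nm and pairing_threshold_nm must be > 0")
        if self.min_tf_points < 2:
            raise ValueError("min_tf_points must be >= 2")


@dataclass
class SideAssignment:
    side: str  # left / right / unresolved
    le_end_first: bool = True  # is points[0] the LE-end?


@dataclass
class TFMetrics:
    """One filament's measured record (lengths in nm; nan = not measurable)."""

    tf_id: int
    side: str
    endpoint_le: np.ndarray | None
    endpoint_ce: np.ndarray | None
    x_le: np.ndarray | None = None
    x_ce: np.ndarray | None = None
    len_total_nm: float = math.nan
    len_le_indent_nm: float = math.nan
    len_ce_indent_nm: float = math.nan
    len_midsection_nm: float = math.nan
    nn_parallel_nm: float = math.nan
    nn_opposite_nm: float = math.nan
    nn_le_nm: float = math.nan
    pairing: str = UNRESOLVED


def _endpoint_element(point, model: SCModel) -> tuple[str, float]:
    """Nearest element ('left'/'right'/'ce') and the distance to it."""
    dists = {
        SIDE_LEFT: point_region_distance(point, model.le_left),
        SIDE_RIGHT: point_region_distance(point, model.le_right),
        "ce": point_region_distance(point, model.ce),
    }
    element = min(dists, key=dists.get)
    return element, dists[element]


def assign_tf_sides(model: SCModel, config: QuantConfig | None = None) -> list[SideAssignment]:
    """Assign each TF to the closest LE and decide which end is the LE-end.

    The LE-end is the endpoint whose nearest element is a lateral element
    (the CE competes: a filament's CE-end always lies closer to its own-side
    LE than to the opposite LE, so a two-LE comparison alone is ambiguous).
    A filament whose endpoints both resolve to the same LE, or to no LE at
    all, is labeled unresolved, excluded from side-specific statistics and
    reported.
    """
    config = config or QuantConfig()
    out: list[SideAssignment] = []
    for tf in model.tfs:
        if tf.is_degenerate or len(tf.points) < config.min_tf_points:
            out.append(SideAssignment(UNRESOLVED))
            continue
        (el0, d0), (el1, d1) = (
            _endpoint_element(tf.points[0], model),
            _endpoint_element(tf.points[-1], model),
        )
        le0, le1 = el0 != "ce", el1 != "ce"
        if le0 and le1 and el0 == el1:  # suspect: never leaves one LE's vicinity
            out.append(SideAssignment(UNRESOLVED))
        elif le0 and le1:  # spans LE to LE: orient by the deeper-embedded end
            first = d0 <= d1
            out.append(SideAssignment(el0 if first else el1, le_end_first=first))
        elif le0:
            out.append(SideAssignment(el0, le_end_first=True))
        elif le1:
            out.append(SideAssignment(el1, le_end_first=False))
        else:
            out.append(SideAssignment(UNRESOLVED))
    return out


def compute_tf_metrics(
    model: SCModel,
    config: QuantConfig | None = None,
    assignments: Sequence[SideAssignment] | None = None,
) -> list[TFMetrics]:
    """Intersect every sided TF with its LE and the CE and measure the
    total / LE-indent / midsection / CE-indent lengths.

    A missing intersection leaves the affected fields nan; the filament is
    then excluded from the affected summary only.
    """
    config = config or QuantConfig()
    if model.units != "nm":
        raise ValueError("metrics require a scaled (nm) model")
    assignments = assignments or assign_tf_sides(model, config)
    le_regions = {SIDE_LEFT: model.le_left, SIDE_RIGHT: model.le_right}
    records: list[TFMetrics] = []
    for i, (tf, asg) in enumerate(zip(model.tfs, assignments)):
        if asg.side == UNRESOLVED:
            rec = TFMetrics(i, UNRESOLVED, None, None)
            if not tf.is_degenerate:
                rec.len_total_nm = float(np.linalg.norm(tf.points[-1] - tf.points[0]))
            records.append(rec)
            continue
        oriented = tf if asg.le_end_first else tf.reversed()
        e_le, e_ce = oriented.points[0], oriented.points[-1]
        rec = TFMetrics(i, asg.side, e_le, e_ce)
        rec.len_total_nm = float(np.linalg.norm(e_ce - e_le))
        hit_le = polyline_region_intersection(
            oriented, le_regions[asg.side], config.delta_nm, from_end="first"
        )
        hit_ce = polyline_region_intersection(
            oriented, model.ce, config.delta_nm, from_end="last"
        )
        if hit_le is not None and not hit_le.interior:
            rec.x_le = hit_le.point
            rec.len_le_indent_nm = float(np.linalg.norm(e_le - hit_le.point))
        if hit_ce is not None and not hit_ce.interior:
            rec.x_ce = hit_ce.point
            rec.len_ce_indent_nm = float(np.linalg.norm(e_ce - hit_ce.point))
        if rec.x_le is not None and rec.x_ce is not None:
            rec.len_midsection_nm = float(np.linalg.norm(rec.x_le - rec.x_ce))
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# widths


@dataclass
class WidthSamples:
    """Per-intersection-point width samples (nm)."""

    cr_width: np.ndarray
    le_ce: np.ndarray
    ce_width: np.ndarray


def width_samples_from_points(
    xle_left: np.ndarray,
    xle_right: np.ndarray,
    xce_left: np.ndarray,
    xce_right: np.ndarray,
) -> WidthSamples:
    """Width samples from LE / CE intersection point sets.

    CR width: per LE intersection point, NN distance to the opposing LE's
    intersection points (both sides contribute samples). LE–CE: per LE
    intersection, NN distance to same-side CE intersections. CE width: per
    CE intersection, NN distance to opposite-side CE intersections.
    """

    def nn(queries, cands):
        if len(queries) == 0 or len(cands) == 0:
            return np.empty(0)
        return group_nearest_neighbors(np.asarray(queries), np.asarray(cands))

    cr = np.concatenate([nn(xle_left, xle_right), nn(xle_right, xle_left)])
    le_ce = np.concatenate([nn(xle_left, xce_left), nn(xle_right, xce_right)])
    ce = np.concatenate([nn(xce_left, xce_right), nn(xce_right, xce_left)])
    return WidthSamples(cr, le_ce, ce)


def _points_by_side(tf_metrics: Sequence[TFMetrics], attr: str) -> dict[str, np.ndarray]:
    out = {}
    for side in (SIDE_LEFT, SIDE_RIGHT):
        pts = [
            getattr(m, attr)
            for m in tf_metrics
            if m.side == side and getattr(m, attr) is not None
        ]
        out[side] = np.asarray(pts) if pts else np.empty((0, 3))
    return out


def compute_region_widths(tf_metrics: Sequence[TFMetrics]) -> WidthSamples:
    xle = _points_by_side(tf_metrics, "x_le")
    xce = _points_by_side(tf_metrics, "x_ce")
    return width_samples_from_points(
        xle[SIDE_LEFT], xle[SIDE_RIGHT], xce[SIDE_LEFT], xce[SIDE_RIGHT]
    )


# ---------------------------------------------------------------------------
# nearest neighbors at the CE and in the LEs


def compute_ce_nn(tf_metrics: Sequence[TFMetrics]) -> None:
    """Fill nn_parallel_nm / nn_opposite_nm from CE-endpoint distances.

    For each filament's CE endpoint: minimum distance to same-side CE
    endpoints (excluding itself) and to opposite-side CE endpoints.
    """
    groups = {
        side: [m for m in tf_metrics if m.side == side and m.endpoint_ce is not None]
        for side in (SIDE_LEFT, SIDE_RIGHT)
    }
    pts = {side: np.asarray([m.endpoint_ce for m in ms]) if ms else np.empty((0, 3))
           for side, ms in groups.items()}
    for side, other in ((SIDE_LEFT, SIDE_RIGHT), (SIDE_RIGHT, SIDE_LEFT)):
        ms = groups[side]
        if not ms:
            continue
        own = pts[side]
        par = group_nearest_neighbors(own, own, exclude_self=True)
        opp = group_nearest_neighbors(own, pts[other])
        for m, dp, do in zip(ms, par, opp):
            m.nn_parallel_nm = float(dp)
            m.nn_opposite_nm = float(do)


def compute_le_nn(tf_metrics: Sequence[TFMetrics]) -> None:
    """Fill nn_le_nm: per LE endpoint, minimum distance to other endpoints
    embedded in the same LE."""
    for side in (SIDE_LEFT, SIDE_RIGHT):
        ms = [m for m in tf_metrics if m.side == side and m.endpoint_le is not None]
        if not ms:
            continue
        own = np.asarray([m.endpoint_le for m in ms])
        nn = group_nearest_neighbors(own, own, exclude_self=True)
        for m, d in zip(ms, nn):
            m.nn_le_nm = float(d)


def classify_pairings(
    tf_metrics: Sequence[TFMetrics], threshold_nm: float = 15.0
) -> dict[str, float]:
    """Label each filament opposite / parallel / single from its CE NN
    distances (opposite takes precedence) and return class proportions."""
    counts = {PAIRING_OPPOSITE: 0, PAIRING_PARALLEL: 0, PAIRING_SINGLE: 0}
    for m in tf_metrics:
        if m.side == UNRESOLVED or m.endpoint_ce is None:
            m.pairing = UNRESOLVED
            continue
        if not math.isnan(m.nn_opposite_nm) and m.nn_opposite_nm <= threshold_nm:
            m.pairing = PAIRING_OPPOSITE
        elif not math.isnan(m.nn_parallel_nm) and m.nn_parallel_nm <= threshold_nm:
            m.pairing = PAIRING_PARALLEL
        else:
            m.pairing = PAIRING_SINGLE
        counts[m.pairing] += 1
    total = sum(counts.values())
    if total == 0:
        return {k: math.nan for k in counts}
    return {k: v / total for k, v in counts.items()}


def compute_asymmetry(n_left: int, n_right: int) -> float:
    """Percent difference in per-side TF counts relative to the larger side."""
    if n_left <= 0 or n_right <= 0:
        return math.nan
    return 100.0 * abs(n_left - n_right) / max(n_left, n_right)


# ---------------------------------------------------------------------------
# density


@dataclass
class DensityResult:
    tfs_per_um: float
    tfs_per_um2: float
    rect: RectFit | None
    plane: PlaneFit | None
    n_site_points: int


def compute_density(
    tf_metrics: Sequence[TFMetrics],
    site: str = "CE",
    n_tfs: int | None = None,
) -> DensityResult:
    """TF density along (per µm) and across (per µm²) the SC.

    Site points — CE intersection points, or one side's LE endpoints — are
    projected onto their best-fit plane; a rectangle fitted to the per-axis
    extrema gives the SC length and area occupied by TFs.
    """
    if site == "CE":
        pts = [m.x_ce for m in tf_metrics if m.x_ce is not None]
    elif site in (ROLE_LE_LEFT, ROLE_LE_RIGHT):
        side = SIDE_LEFT if site == ROLE_LE_LEFT else SIDE_RIGHT
        pts = [m.endpoint_le for m in tf_metrics if m.side == side and m.endpoint_le is not None]
    else:
        raise ValueError(f"unknown density site {site!r}")
    n_tfs = len(tf_metrics) if n_tfs is None else n_tfs
    if len(pts) < 3:
        log.info("density undefined: only %d site points", len(pts))
        return DensityResult(math.nan, math.nan, None, None, len(pts))
    pts = np.asarray(pts)
    try:
        plane = fit_plane(pts)
        rect = bounding_rectangle(project_to_plane(pts, plane))
    except DegenerateFitError as exc:
        log.info("density undefined: %s", exc)
        return DensityResult(math.nan, math.nan, None, None, len(pts))
    length_um = rect.length_nm / 1000.0
    area_um2 = rect.area_nm2 / 1e6
    per_um = n_tfs / length_um if length_um > 0 else math.nan
    per_um2 = len(pts) / area_um2 if area_um2 > 0 else math.nan
    return DensityResult(per_um, per_um2, rect, plane, len(pts))


# ---------------------------------------------------------------------------
# summaries


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return math.nan, math.nan
    if len(v) == 1:
        return float(v[0]), math.nan
    return float(v.mean()), float(v.std(ddof=1))  # sample sd: small per-tomogram n


@dataclass
class SummaryMetrics:
    """Per-tomogram (or cohort-pooled) aggregate measurements."""

    cr_width_mean: float = math.nan
    cr_width_sd: float = math.nan
    le_ce_mean: float = math.nan
    le_ce_sd: float = math.nan
    ce_width_mean: float = math.nan
    ce_width_sd: float = math.nan
    tf_len_mean: float = math.nan
    tf_len_sd: float = math.nan
    le_indent_mean: float = math.nan
    le_indent_sd: float = math.nan
    ce_indent_mean: float = math.nan
    ce_indent_sd: float = math.nan
    midsection_mean: float = math.nan
    midsection_sd: float = math.nan
    nn_opposite_mean: float = math.nan
    nn_opposite_sd: float = math.nan
    nn_parallel_mean: float = math.nan
    nn_parallel_sd: float = math.nan
    nn_le_mean: float = math.nan
    nn_le_sd: float = math.nan
    tfs_per_um: float = math.nan
    tfs_per_um_sd: float = math.nan
    tfs_per_um2: float = math.nan
    tfs_per_um2_sd: float = math.nan
    asymmetry_pct: float = math.nan
    n_tfs: int = 0
    n_left: int = 0
    n_right: int = 0
    n_unresolved: int = 0
    prop_parallel: float = math.nan
    prop_opposite: float = math.nan
    prop_single: float = math.nan

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class TomogramResult:
    """Full measurement output for one tomogram."""

    tf_metrics: list[TFMetrics]
    widths: WidthSamples
    density: DensityResult
    summary: SummaryMetrics
    pairing_proportions: dict[str, float] = field(default_factory=dict)
    source: str = ""

    @property
    def n_left(self) -> int:
        return sum(1 for m in self.tf_metrics if m.side == SIDE_LEFT)

    @property
    def n_right(self) -> int:
        return sum(1 for m in self.tf_metrics if m.side == SIDE_RIGHT)


def _samples(tf_metrics: Sequence[TFMetrics], attr: str, resolved_only: bool = True) -> np.ndarray:
    vals = [
        getattr(m, attr)
        for m in tf_metrics
        if not (resolved_only and m.side == UNRESOLVED)
    ]
    return np.asarray(vals, dtype=float)


def _build_summary(
    tf_metrics: Sequence[TFMetrics],
    widths: WidthSamples,
    per_um_values: np.ndarray,
    per_um2_values: np.ndarray,
    proportions: dict[str, float],
    asymmetry: float,
) -> SummaryMetrics:
    s = SummaryMetrics()
    for attr, prefix in (
        ("len_total_nm", "tf_len"),
        ("len_le_indent_nm", "le_indent"),
        ("len_ce_indent_nm", "ce_indent"),
        ("len_midsection_nm", "midsection"),
        ("nn_opposite_nm", "nn_opposite"),
        ("nn_parallel_nm", "nn_parallel"),
        ("nn_le_nm", "nn_le"),
    ):
        mean, sd = _mean_sd(_samples(tf_metrics, attr))
        setattr(s, f"{prefix}_mean", mean)
        setattr(s, f"{prefix}_sd", sd)
    for arr, prefix in (
        (widths.cr_width, "cr_width"),
        (widths.le_ce, "le_ce"),
        (widths.ce_width, "ce_width"),
    ):
        mean, sd = _mean_sd(arr)
        setattr(s, f"{prefix}_mean", mean)
        setattr(s, f"{prefix}_sd", sd)
    s.tfs_per_um, s.tfs_per_um_sd = _mean_sd(per_um_values)
    s.tfs_per_um2, s.tfs_per_um2_sd = _mean_sd(per_um2_values)
    s.asymmetry_pct = asymmetry
    s.n_tfs = len(tf_metrics)
    s.n_left = sum(1 for m in tf_metrics if m.side == SIDE_LEFT)
    s.n_right = sum(1 for m in tf_metrics if m.side == SIDE_RIGHT)
    s.n_unresolved = sum(1 for m in tf_metrics if m.side == UNRESOLVED)
    s.prop_parallel = proportions.get(PAIRING_PARALLEL, math.nan)
    s.prop_opposite = proportions.get(PAIRING_OPPOSITE, math.nan)
    s.prop_single = proportions.get(PAIRING_SINGLE, math.nan)
    return s


def quantify_model(model: SCModel, config: QuantConfig | None = None) -> TomogramResult:
    """Run the full per-tomogram measurement chain."""
    config = config or QuantConfig()
    tfm = compute_tf_metrics(model, config)
    widths = compute_region_widths(tfm)
    compute_ce_nn(tfm)
    compute_le_nn(tfm)
    proportions = classify_pairings(tfm, config.pairing_threshold_nm)
    density = compute_density(tfm, config.density_site)
    n_left = sum(1 for m in tfm if m.side == SIDE_LEFT)
    n_right = sum(1 for m in tfm if m.side == SIDE_RIGHT)
    n_missing = sum(1 for m in tfm if m.side != UNRESOLVED and m.x_le is None)
    if n_missing:
        log.info(
            "%s: %d/%d TFs lack an LE intersection and are excluded from indent stats",
            model.source, n_missing, len(tfm),
        )
    summary = _build_summary(
        tfm,
        widths,
        np.array([density.tfs_per_um]),
        np.array([density.tfs_per_um2]),
        proportions,
        compute_asymmetry(n_left, n_right),
    )
    return TomogramResult(
        tf_metrics=tfm,
        widths=widths,
        density=density,
        summary=summary,
        pairing_proportions=proportions,
        source=model.source,
    )


def summarize(results: Sequence[TomogramResult]) -> SummaryMetrics:
    """Cohort-pooled summary: all per-TF and per-point samples concatenated
    into one data set; densities and asymmetry summarized across tomograms."""
    if not results:
        raise ValueError("no tomogram results to summarize")
    all_tfm = [m for r in results for m in r.tf_metrics]
    widths = WidthSamples(
        cr_width=np.concatenate([r.widths.cr_width for r in results]),
        le_ce=np.concatenate([r.widths.le_ce for r in results]),
        ce_width=np.concatenate([r.widths.ce_width for r in results]),
    )
    per_um = np.array([r.density.tfs_per_um for r in results])
    per_um2 = np.array([r.density.tfs_per_um2 for r in results])
    classified = [m for m in all_tfm if m.pairing != UNRESOLVED]
    proportions = {}
    if classified:
        for cls in (PAIRING_PARALLEL, PAIRING_OPPOSITE, PAIRING_SINGLE):
            proportions[cls] = sum(1 for m in classified if m.pairing == cls) / len(classified)
    asym = np.array([r.summary.asymmetry_pct for r in results], dtype=float)
    asym = float(np.nanmean(asym)) if np.isfinite(asym).any() else math.nan
    return _build_summary(all_tfm, widths, per_um, per_um2, proportions, asym)


def metrics_dataframe(tf_metrics: Sequence[TFMetrics]) -> pd.DataFrame:
    """Per-TF table (one row per filament) for CSV export."""
    rows = []
    for m in tf_metrics:
        row = {"tf_id": m.tf_id, "side": m.side, "pairing": m.pairing}
        for name, pt in (
            ("endpoint_le", m.endpoint_le),
            ("endpoint_ce", m.endpoint_ce),
            ("x_le", m.x_le),
            ("x_ce", m.x_ce),
        ):
            for i, ax in enumerate("xyz"):
                row[f"{name}_{ax}"] = math.nan if pt is None else float(pt[i])
        for name in (
            "len_total_nm", "len_le_indent_nm", "len_ce_indent_nm", "len_midsection_nm",
            "nn_parallel_nm", "nn_opposite_nm", "nn_le_nm",
        ):
            row[name] = getattr(m, name)
        rows.append(row)
    return pd.DataFrame(rows)
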
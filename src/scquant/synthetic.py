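"""Synthetic SC generator with known ground truth.

Emulates the measured geometry of pachytene mouse SC tomograms: two lateral
element (LE) slabs flanking a central region of ~114 nm, a ~29 nm central
element (CE) at the midline, and straight transverse filaments (TFs) of
~88 nm total length whose midsection chord spans the LE→CE gap obliquely
(the printed midsection mean exceeds the flat LE–CE gap, so filaments must
tilt: obliquity angle = arccos(gap / midsection)). TFs are planted in
pairing classes (opposite / parallel / single), optionally with a per-side
count asymmetry, in a single layer or an artificial bilayer, and optionally
on a sinusoidally curved SC course.

Every model is returned together with a :class:`GroundTruth` holding the
pre-jitter per-filament truths and the realized aggregates each downstream
estimator targets.

Length draws use *symmetric* two-sided truncation about the configured mean
(floor 1 nm; midsections floored at the LE→CE gap), so configured means are
preserved exactly in expectation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .model import (
    ROLE_CE,
    ROLE_LE_LEFT,
    ROLE_LE_RIGHT,
    ElementRegion,
    Polyline,
    SCModel,
    ScaleInfo,
)

_SEED_MOD = 2**31


@dataclass
class GeneratorConfig:
    """Geometry and sampling parameters of the synthetic SC.

    Defaults reproduce the measured cohort geometry: central-region width
    114 ± 17 nm, CE width 29 nm, TF length 88 ± 14 nm, LE/CE indents
    21 ± 9 / 14 ± 7 nm, 79 TFs/µm in total over both sides.
    """

    sc_length_nm: float = 2000.0
    course_amplitude_nm: float = 0.0
    course_period_nm: float = 1000.0
    cr_width_mean_nm: float = 114.0
    cr_width_sd_nm: float = 17.0
    ce_width_nm: float = 29.0
    le_thickness_nm: float = 40.0
    tf_per_um_total: float = 79.0
    asymmetry_fraction: float = 0.0  # up to 0.21 observed
    tf_total_len_mean_nm: float = 88.0
    tf_total_len_sd_nm: float = 14.0
    le_indent_mean_nm: float = 21.0
    le_indent_sd_nm: float = 9.0
    ce_indent_mean_nm: float = 14.0
    ce_indent_sd_nm: float = 7.0
    pairing_weights: tuple[float, float, float] = (0.25, 0.5, 0.25)  # parallel, opposite, single
    layer_mode: str = "single"  # "single" | "bilayer"
    bilayer_gap_nm: float = 30.0
    endpoint_jitter_sd_nm: float = 2.0
    points_per_tf: int = 5
    element_cloud_spacing_nm: float = 3.0
    cloud_margin_nm: float = 4.0  # erosion of cloud volumes; = default membership delta
    tilt_azimuth_sd_deg: float = 35.0  # out-of-longitudinal spread of the tilt direction
    pair_offset_nm: float = 5.0  # max in-CE-plane separation within a planted pair
    opposite_max_depth_gap_nm: float = 10.0  # max cross-CE depth gap within an opposite pair
    single_exclusion_nm: float = 25.0  # intended clearance around planted singles
    build_point_clouds: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "sc_length_nm", "course_period_nm", "cr_width_mean_nm", "ce_width_nm",
            "le_thickness_nm", "tf_per_um_total", "tf_total_len_mean_nm",
            "le_indent_mean_nm", "ce_indent_mean_nm", "bilayer_gap_nm",
            "element_cloud_spacing_nm", "cloud_margin_nm",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.asymmetry_fraction < 1.0):
            raise ValueError("asymmetry_fraction must be in [0, 1)")
        w = np.asarray(self.pairing_weights, dtype=float)
        if len(w) != 3 or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("pairing_weights must be 3 non-negative values with sum > 0")
        if self.layer_mode not in ("single", "bilayer"):
            raise ValueError("layer_mode must be 'single' or 'bilayer'")
        if self.points_per_tf < 2:
            raise ValueError("points_per_tf must be >= 2")
        if self.midsection_mean_nm < self.nominal_gap_nm:
            raise ValueError(
                "infeasible geometry: implied midsection mean "
                f"{self.midsection_mean_nm:.1f} nm is shorter than the LE-CE gap "
                f"{self.nominal_gap_nm:.1f} nm it must span"
            )

    @property
    def midsection_mean_nm(self) -> float:
        return self.tf_total_len_mean_nm - self.le_indent_mean_nm - self.ce_indent_mean_nm

    @property
    def midsection_sd_nm(self) -> float:
        var = (
            self.tf_total_len_sd_nm**2
            - self.le_indent_sd_nm**2
            - self.ce_indent_sd_nm**2
        )
        return math.sqrt(max(var, 0.0))

    @property
    def nominal_gap_nm(self) -> float:
        """Flat-geometry LE inner face to CE face distance."""
        return (self.cr_width_mean_nm - self.ce_width_nm) / 2.0


def zero_noise_config(**overrides) -> GeneratorConfig:
    """Config with every noise source off and perpendicular filaments.

    All sds, jitter and pair offsets are zero, pairing is all-opposite with
    aligned partners, and the TF total length is set so the midsection
    exactly equals the LE→CE gap (no obliquity). Every width and length
    estimator then recovers its configured value exactly.
    """
    base = dict(
        cr_width_sd_nm=0.0,
        tf_total_len_sd_nm=0.0,
        le_indent_sd_nm=0.0,
        ce_indent_sd_nm=0.0,
        endpoint_jitter_sd_nm=0.0,
        tilt_azimuth_sd_deg=0.0,
        pair_offset_nm=0.0,
        asymmetry_fraction=0.0,
        course_amplitude_nm=0.0,
        pairing_weights=(0.0, 1.0, 0.0),
    )
    base.update(overrides)
    cfg = GeneratorConfig(**base)
    if "tf_total_len_mean_nm" not in overrides:
        cfg = replace(
            cfg,
            tf_total_len_mean_nm=cfg.nominal_gap_nm
            + cfg.le_indent_mean_nm
            + cfg.ce_indent_mean_nm,
        )
    return cfg


@dataclass
class TFTruth:
    """Pre-jitter truth for one planted filament."""

    tf_id: int
    side: str  # "left" | "right"
    pairing: str  # "parallel" | "opposite" | "single"
    layer: int
    anchor: int
    endpoint_le: np.ndarray
    endpoint_ce: np.ndarray
    x_le: np.ndarray
    x_ce: np.ndarray
    len_total_nm: float
    len_le_indent_nm: float
    len_ce_indent_nm: float
    len_midsection_nm: float


@dataclass
class GroundTruth:
    """Realized truths of one synthetic tomogram.

    ``aggregates`` holds, for every downstream estimator, the value of that
    estimator's functional evaluated on the noise-free geometry (true
    intersection points and endpoints); ``cr_width_nm`` etc. are the
    realized flat-geometry widths themselves.
    """

    seed: int
    config: GeneratorConfig
    tfs: list[TFTruth]
    cr_width_nm: float
    ce_width_nm: float
    le_ce_nm: float
    n_left: int
    n_right: int
    aggregates: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_tfs(self) -> int:
        return len(self.tfs)

    def sides(self) -> list[str]:
        return [t.side for t in self.tfs]

    def pairings(self) -> list[str]:
        return [t.pairing for t in self.tfs]

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "config": asdict(self.config),
            "cr_width_nm": self.cr_width_nm,
            "ce_width_nm": self.ce_width_nm,
            "le_ce_nm": self.le_ce_nm,
            "n_left": self.n_left,
            "n_right": self.n_right,
            "aggregates": self.aggregates,
            "warnings": self.warnings,
            "tfs": [
                {
                    **{k: v for k, v in asdict(t).items() if not isinstance(v, np.ndarray)},
                    **{
                        k: np.asarray(v).tolist()
                        for k, v in asdict(t).items()
                        if isinstance(v, np.ndarray)
                    },
                }
                for t in self.tfs
            ],
        }
        return d

    def to_json(self, path) -> None:
        with open(str(path), "w") as fh:
            json.dump(self.to_dict(), fh)


def _sym_trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, size: int | None = None
) -> np.ndarray | float:
    """Normal draw truncated symmetrically about the mean (window [lo, 2*mean-lo]),
    preserving the configured mean exactly in expectation."""
    hi = 2.0 * mean - lo
    if lo > mean + 1e-12:
        raise ValueError(f"truncation floor {lo} exceeds mean {mean}")
    n = 1 if size is None else size
    if sd == 0.0 or hi - lo < 1e-12:
        out = np.full(n, float(np.clip(mean, lo, hi)))
    else:
        out = np.empty(n)
        remaining = np.arange(n)
        while len(remaining):
            draw = rng.normal(mean, sd, size=len(remaining))
            ok = (draw >= lo) & (draw <= hi)
            out[remaining[ok]] = draw[ok]
            remaining = remaining[~ok]
    return float(out[0]) if size is None else out


def sample_nn_distances(
    mean: float, sd: float, n: int, rng: np.random.Generator | None = None, seed: int = 0
) -> np.ndarray:
    """Planted nearest-neighbor distance sample: truncated normal with a
    1 nm floor (symmetric truncation, so the planted mean is exact)."""
    rng = np.random.default_rng(seed) if rng is None else rng
    return np.asarray(_sym_trunc_normal(rng, mean, sd, 1.0, size=n))


# ---------------------------------------------------------------------------
# generation


def _plan_anchors(
    rng: np.random.Generator, cfg: GeneratorConfig, notes: list[str]
) -> tuple[int, int, list[tuple[str, str]]]:
    """Decide per-side counts and the pairing-class plan.

    Returns (n_left, n_right, anchor plan); each anchor is (class, side)
    with side '' for opposite pairs (they occupy both sides).
    """
    rate = cfg.tf_per_um_total * cfg.sc_length_nm / 1000.0
    n_total = max(1, int(rng.poisson(rate)))
    big = int(rng.integers(2))  # 0 -> left larger
    n_big = int(round(n_total / (2.0 - cfg.asymmetry_fraction)))
    n_big = min(max(n_big, 1), n_total)
    n_small = n_total - n_big
    n_left, n_right = (n_big, n_small) if big == 0 else (n_small, n_big)

    w = np.asarray(cfg.pairing_weights, dtype=float)
    wp, wo, ws = w / w.sum()
    if ws == 0 and wp == 0:
        # pure opposite pairing admits only equal even side counts
        k = min(n_left, n_right)
        if (n_left, n_right) != (k, k):
            notes.append(
                f"pure-opposite pairing: side counts adjusted {n_left}/{n_right} -> {k}/{k}"
            )
        n_left = n_right = max(k, 1)
    n_total = n_left + n_right
    k_o = int(round(wo * n_total / 2.0))
    k_o = min(k_o, n_left, n_right)
    plan: list[tuple[str, str]] = [("opposite", "")] * k_o
    for side, n_side in (("left", n_left), ("right", n_right)):
        rem = max(n_side - k_o, 0)
        if wp + ws > 0:
            k_p = int(round(wp / (wp + ws) * rem / 2.0))
        else:
            k_p = rem // 2
        k_p = min(k_p, rem // 2)
        n_single = rem - 2 * k_p
        if ws == 0 and n_single > 0 and k_p > 0:
            # pure pairing weights: absorb the leftover into one fewer pair
            notes.append(
                f"pairing quota unsatisfiable on side {side}: "
                f"{n_single} leftover filament(s) planted as singles"
            )
        plan.extend([("parallel", side)] * k_p)
        plan.extend([("single", side)] * n_single)
    if not plan:
        plan = [("single", "left")]
        n_left, n_right = 1, 0
    cell = cfg.sc_length_nm / max(len(plan), 1)
    if cell < 15.0:
        notes.append(
            f"anchor spacing {cell:.1f} nm is tight; pairing classes may overlap"
        )
    return n_left, n_right, plan


def generate_sc(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[SCModel, GroundTruth]:
    """Generate one synthetic SC model (units = nm) plus its ground truth."""
    cfg = config or GeneratorConfig()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    notes: list[str] = []

    # per-tomogram flat geometry; the CR draw is truncated so that the
    # implied LE-CE gap stays spannable by the configured midsection
    m_mean, m_sd = cfg.midsection_mean_nm, cfg.midsection_sd_nm
    gap_cap = 2.0 * (m_mean - 0.25) + cfg.ce_width_nm  # cr value where gap hits m_mean
    half_window = min(gap_cap - cfg.cr_width_mean_nm, cfg.cr_width_mean_nm - (cfg.ce_width_nm + 2.0))
    half_window = max(half_window, 0.0)
    cr_width = _sym_trunc_normal(
        rng, cfg.cr_width_mean_nm, cfg.cr_width_sd_nm, cfg.cr_width_mean_nm - half_window
    )
    ce_half = cfg.ce_width_nm / 2.0
    gap = (cr_width - cfg.ce_width_nm) / 2.0

    n_left, n_right, plan = _plan_anchors(rng, cfg, notes)
    plan = [plan[i] for i in rng.permutation(len(plan))]
    n_anchors = len(plan)
    cell = cfg.sc_length_nm / n_anchors
    anchor_x = (np.arange(n_anchors) + rng.uniform(0.4, 0.6, size=n_anchors)) * cell
    if cfg.layer_mode == "bilayer":
        layer_ids = rng.integers(0, 2, size=n_anchors)
        anchor_z = (2.0 * layer_ids - 1.0) * cfg.bilayer_gap_nm / 2.0
    else:
        layer_ids = np.zeros(n_anchors, dtype=int)
        anchor_z = np.zeros(n_anchors)

    az_sd = math.radians(cfg.tilt_azimuth_sd_deg)
    truths: list[TFTruth] = []
    polylines: list[Polyline] = []

    def shear(x: float) -> float:
        if cfg.course_amplitude_nm == 0.0:
            return 0.0
        return cfg.course_amplitude_nm * math.sin(2.0 * math.pi * x / cfg.course_period_nm)

    # One length draw is made per *filament*; a pair's shared value is the
    # average of the two draws its members consume, so the per-filament mean
    # of every length equals the pool mean no matter how draws are routed.
    # Opposite pairs meet head-to-head and must embed deeply enough that the
    # cross-CE depth gap stays small (recoverable by construction), so they
    # consume the deepest CE-indent draws.
    n_opp = sum(1 for cls, _ in plan if cls == "opposite")
    n_tfs_planned = sum(2 if cls != "single" else 1 for cls, _ in plan)
    pool_a = np.atleast_1d(
        _sym_trunc_normal(rng, cfg.le_indent_mean_nm, cfg.le_indent_sd_nm, 1.0, n_tfs_planned)
    )
    pool_c = np.atleast_1d(
        _sym_trunc_normal(rng, cfg.ce_indent_mean_nm, cfg.ce_indent_sd_nm, 1.0, n_tfs_planned)
    )
    pool_m = np.atleast_1d(
        _sym_trunc_normal(rng, m_mean, m_sd, max(gap, 1.0), n_tfs_planned)
    )
    c_desc = np.sort(pool_c)[::-1]
    c_opp_iter = iter(c_desc[: 2 * n_opp])
    c_rest_iter = iter(rng.permutation(c_desc[2 * n_opp :]))
    a_iter = iter(rng.permutation(pool_a))
    m_iter = iter(rng.permutation(pool_m))
    max_opp_depth_gap = 0.0

    for anchor_idx, (cls, side) in enumerate(plan):
        x_a, z_a = float(anchor_x[anchor_idx]), float(anchor_z[anchor_idx])
        layer = int(layer_ids[anchor_idx])
        # shared within-anchor values: members of a pair are mirror twins
        n_members = 1 if cls == "single" else 2
        c_iter = c_opp_iter if cls == "opposite" else c_rest_iter
        a = float(np.mean([next(a_iter) for _ in range(n_members)]))
        c = float(np.mean([next(c_iter) for _ in range(n_members)]))
        m = float(np.mean([next(m_iter) for _ in range(n_members)]))
        cos_t = min(gap / m, 1.0)
        # embed-depth feasibility: stay inside the element volumes
        a = min(a, (cfg.le_thickness_nm - 0.5) / max(cos_t, 1e-9))
        c = min(c, (cfg.ce_width_nm - 0.25) / max(cos_t, 1e-9))
        if cls == "opposite":
            max_opp_depth_gap = max(
                max_opp_depth_gap, cfg.ce_width_nm - 2.0 * c * cos_t
            )
        sin_t = math.sqrt(max(1.0 - cos_t**2, 0.0))
        phi = rng.normal(0.0, az_sd) + (math.pi if rng.integers(2) else 0.0)
        lat = np.array([math.cos(phi), 0.0, math.sin(phi)])

        members = {"opposite": ("left", "right"), "parallel": (side, side), "single": (side,)}[cls]
        for member_side in members:
            s = -1.0 if member_side == "left" else 1.0
            u = sin_t * lat + np.array([0.0, s * cos_t, 0.0])
            if cfg.pair_offset_nm > 0 and len(members) > 1:
                r_off = cfg.pair_offset_nm / 2.0 * math.sqrt(rng.uniform())
                ang = rng.uniform(0.0, 2.0 * math.pi)
                off = np.array([r_off * math.cos(ang), 0.0, r_off * math.sin(ang)])
            else:
                off = np.zeros(3)
            e_ce = np.array([x_a, s * (ce_half - c * cos_t), z_a]) + off
            e_ce[2] += shear(x_a)
            x_ce = e_ce + c * u
            x_le = e_ce + (c + m) * u
            e_le = e_ce + (a + c + m) * u
            t_len = a + c + m
            tf_id = len(truths)
            truths.append(
                TFTruth(
                    tf_id=tf_id,
                    side=member_side,
                    pairing=cls,
                    layer=layer,
                    anchor=int(anchor_idx),
                    endpoint_le=e_le,
                    endpoint_ce=e_ce,
                    x_le=x_le,
                    x_ce=x_ce,
                    len_total_nm=t_len,
                    len_le_indent_nm=a,
                    len_ce_indent_nm=c,
                    len_midsection_nm=m,
                )
            )
            pts = np.linspace(e_le, e_ce, cfg.points_per_tf)
            if cfg.endpoint_jitter_sd_nm > 0:
                pts = pts + rng.normal(0.0, cfg.endpoint_jitter_sd_nm, size=pts.shape)
            polylines.append(Polyline(pts, label=f"tf_{tf_id:04d}"))

    if n_opp and max_opp_depth_gap > cfg.opposite_max_depth_gap_nm:
        notes.append(
            "some opposite pairs exceed the intended cross-CE depth gap of "
            f"{cfg.opposite_max_depth_gap_nm} nm (best effort)"
        )

    model = _build_model(cfg, cr_width, polylines, truths, seed)
    truth = GroundTruth(
        seed=seed,
        config=cfg,
        tfs=truths,
        cr_width_nm=cr_width,
        ce_width_nm=cfg.ce_width_nm,
        le_ce_nm=gap,
        n_left=n_left,
        n_right=n_right,
        warnings=notes,
    )
    truth.aggregates = _realized_aggregates(truth)
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return model, truth


def _build_model(
    cfg: GeneratorConfig,
    cr_width: float,
    polylines: list[Polyline],
    truths: list[TFTruth],
    seed: int,
) -> SCModel:
    all_pts = np.vstack([p.points for p in polylines])
    x_lo = float(all_pts[:, 0].min()) - 10.0
    x_hi = float(all_pts[:, 0].max()) + 10.0
    # z extent of the straight-frame geometry (course shear removed)
    if cfg.course_amplitude_nm > 0:
        unsheared = np.abs(
            all_pts[:, 2]
            - cfg.course_amplitude_nm
            * np.sin(2.0 * math.pi * all_pts[:, 0] / cfg.course_period_nm)
        )
        # rigid per-filament shear vs pointwise element shear can disagree by
        # amplitude * (2*pi/period) * filament x-extent; widen the band
        z_buffer = 15.0 + cfg.course_amplitude_nm * 2.0 * math.pi / cfg.course_period_nm * 60.0
    else:
        unsheared = np.abs(all_pts[:, 2])
        z_buffer = 5.0
    h_core = float(unsheared.max()) + cfg.cloud_margin_nm + z_buffer
    h_slab = h_core + cfg.course_amplitude_nm

    cr_half = cr_width / 2.0
    ce_half = cfg.ce_width_nm / 2.0
    th = cfg.le_thickness_nm
    x_center, x_half = (x_lo + x_hi) / 2.0, (x_hi - x_lo) / 2.0

    def slab(role: str, y_center: float, y_half: float) -> dict:
        return dict(
            center=np.array([x_center, y_center, 0.0]),
            axes=np.eye(3),
            half_extents=np.array([x_half, y_half, h_slab]),
        )

    slabs = {
        ROLE_LE_LEFT: slab(ROLE_LE_LEFT, -(cr_half + th / 2.0), th / 2.0),
        ROLE_LE_RIGHT: slab(ROLE_LE_RIGHT, cr_half + th / 2.0, th / 2.0),
        ROLE_CE: slab(ROLE_CE, 0.0, ce_half),
    }
    clouds: dict[str, np.ndarray | None] = {r: None for r in slabs}
    if cfg.build_point_clouds:
        margin, spacing = cfg.cloud_margin_nm, cfg.element_cloud_spacing_nm
        bands = {
            ROLE_LE_LEFT: (-(cr_half + th) + margin, -cr_half - margin),
            ROLE_LE_RIGHT: (cr_half + margin, cr_half + th - margin),
            ROLE_CE: (-ce_half + margin, ce_half - margin),
        }
        xs = np.arange(x_lo + margin, x_hi - margin + 1e-9, spacing)
        zs = np.arange(-h_core, h_core + 1e-9, spacing)
        for role, (y0, y1) in bands.items():
            ys = np.arange(y0, y1 + 1e-9, spacing)
            if len(ys) == 0:  # element thinner than twice the margin
                ys = np.array([(y0 + y1) / 2.0])
            gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
            if cfg.course_amplitude_nm > 0:
                pts[:, 2] += cfg.course_amplitude_nm * np.sin(
                    2.0 * math.pi * pts[:, 0] / cfg.course_period_nm
                )
            clouds[role] = pts

    def region(role: str) -> ElementRegion:
        return ElementRegion(
            role=role,
            kind="slab",
            points=clouds[role],
            delta_nm=cfg.cloud_margin_nm,
            **slabs[role],
        )

    return SCModel(
        le_left=region(ROLE_LE_LEFT),
        le_right=region(ROLE_LE_RIGHT),
        ce=region(ROLE_CE),
        tfs=polylines,
        scale=ScaleInfo(),
        units="nm",
        source=f"synthetic(seed={seed})",
    )


def _realized_aggregates(truth: GroundTruth) -> dict[str, float]:
    """Estimator targets evaluated on the noise-free geometry."""
    from .geometry import bounding_rectangle, fit_plane, group_nearest_neighbors, project_to_plane
    from .metrics import compute_asymmetry, width_samples_from_points

    tfs = truth.tfs

    def arr(getter) -> np.ndarray:
        return np.asarray([getter(t) for t in tfs], dtype=float)

    def mean_sd(v: np.ndarray) -> tuple[float, float]:
        v = v[np.isfinite(v)]
        if len(v) == 0:
            return math.nan, math.nan
        return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else math.nan

    agg: dict[str, float] = {}
    for key, getter in (
        ("tf_len", lambda t: t.len_total_nm),
        ("le_indent", lambda t: t.len_le_indent_nm),
        ("ce_indent", lambda t: t.len_ce_indent_nm),
        ("midsection", lambda t: t.len_midsection_nm),
    ):
        agg[f"{key}_mean"], agg[f"{key}_sd"] = mean_sd(arr(getter))

    by_side = {
        side: [t for t in tfs if t.side == side] for side in ("left", "right")
    }

    def pts(side: str, attr: str) -> np.ndarray:
        sel = by_side[side]
        return (
            np.asarray([getattr(t, attr) for t in sel]) if sel else np.empty((0, 3))
        )

    widths = width_samples_from_points(
        pts("left", "x_le"), pts("right", "x_le"), pts("left", "x_ce"), pts("right", "x_ce")
    )
    for name, samples in (
        ("cr_width", widths.cr_width),
        ("le_ce", widths.le_ce),
        ("ce_width", widths.ce_width),
    ):
        agg[f"{name}_mean"], agg[f"{name}_sd"] = mean_sd(samples)

    nn_par, nn_opp, nn_le = [], [], []
    for side, other in (("left", "right"), ("right", "left")):
        own_ce, other_ce = pts(side, "endpoint_ce"), pts(other, "endpoint_ce")
        own_le = pts(side, "endpoint_le")
        if len(own_ce):
            nn_par.append(group_nearest_neighbors(own_ce, own_ce, exclude_self=True))
            nn_opp.append(group_nearest_neighbors(own_ce, other_ce))
            nn_le.append(group_nearest_neighbors(own_le, own_le, exclude_self=True))
    for name, chunks in (("nn_parallel", nn_par), ("nn_opposite", nn_opp), ("nn_le", nn_le)):
        samples = np.concatenate(chunks) if chunks else np.empty(0)
        agg[f"{name}_mean"], agg[f"{name}_sd"] = mean_sd(samples)

    site = np.asarray([t.x_ce for t in tfs])
    agg["tfs_per_um"] = agg["tfs_per_um2"] = math.nan
    if len(site) >= 3:
        try:
            rect = bounding_rectangle(project_to_plane(site, fit_plane(site)))
            if rect.length_nm > 0:
                agg["tfs_per_um"] = len(tfs) / (rect.length_nm / 1000.0)
            if rect.area_nm2 > 0:
                agg["tfs_per_um2"] = len(site) / (rect.area_nm2 / 1e6)
        except Exception:
            pass

    agg["asymmetry_pct"] = compute_asymmetry(truth.n_left, truth.n_right)
    n = max(len(tfs), 1)
    for cls in ("parallel", "opposite", "single"):
        agg[f"prop_{cls}"] = sum(1 for t in tfs if t.pairing == cls) / n
    return agg


def generate_cohort(
    config: GeneratorConfig | None = None, n_tomograms: int = 6, seed: int = 0
) -> list[tuple[SCModel, GroundTruth]]:
    """n independent synthetic tomograms; per-tomogram seeds are derived
    deterministically from the master seed (master + index)."""
    if n_tomograms < 1:
        raise ValueError("n_tomograms must be >= 1")
    cfg = config or GeneratorConfig()
    return [generate_sc(cfg, (seed + i) % _SEED_MOD) for i in range(n_tomograms)]
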
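"""Report-layer arithmetic and result tables.

Turns pooled summaries into the two standard tables (central-region widths;
TF segment lengths and densities) and applies the molecule-count
conversion: each TF is one SYCP1 dimer, so a TF linear density of
(mean ± sd) per µm implies 2x(mean - sd) .. 2x(mean + sd) SYCP1 molecules
per µm of SC.
"""

from __future__ import annotations

import math

import pandas as pd

from .metrics import SummaryMetrics

SYCP1_PER_TF = 2  # one dimer per filament


def sycp1_per_um_range(
    tfs_per_um_mean: float, tfs_per_um_sd: float, molecules_per_tf: int = SYCP1_PER_TF
) -> tuple[float, float]:
    """SYCP1 molecules per µm of SC implied by the TF linear density."""
    sd = 0.0 if (tfs_per_um_sd is None or math.isnan(tfs_per_um_sd)) else tfs_per_um_sd
    if sd < 0:
        raise ValueError("sd must be >= 0")
    low = molecules_per_tf * (tfs_per_um_mean - sd)
    high = molecules_per_tf * (tfs_per_um_mean + sd)
    return low, high


def midsection_from_segments(total_nm: float, le_indent_nm: float, ce_indent_nm: float) -> float:
    """Central-region midsection length implied by the printed segment means
    of a straight filament: total minus both embedded indents."""
    return total_nm - le_indent_nm - ce_indent_nm


def central_region_table(summary: SummaryMetrics) -> pd.DataFrame:
    """Central-region quantification table (nm)."""
    return pd.DataFrame(
        [
            {"metric": "CR-width", "mean": summary.cr_width_mean, "std": summary.cr_width_sd},
            {"metric": "LE-CE", "mean": summary.le_ce_mean, "std": summary.le_ce_sd},
            {"metric": "CE-width", "mean": summary.ce_width_mean, "std": summary.ce_width_sd},
        ]
    )


def tf_table(summary: SummaryMetrics) -> pd.DataFrame:
    """Transverse-filament quantification table (lengths nm, densities /µm, /µm²)."""
    rows = [
        {"metric": "TF length (I)", "mean": summary.tf_len_mean, "std": summary.tf_len_sd},
        {"metric": "LE-indent (II)", "mean": summary.le_indent_mean, "std": summary.le_indent_sd},
        {"metric": "CR-midsection (III)", "mean": summary.midsection_mean, "std": summary.midsection_sd},
        {"metric": "CE-indent (IV)", "mean": summary.ce_indent_mean, "std": summary.ce_indent_sd},
        {"metric": "TFs per um", "mean": summary.tfs_per_um, "std": summary.tfs_per_um_sd},
        {"metric": "TFs per um^2", "mean": summary.tfs_per_um2, "std": summary.tfs_per_um2_sd},
    ]
    return pd.DataFrame(rows)


def render_report(summary: SummaryMetrics) -> str:
    """Human-readable report of one pooled summary."""
    lines = ["Central region quantification [nm]", ""]
    lines.append(central_region_table(summary).to_string(index=False, float_format="%.1f"))
    lines += ["", "Transverse filament quantification", ""]
    lines.append(tf_table(summary).to_string(index=False, float_format="%.1f"))
    low, high = sycp1_per_um_range(summary.tfs_per_um, summary.tfs_per_um_sd)
    lines += [
        "",
        f"TF CE nearest neighbors: opposite {summary.nn_opposite_mean:.1f} "
        f"(±{summary.nn_opposite_sd:.1f}) nm, parallel {summary.nn_parallel_mean:.1f} "
        f"(±{summary.nn_parallel_sd:.1f}) nm; LE {summary.nn_le_mean:.1f} "
        f"(±{summary.nn_le_sd:.1f}) nm",
        f"Side asymmetry: {summary.asymmetry_pct:.1f}% "
        f"(n_left {summary.n_left}, n_right {summary.n_right})",
        f"Pairing classes: parallel {summary.prop_parallel:.2f}, "
        f"opposite {summary.prop_opposite:.2f}, single {summary.prop_single:.2f}",
        f"Implied SYCP1 per um of SC: {low:.0f} to {high:.0f} molecules",
    ]
    return "\n".join(lines)
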
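"""Plain-text and CSV renderers for the four analysis tables.

Reports are views over already-computed numbers: every figure printed here
also appears, unrounded, in the pipeline's JSON output. Percent statistics
are rounded to integers and AUCs to two decimals only at render time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import CutoffStats


def _fmt_range(mean: float, lo: float, hi: float) -> str:
    if np.isnan(mean):
        return ""
    if np.isnan(lo) or (round(lo) == round(mean) == round(hi)):
        return f"{mean:.0f}"
    return f"{mean:.0f} ({lo:.0f}–{hi:.0f})"


def characteristics_text(summary: pd.DataFrame, n_negative: int, n_positive: int) -> str:
    """Table-1-style cohort characterization."""
    lines = [
        "Population characteristics according to amyloid status",
        f"{'Feature':<28}{f'Amyloid- (n={n_negative})':>22}"
        f"{f'Amyloid+ (n={n_positive})':>22}{'p-value':>10}",
    ]
    for feat, row in summary.iterrows():
        p = "" if np.isnan(row["p_value"]) else f"{row['p_value']:.3f}"
        lines.append(f"{feat:<28}{row['negative']:>22}{row['positive']:>22}{p:>10}")
    return "\n".join(lines) + "\n"


def performance_text(perf: pd.DataFrame) -> str:
    """Table-2-style per-factor performance listing.

    ``perf`` rows carry name, level, direction (↑/↓/blank), mean_auc and CI.
    """
    lines = [
        "Cross-validated performance for detecting amyloid positivity",
        f"{'Factor':<40}{'Dir':>4}{'AUC (95% CI)':>20}",
    ]
    for _, row in perf.iterrows():
        indent = "  " * int(row.get("level", 0))
        auc = f"{row['mean_auc']:.2f} ({row['ci_low']:.2f}–{row['ci_high']:.2f})"
        lines.append(f"{indent + str(row['name']):<40}{row.get('direction', ''):>4}{auc:>20}")
    return "\n".join(lines) + "\n"


def cutoff_text(stats: CutoffStats) -> str:
    """Table-3-style screening statistics; undefined ratios render blank."""
    lines = [
        "Classifier statistics for selected DSI cutoff levels",
        f"{'Cutoff':<8}{'Sens (%)':>14}{'Spec (%)':>14}{'PPV (%)':>14}"
        f"{'NPV (%)':>14}{'RPP (%)':>14}",
    ]
    for cutoff, row in stats.table.iterrows():
        cells = [
            _fmt_range(row[f"{s}_mean"], row[f"{s}_lo"], row[f"{s}_hi"])
            for s in CutoffStats.STATS
        ]
        lines.append(f"{cutoff:<8.1f}" + "".join(f"{c:>14}" for c in cells))
    return "\n".join(lines) + "\n"


def scenarios_text(results: pd.DataFrame) -> str:
    """Table-4-style added-value listing, grouped by block."""
    lines = ["Added value of factor groups (shared CV partitions)"]
    for block, chunk in results.groupby("block", sort=False):
        lines.append(f"\n[{block}]")
        for name, row in chunk.iterrows():
            auc = f"{row['mean_auc']:.2f} ({row['ci_low']:.2f}–{row['ci_high']:.2f})"
            lines.append(f"  {name:<36}{auc:>20}")
    return "\n".join(lines) + "\n"
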
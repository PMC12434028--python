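"""Small report helpers for group summaries."""
from __future__ import annotations

import pandas as pd


def percent_reduction(group_value: float, reference_value: float) -> float:
    """Percent reduction of ``group_value`` relative to ``reference_value``.

    E.g. group mean 3857 vs reference 4207 mm^3 -> 8.3 (percent smaller).
    """
    if reference_value == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (reference_value - group_value) / reference_value


def percent_difference(group_value: float, reference_value: float) -> float:
    """Signed percent difference of ``group_value`` vs ``reference_value``."""
    if reference_value == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (group_value - reference_value) / reference_value


def fold_change(a: float, b: float) -> float:
    """Fold difference a / b (e.g. largest-cluster volumes 571/162 -> 3.5)."""
    if b == 0:
        raise ValueError("denominator must be nonzero")
    return a / b


def group_means(measures: pd.DataFrame, outcome: str,
                group_col: str = "group") -> dict[str, float]:
    """Unadjusted group means of one measure."""
    return measures.groupby(group_col)[outcome].mean().to_dict()


def summary_text(analysis) -> str:
    """Human-readable summary of a :class:`~striocomp.pipeline.CohortAnalysis`."""
    lines = ["# Cohort summary", ""]
    n = analysis.manifest["group"].value_counts().to_dict()
    lines.append(f"subjects: {n}")
    lines.append("")
    lines.append("## Covariate-adjusted group comparisons (BH within family)")
    lines.append(analysis.group_stats.to_string(index=False))
    if len(analysis.severity_stats):
        lines.append("")
        lines.append("## Severity associations (MDD subset)")
        lines.append(analysis.severity_stats.to_string(index=False))
    for name, table in analysis.clusters.items():
        lines.append("")
        lines.append(f"## Significant clusters: {name} (p < 0.05 FWE)")
        lines.append(table.to_string(index=False) if len(table) else "(none)")
    return "\n".join(lines) + "\n"
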
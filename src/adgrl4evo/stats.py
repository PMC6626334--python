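"""Group-comparison statistics on orthologue similarity tables, and the
consolidated report bundle.

Two-sample comparisons use the unpaired Student's t-test (pooled variance)
or Welch's variant; multi-group comparisons use one-way ANOVA. For two
groups the pooled-variance identity F = t**2 holds. No multiple-testing
correction is applied anywhere (noted in the report footer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Significance star thresholds (the standard GraphPad-style annotation).
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p <= thr:
            return stars
    return "ns"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def group_test(
    values_a: Sequence[float], values_b: Sequence[float], mode: str = "student_t"
) -> TestResult:
    """Two-sample t statistic with two-sided p.

    ``student_t`` pools variances; ``welch_t`` does not. Each group needs
    n >= 2; zero pooled variance with equal means is degenerate and raises.
    """
    if mode not in ("student_t", "welch_t"):
        raise ValueError(f"unknown mode {mode!r}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    equal_var = mode == "student_t"
    if equal_var and a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        raise ValueError("all observations identical: t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue))


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way ANOVA: (F, df_between, df_within, p). Needs >= 2 groups of
    n >= 2 each; F = 0 when every observation is equal."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least two observations")
    k = len(arrays)
    n = sum(len(g) for g in arrays)
    df1, df2 = k - 1, n - k
    if all((g == arrays[0][0]).all() for g in arrays):
        return 0.0, df1, df2, 1.0
    res = sps.f_oneway(*arrays)
    return float(res.statistic), df1, df2, float(res.pvalue)


def similarity_group_tests(
    table: pd.DataFrame, gene: str, baseline_gene: str, mode: str = "student_t"
) -> pd.DataFrame:
    """Per-group comparison of one gene's percent similarities against a
    baseline gene's (the exome-similarity rows travel as a pseudo-gene)."""
    rows = []
    for group, sub in table.groupby("group"):
        a = sub.loc[sub["gene"] == gene, "pct_similarity"]
        b = sub.loc[sub["gene"] == baseline_gene, "pct_similarity"]
        if len(a) < 2 or len(b) < 2:
            continue
        res = group_test(a, b, mode=mode)
        rows.append(
            {
                "group": group,
                "gene": gene,
                "baseline": baseline_gene,
                "mean_gene": float(a.mean()),
                "mean_baseline": float(b.mean()),
                "t": res.statistic,
                "df": res.df,
                "p": res.p_value,
                "stars": res.stars,
            }
        )
    return pd.DataFrame(rows)


def write_report(
    out_dir: str | Path,
    classification: pd.DataFrame | None = None,
    rankings: pd.DataFrame | None = None,
    events: pd.DataFrame | None = None,
    stats_tables: dict[str, pd.DataFrame] | None = None,
) -> Path:
    """Bundle pipeline outputs into a JSON + TSV report directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "footer": "No multiple-testing correction applied to any p value."
    }
    if classification is not None:
        classification.to_csv(out / "classification.tsv", sep="\t", index=False)
        summary["n_transcripts"] = int(len(classification))
        summary["variant_counts"] = (
            classification["variant"].value_counts().to_dict()
        )
    if rankings is not None:
        rankings.to_csv(out / "conservation_rankings.tsv", sep="\t", index=False)
        summary["top_domain"] = (
            str(rankings.iloc[0]["domain"]) if len(rankings) else None
        )
    if events is not None:
        events.to_csv(out / "emergence_events.tsv", sep="\t", index=False)
        summary["n_emergence_events"] = int(len(events))
    for name, df in (stats_tables or {}).items():
        df.to_csv(out / f"stats_{name}.tsv", sep="\t", index=False)
    path = out / "report.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return path
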
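"""Condition-level hit tables, methylation-level classes, global summaries.

A "hit" is a significant methylation event at a gene promoter on one array.
Per condition, a gene's replicate hit count classifies its methylation level:
unmethylated (0 hits in the set), methylated (hits in all arrays, 3/3 or 2/2),
partly methylated otherwise.  The mean total hit count of an array set is the
semi-quantitative, unitless global methylation measure; conditions are
compared with an unpaired two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import ArrayCondition


@dataclass
class HitTable:
    """Gene x array boolean hit matrix with the replicate grouping.

    ``hits``: DataFrame, index = gene_ids, columns = array_ids (bool).
    ``arrays``: DataFrame with one row per array:
    ``array_id, injury_type, arm, day, replicate, set_label``.
    """

    hits: pd.DataFrame
    arrays: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.hits.columns) != list(self.arrays["array_id"]):
            raise ValueError("hit columns must match array table order")

    @classmethod
    def from_array_hits(
        cls, per_array: list[tuple[ArrayCondition, pd.Series]]
    ) -> "HitTable":
        hits = pd.DataFrame({c.array_id: h.astype(bool) for c, h in per_array})
        arrays = pd.DataFrame(
            [
                {
                    "array_id": c.array_id,
                    "injury_type": c.injury_type,
                    "arm": c.arm,
                    "day": c.day,
                    "replicate": c.replicate,
                    "set_label": c.set_label,
                }
                for c, _ in per_array
            ]
        )
        return cls(hits=hits, arrays=arrays)

    @property
    def gene_ids(self) -> pd.Index:
        return self.hits.index

    @property
    def set_labels(self) -> list[str]:
        return list(dict.fromkeys(self.arrays["set_label"]))

    def arrays_of(self, set_label: str) -> list[str]:
        sel = self.arrays.loc[self.arrays["set_label"] == set_label, "array_id"]
        if sel.empty:
            raise KeyError(f"unknown condition set: {set_label}")
        return list(sel)

    def group_size(self, set_label: str) -> int:
        return len(self.arrays_of(set_label))

    def hit_counts(self, set_label: str) -> pd.Series:
        """Per-gene replicate hit count within one condition set."""
        return self.hits[self.arrays_of(set_label)].sum(axis=1)

    def array_totals(self, set_label: str) -> pd.Series:
        """Total hits per array of one set."""
        return self.hits[self.arrays_of(set_label)].sum(axis=0)


def classify_levels(hit_count: int, group_size: int) -> str:
    """Methylation-level class of one gene in one replicate set.

    unmethylated: no hit in any array (0/3 or 0/2); methylated: hits in all
    arrays (3/3 or 2/2); partly methylated in between (1/3, 2/3 or 1/2).
    """
    if group_size not in (2, 3):
        raise ValueError("group_size must be 2 (sham) or 3 (injury/naive)")
    if not 0 <= hit_count <= group_size:
        raise ValueError(f"hit_count {hit_count} out of range 0..{group_size}")
    if hit_count == 0:
        return "unmethylated"
    if hit_count == group_size:
        return "methylated"
    return "partly"


def global_methylation(hit_table: HitTable, set_label: str) -> float:
    """Mean total hit count over the replicate arrays of one condition set."""
    totals = hit_table.array_totals(set_label)
    if totals.empty:
        raise ValueError(f"empty condition: {set_label}")
    return float(totals.mean())


def star_code(p: float) -> str:
    """Significance stars: * P<=0.05, ** P<=0.01, *** P<=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare_conditions(
    hit_table: HitTable, set_a: str, set_b: str
) -> tuple[float, float, str]:
    """Unpaired two-tailed pooled-variance t-test on per-array total hits.

    Returns ``(t, P, stars)``.  Degenerate zero-variance groups: equal means
    give P = 1 by convention; unequal means give P = 0 (infinite t).
    """
    a = hit_table.array_totals(set_a).to_numpy(dtype=float)
    b = hit_table.array_totals(set_b).to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 arrays per condition")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, ""
        t = float(np.inf) if a.mean() > b.mean() else float(-np.inf)
        return t, 0.0, "***"
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), star_code(float(p))


def condition_summary(hit_table: HitTable, set_label: str) -> dict:
    """Level-class gene counts and global methylation for one condition set."""
    k = hit_table.group_size(set_label)
    counts = hit_table.hit_counts(set_label)
    levels = counts.map(lambda c: classify_levels(int(c), k))
    n = len(counts)
    return {
        "set_label": set_label,
        "group_size": k,
        "mean_total_hits": global_methylation(hit_table, set_label),
        "n_methylated": int((levels == "methylated").sum()),
        "n_partly": int((levels == "partly").sum()),
        "n_unmethylated": int((levels == "unmethylated").sum()),
        "pct_methylated": 100.0 * (levels == "methylated").sum() / n,
    }


def summarize_conditions(hit_table: HitTable) -> pd.DataFrame:
    """One summary row per condition set (global-methylation figure data)."""
    return pd.DataFrame(
        [condition_summary(hit_table, s) for s in hit_table.set_labels]
    )


def cross_condition_summary(hit_table: HitTable) -> dict:
    """Genes never / always methylated across every array, plus the
    per-condition percent-methylated range."""
    m = hit_table.hits.to_numpy(dtype=bool)
    n_genes = m.shape[0]
    never = int((~m).all(axis=1).sum())
    always = int(m.all(axis=1).sum())
    pcts = [
        condition_summary(hit_table, s)["pct_methylated"]
        for s in hit_table.set_labels
    ]
    return {
        "n_genes": n_genes,
        "unmethylated_all_conditions": never,
        "pct_unmethylated_all": 100.0 * never / n_genes,
        "methylated_all_arrays": always,
        "pct_methylated_all": 100.0 * always / n_genes,
        "pct_methylated_range": (min(pcts), max(pcts)),
    }
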
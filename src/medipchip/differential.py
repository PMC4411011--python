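"""D_MV differential scheme: Methylation Values, strict filters, DM genes.

For each gene and each injury-vs-sham pair the difference of relative hit
numbers

    D_MV = injury_hits / 3 - sham_hits / 2

is computed exactly (as a rational), then mapped to an ordinal Methylation
Value (MV).  The default table ranks the five distinct positive D_MV values
{1, 2/3, 1/2, 1/3, 1/6} to {+5, +4, +3, +2, +1} and mirrors them for the
negatives, the only antisymmetric order-preserving reading of a
ranked-highest-to-lowest scale; D_MV = 0 is 'M' (methylated in sham, still
methylated upon injury: 3/3 vs 2/2) or 'U' (persistently unmethylated: 0/3
vs 0/2).  An alternate preset reproduces a published worked example that
assigns (2/3 injury, 0/2 sham) to MV=+1 instead.

The strict filter keeps only MV = +5/-5 and requires the naive hit count to
resemble the sham: hyper needs naive 0/3 or 1/3, hypo needs naive 2/3 or 3/3.
A gene is differentially methylated (DM) between injury models when it passes
the strict filter under exactly one model at a given day.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .design import DAYS, INJURY_TYPES, NAIVE, condition_label
from .hits import HitTable

INJURY_GROUP = 3
SHAM_GROUP = 2

#: rank of each positive |D_MV| value; antisymmetric for negatives
_RANK_TABLE: dict[Fraction, int] = {
    Fraction(1, 1): 5,
    Fraction(2, 3): 4,
    Fraction(1, 2): 3,
    Fraction(1, 3): 2,
    Fraction(1, 6): 1,
}

#: published worked example: (injury 2/3, sham 0/2), D_MV ~ 0.7 -> MV +1
_FIGURE_OVERRIDES: dict[tuple[int, int], int] = {(2, 0): 1, (1, 2): -1}

MV_PRESETS = ("rank", "figure")


def compute_dmv(injury_hits: int, sham_hits: int) -> Fraction:
    """Exact difference of relative hit numbers, injury/3 - sham/2."""
    if not 0 <= injury_hits <= INJURY_GROUP:
        raise ValueError(f"injury_hits must be in 0..{INJURY_GROUP}")
    if not 0 <= sham_hits <= SHAM_GROUP:
        raise ValueError(f"sham_hits must be in 0..{SHAM_GROUP}")
    return Fraction(injury_hits, INJURY_GROUP) - Fraction(sham_hits, SHAM_GROUP)


def assign_mv(
    injury_hits: int, sham_hits: int, preset: str = "rank"
) -> int | str:
    """Methylation Value for one injury/sham hit pattern.

    Returns a signed integer in -5..+5, or 'M'/'U' for the two neutral
    patterns (3/3 vs 2/2 methylated throughout; 0/3 vs 0/2 unmethylated
    throughout).  ``preset='figure'`` applies the worked-example override.
    """
    if preset not in MV_PRESETS:
        raise ValueError(f"unknown MV preset: {preset!r}")
    d = compute_dmv(injury_hits, sham_hits)
    if d == 0:
        if injury_hits == INJURY_GROUP and sham_hits == SHAM_GROUP:
            return "M"
        if injury_hits == 0 and sham_hits == 0:
            return "U"
        # injury/3 == sham/2 has no other integer solutions; kept defensively
        return "neutral-0"
    if preset == "figure" and (injury_hits, sham_hits) in _FIGURE_OVERRIDES:
        return _FIGURE_OVERRIDES[(injury_hits, sham_hits)]
    rank = _RANK_TABLE[abs(d)]
    return rank if d > 0 else -rank


def mv_category(mv: int | str) -> str:
    """Verbal category of an MV: strong/medium/weak hyper- or hypomethylation,
    or the neutral persistently-(un)methylated cases."""
    if mv == "M":
        return "neutral-M"
    if mv == "U":
        return "neutral-U"
    if not isinstance(mv, int):
        return "neutral-0"
    strength = {5: "strong", 4: "medium", 3: "medium", 2: "weak", 1: "weak"}
    direction = "hyper" if mv > 0 else "hypo"
    return f"{strength[abs(mv)]} {direction}"


def strict_filter(
    mv: int | str, naive_hits: int, mv_levels: tuple[int, ...] = (5,)
) -> str:
    """Strict naive-constrained verdict: 'hyper', 'hypo' or 'none'.

    Only |MV| in ``mv_levels`` (default {5}) qualifies, and the naive set must
    look like the sham: hyper requires naive 0/3 or 1/3 (mostly unmethylated
    before injury), hypo requires naive 2/3 or 3/3.
    """
    if naive_hits is None:
        raise ValueError("naive hit count required for the strict filter")
    if not 0 <= naive_hits <= 3:
        raise ValueError("naive_hits must be in 0..3")
    if not isinstance(mv, int):
        return "none"
    if mv in mv_levels and naive_hits in (0, 1):
        return "hyper"
    if -mv in mv_levels and naive_hits in (2, 3):
        return "hypo"
    return "none"


def mv_records(
    hit_table: HitTable,
    injury_type: str,
    day: int,
    preset: str = "rank",
    strict: bool = True,
    mv_levels: tuple[int, ...] = (5,),
) -> pd.DataFrame:
    """Per-gene MV table for one injury-vs-sham comparison.

    Columns: ``gene_id, injury_hits, sham_hits, naive_hits, d_mv, mv,
    category, verdict``.  With ``strict=False`` the naive constraint is
    dropped and the verdict reflects MV sign alone (lenient mode).
    """
    inj = hit_table.hit_counts(condition_label(injury_type, "injury", day))
    sham = hit_table.hit_counts(condition_label(injury_type, "sham", day))
    naive = hit_table.hit_counts(NAIVE)
    rows = []
    for gene in hit_table.gene_ids:
        i, s, nv = int(inj[gene]), int(sham[gene]), int(naive[gene])
        d = compute_dmv(i, s)
        mv = assign_mv(i, s, preset=preset)
        if strict:
            verdict = strict_filter(mv, nv, mv_levels)
        else:
            if isinstance(mv, int) and mv in mv_levels:
                verdict = "hyper"
            elif isinstance(mv, int) and -mv in mv_levels:
                verdict = "hypo"
            else:
                verdict = "none"
        rows.append((gene, i, s, nv, float(d), mv, mv_category(mv), verdict))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "injury_hits", "sham_hits", "naive_hits",
            "d_mv", "mv", "category", "verdict",
        ],
    )


def dm_between_injuries(
    records_a: pd.DataFrame, records_b: pd.DataFrame
) -> pd.DataFrame:
    """Differentially methylated genes between the two injury models at one day.

    A gene is DM when its strict-filter verdict is not 'none' under exactly
    one model.  Inputs are ``mv_records`` frames for the same day; returns
    ``gene_id, verdict_a, verdict_b``.
    """
    a = records_a.set_index("gene_id")["verdict"]
    b = records_b.set_index("gene_id")["verdict"]
    if set(a.index) != set(b.index):
        raise ValueError("record gene sets do not match")
    b = b.reindex(a.index)
    dm = (a != "none") ^ (b != "none")
    out = pd.DataFrame(
        {"gene_id": a.index[dm], "verdict_a": a[dm].values, "verdict_b": b[dm].values}
    )
    return out.reset_index(drop=True)


def differential_analysis(
    hit_table: HitTable,
    preset: str = "rank",
    strict: bool = True,
    mv_levels: tuple[int, ...] = (5,),
) -> tuple[dict[tuple[str, int], pd.DataFrame], dict[int, pd.DataFrame]]:
    """All per-(injury, day) MV tables plus the per-day DM gene sets.

    Days are never pooled: differential methylation is timepoint-specific.
    """
    records = {
        (it, day): mv_records(hit_table, it, day, preset, strict, mv_levels)
        for it in INJURY_TYPES
        for day in DAYS
    }
    dm = {
        day: dm_between_injuries(records[("SNA", day)], records[("DCA", day)])
        for day in DAYS
    }
    return records, dm
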
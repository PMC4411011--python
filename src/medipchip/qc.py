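"""Technical-validation statistics for MeDIP experiments.

MeDIP enrichment of a fragment population scales with the number of
methylated CpGs the fragments carry.  For a sonicated sample with the typical
Gaussian fragment-size distribution (200-1,000 bp), each amplicon is
summarized by the weighted geometric mean of the CpG counts of hypothetical
fragments of 200, 400, 700 and 1,000 bp centered on it:

    weighted #CpG = (c200 * c400^2 * c700^2 * c1000)^(1/6)

which is then correlated (Pearson) against the measured IP/Input enrichment
ratios.  Replicate-array reproducibility is the Pearson R (and R^2) over the
matched per-probe log2 values of each within-set array pair.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .design import ProbeSignal

#: geometric-mean weights of the 200/400/700/1000 bp fragment sizes
FRAGMENT_WEIGHTS = (1, 2, 2, 1)


def weighted_cpg(counts) -> float:
    """Weighted geometric mean CpG count of one amplicon's fragment family.

    ``counts`` are the CpG counts at fragment sizes 200, 400, 700, 1000 bp.
    Computed in log space; any zero count short-circuits to 0 exactly.
    """
    c = [float(x) for x in counts]
    if len(c) != 4:
        raise ValueError("need exactly four counts (200/400/700/1000 bp)")
    if any(x < 0 for x in c):
        raise ValueError("CpG counts must be non-negative")
    if any(x == 0.0 for x in c):
        return 0.0
    logs = [w * math.log(x) for w, x in zip(FRAGMENT_WEIGHTS, c)]
    return math.exp(sum(logs) / sum(FRAGMENT_WEIGHTS))


def enrichment_correlation(enrichment_ratios, weighted_counts) -> float | None:
    """Pearson R between IP/Input enrichment and weighted CpG counts.

    Returns None when either vector has zero variance (undefined, reported
    missing rather than 0).
    """
    x = np.asarray(enrichment_ratios, dtype=float)
    y = np.asarray(weighted_counts, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def replicate_correlation(a: ProbeSignal, b: ProbeSignal) -> tuple[float, float]:
    """Pearson R and R^2 over the matched probes of two replicate arrays."""
    if len(a.log2) != len(b.log2):
        raise ValueError("probe sets do not match")
    x = a.values if a.centered is not None else a.log2
    y = b.values if b.centered is not None else b.log2
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


def replicate_correlation_matrix(signals: list[ProbeSignal]) -> pd.DataFrame:
    """All within-set array-pair correlations: one row per pair with
    ``set_label, array_a, array_b, r, r2``."""
    by_set: dict[str, list[ProbeSignal]] = {}
    for s in signals:
        by_set.setdefault(s.condition.set_label, []).append(s)
    rows = []
    for label, group in by_set.items():
        for a, b in combinations(group, 2):
            r, r2 = replicate_correlation(a, b)
            rows.append((label, a.array_id, b.array_id, r, r2))
    return pd.DataFrame(rows, columns=["set_label", "array_a", "array_b", "r", "r2"])
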
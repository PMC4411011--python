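"""CpG-island detection and normalized obs/exp CpG density around the TSS.

The island criterion follows the classic CpGPlot/Gardiner-Garden definition:
a region of at least 200 bp (100 bp optionally) whose observed/expected CpG
ratio exceeds 0.6 and whose G+C content exceeds 50%, found with a sliding
window (100 bp, step 1).  The promoter CpG density statistic is the obs/exp
ratio over the symmetric 3 kb window centered on the TSS:

    obs/exp CpG = (#CpG * window_length) / (#C * #G)

where #CpG counts the CG dinucleotide at consecutive positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CpGDensity:
    """Normalized CpG density of one promoter window."""

    seq_id: str
    window_length: int
    n_cpg: int
    n_c: int
    n_g: int
    ratio: float | None  # None when #C or #G is zero (undefined, not 0)


@dataclass
class CpGIsland:
    """One detected island, 0-based half-open coordinates."""

    seq_id: str
    start: int
    end: int
    obs_exp: float
    gc: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _encode(sequence: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indicator arrays (is_C, is_G, starts_CpG); ambiguous bases count as
    neither C nor G and break CpG pairs."""
    s = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_c = s == ord("C")
    is_g = s == ord("G")
    cpg = np.zeros(len(s), dtype=bool)
    if len(s) > 1:
        cpg[:-1] = is_c[:-1] & is_g[1:]
    return is_c, is_g, cpg


def count_cpg(sequence: str) -> tuple[int, int, int]:
    """(#CpG, #C, #G) of a sequence; CG pairs at consecutive positions."""
    is_c, is_g, cpg = _encode(sequence)
    return int(cpg.sum()), int(is_c.sum()), int(is_g.sum())


def obs_exp_ratio(sequence: str, seq_id: str = "", expected_length: int = 3000
                  ) -> CpGDensity:
    """Normalized obs/exp CpG ratio of a TSS-centered window.

    The nominal window is 3 kb; a shorter sequence (promoter truncated at a
    contig end) substitutes its actual length into the normalization so the
    statistic stays a proper obs/exp ratio.
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    n_cpg, n_c, n_g = count_cpg(sequence)
    if n_c == 0 or n_g == 0:
        ratio = None
    else:
        ratio = n_cpg * n / (n_c * n_g)
    return CpGDensity(seq_id=seq_id, window_length=n, n_cpg=n_cpg,
                      n_c=n_c, n_g=n_g, ratio=ratio)


def tss_window(sequence: str, tss: int, half: int = 1500) -> str:
    """Symmetric window around a TSS, truncated at the sequence ends."""
    return sequence[max(0, tss - half): min(len(sequence), tss + half)]


def _window_stats(sequence: str, window: int):
    """Per-start obs/exp and GC over all sliding windows (vectorized)."""
    is_c, is_g, cpg = _encode(sequence)
    n = len(sequence)
    if n < window:
        raise ValueError("sequence shorter than the window")

    def winsum(x: np.ndarray, w: int) -> np.ndarray:
        c = np.concatenate(([0], np.cumsum(x)))
        return c[w:] - c[:-w]

    c = winsum(is_c, window)
    g = winsum(is_g, window)
    # only CG pairs lying fully inside the window count: pair starts at
    # window offsets [0, window-1)
    p = winsum(cpg[: n - 1], window - 1)[: n - window + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((c > 0) & (g > 0), p * window / np.maximum(c * g, 1), 0.0)
    gc = (c + g) / window
    return oe, gc


def detect_cgi(
    sequence: str,
    seq_id: str = "",
    window: int = 100,
    min_island: int = 200,
    oe_min: float = 0.6,
    gc_min: float = 0.5,
) -> list[CpGIsland]:
    """CpGPlot-style island scan (window 100 bp, step 1).

    Window start positions where both the obs/exp ratio and the GC fraction
    exceed their thresholds form candidate runs; a run of passing starts
    [a, b] spans the island [a, b + window).  Islands shorter than
    ``min_island`` are dropped; island statistics are recomputed over the
    full island extent.
    """
    oe, gc = _window_stats(sequence, window)
    passing = (oe > oe_min) & (gc > gc_min)
    islands: list[CpGIsland] = []
    n = len(passing)
    i = 0
    while i < n:
        if not passing[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and passing[j + 1]:
            j += 1
        start, end = i, j + window
        if end - start >= min_island:
            seg = sequence[start:end]
            n_cpg, n_c, n_g = count_cpg(seg)
            ratio = n_cpg * len(seg) / (n_c * n_g) if n_c and n_g else 0.0
            islands.append(
                CpGIsland(seq_id=seq_id, start=start, end=end, obs_exp=ratio,
                          gc=(n_c + n_g) / len(seg))
            )
        i = j + 1
    return islands


def merge_cgi(
    islands: list[CpGIsland], sequence: str, max_gap: int = 100
) -> list[CpGIsland]:
    """Combine islands in close proximity (gap <= max_gap, default 100 bp)
    into one large island, recomputing statistics over the union extent.
    Overlapping inputs merge unconditionally."""
    if not islands:
        return []
    islands = sorted(islands, key=lambda c: c.start)
    merged: list[list[int]] = [[islands[0].start, islands[0].end]]
    for isl in islands[1:]:
        if isl.start - merged[-1][1] <= max_gap:
            merged[-1][1] = max(merged[-1][1], isl.end)
        else:
            merged.append([isl.start, isl.end])
    out = []
    seq_id = islands[0].seq_id
    for start, end in merged:
        seg = sequence[start:end]
        n_cpg, n_c, n_g = count_cpg(seg)
        ratio = n_cpg * len(seg) / (n_c * n_g) if n_c and n_g else 0.0
        out.append(CpGIsland(seq_id=seq_id, start=start, end=end,
                             obs_exp=ratio, gc=(n_c + n_g) / len(seg)))
    return out


def islands_to_frame(islands: list[CpGIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"seq_id": c.seq_id, "start": c.start, "end": c.end,
             "length": c.length, "obs_exp": c.obs_exp, "gc": c.gc}
            for c in islands
        ],
        columns=["seq_id", "start", "end", "length", "obs_exp", "gc"],
    )
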
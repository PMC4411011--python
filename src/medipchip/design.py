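"""Core containers: array design geometry, per-array probe signals, condition layout.

A MeDIP-chip promoter tiling array represents each gene by a promoter region
around its transcription start site (TSS), covered by several close-set
oligonucleotide probes.  The study design crossed two axotomy models (SNA:
sciatic nerve axotomy, peripheral; DCA: dorsal column axotomy, central) with
injury/sham arms at 1, 3 and 7 days post surgery, plus uninjured naive animals:
12 condition sets + naive = 13 sets, hybridized in triplicate (injury, naive)
or duplicate (sham) for 33 arrays in total.

Coordinates are 0-based half-open internally; GFF I/O converts at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

INJURY_TYPES = ("SNA", "DCA")
ARMS = ("injury", "sham")
DAYS = (1, 3, 7)
NAIVE = "naive"

#: replicate arrays per set: triplicate injury and naive, duplicate sham
GROUP_SIZES = {"injury": 3, "sham": 2, NAIVE: 3}


def condition_label(injury_type: str, arm: str, day: int | None) -> str:
    """Canonical label of an array set, e.g. ``SNA_injury_d3`` or ``naive``."""
    if injury_type == NAIVE or arm == NAIVE:
        return NAIVE
    return f"{injury_type}_{arm}_d{day}"


def all_condition_labels() -> list[str]:
    """The 13 array-set labels of the full design (12 injury/sham sets + naive)."""
    labels = [
        condition_label(it, arm, day)
        for it in INJURY_TYPES
        for arm in ARMS
        for day in DAYS
    ]
    labels.append(NAIVE)
    return labels


@dataclass(frozen=True)
class ArrayCondition:
    """Identity of one physical array within the replicate design."""

    injury_type: str  # 'SNA', 'DCA' or 'naive'
    arm: str  # 'injury', 'sham' or 'naive'
    day: int | None  # 1, 3, 7 or None for naive
    replicate: int  # 1-based replicate index within the set

    @property
    def set_label(self) -> str:
        return condition_label(self.injury_type, self.arm, self.day)

    @property
    def array_id(self) -> str:
        return f"{self.set_label}_r{self.replicate}"

    @property
    def group_size(self) -> int:
        return GROUP_SIZES[self.arm if self.arm != NAIVE else NAIVE]


def full_design_conditions() -> list[ArrayCondition]:
    """All 33 array identities of the complete replicate design."""
    out: list[ArrayCondition] = []
    for it in INJURY_TYPES:
        for arm in ARMS:
            for day in DAYS:
                for r in range(1, GROUP_SIZES[arm] + 1):
                    out.append(ArrayCondition(it, arm, day, r))
    for r in range(1, GROUP_SIZES[NAIVE] + 1):
        out.append(ArrayCondition(NAIVE, NAIVE, None, r))
    return out


@dataclass
class ArrayDesign:
    """Probe-to-promoter geometry of a tiling array.

    Parameters
    ----------
    probes : DataFrame with columns ``probe_id, chrom, start, length, gene_id``
        (start 0-based; ``gene_id`` may be NA for unassigned probes).
    promoters : DataFrame with columns
        ``gene_id, chrom, tss, strand, region_start, region_end``.
    """

    probes: pd.DataFrame
    promoters: pd.DataFrame

    def __post_init__(self) -> None:
        if self.promoters["gene_id"].duplicated().any():
            raise ValueError("gene_ids must be unique")
        bad = self.promoters["region_start"] >= self.promoters["region_end"]
        if bad.any():
            raise ValueError("region_start must be < region_end")
        # probes sorted by (chrom, start): window scoring relies on it
        self.probes = self.probes.sort_values(
            ["chrom", "start"], kind="mergesort"
        ).reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return len(self.promoters)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.promoters["gene_id"])

    def probes_of_gene(self, gene_id: str) -> pd.DataFrame:
        return self.probes[self.probes["gene_id"] == gene_id]


@dataclass
class ProbeSignal:
    """One array's per-probe log2 IP/Input ratios, aligned with an ArrayDesign.

    ``log2`` holds raw (as-hybridized) ratios; ``centered`` is filled by
    biweight centering and stays None until then.
    """

    condition: ArrayCondition
    log2: np.ndarray
    centered: np.ndarray | None = None
    center_estimate: float | None = None

    @property
    def array_id(self) -> str:
        return self.condition.array_id

    @property
    def values(self) -> np.ndarray:
        """Centered values if available, raw otherwise."""
        return self.centered if self.centered is not None else self.log2

    def with_centered(self, centered: np.ndarray, center: float) -> "ProbeSignal":
        return replace(self, centered=centered, center_estimate=center)


@dataclass
class PValueTrack:
    """Per-window -log10 P scores with optional peak calls attached."""

    scores: pd.DataFrame  # columns: chrom, start, end, score [, gene_id]
    peaks: pd.DataFrame | None = None  # columns: chrom, position, score, gene_id

    def __post_init__(self) -> None:
        if (self.scores["score"] < 0).any():
            raise ValueError("-log10 P scores must be non-negative")
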
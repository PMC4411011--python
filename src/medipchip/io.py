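"""Readers and writers for the tiling-array file dialects.

Pair files are NimbleGen-style tab-delimited probe tables ('#' comments,
header row); score tracks travel as GFF3 (1-based, inclusive — converted to
the internal 0-based half-open convention at the boundary); designs, signals,
truth tables and the interactive hit map are plain tab-delimited text;
sequences are FASTA (Biopython).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import ArrayCondition, ArrayDesign, ProbeSignal
from .hits import HitTable

PAIR_PROBE_COLUMNS = ("PROBE_ID", "probe_id")
PAIR_SIGNAL_COLUMNS = ("PM", "SIGNAL", "signal")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pair files


def read_pair_file(path, probe_column: str | None = None,
                   signal_column: str | None = None) -> pd.DataFrame:
    """Read a pair-file-like probe intensity table.

    Tab-delimited with a header; lines starting with '#' are comments.
    The probe identifier and signal columns are auto-detected from the usual
    NimbleGen names (PROBE_ID, PM) unless given explicitly; any further
    columns are preserved as annotations.  Returns a frame with at least
    ``probe_id`` and ``signal``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    probe_col = probe_column or next(
        (c for c in PAIR_PROBE_COLUMNS if c in df.columns), None
    )
    if probe_col is None or probe_col not in df.columns:
        raise ParseError("pair file is missing the probe identifier column "
                         f"(looked for {probe_column or PAIR_PROBE_COLUMNS})")
    signal_col = signal_column or next(
        (c for c in PAIR_SIGNAL_COLUMNS if c in df.columns), None
    )
    if signal_col is None or signal_col not in df.columns:
        raise ParseError("pair file is missing the signal column "
                         f"(looked for {signal_column or PAIR_SIGNAL_COLUMNS})")
    out = df.rename(columns={probe_col: "probe_id", signal_col: "signal"})
    out["signal"] = pd.to_numeric(out["signal"])
    return out


def write_pair_file(table: pd.DataFrame, path, comments: list[str] | None = None
                    ) -> None:
    """Write a probe table in the pair-file dialect."""
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        table.rename(columns={"probe_id": "PROBE_ID", "signal": "PM"}).to_csv(
            fh, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# GFF score tracks (1-based inclusive on disk, 0-based half-open in memory)

GFF_COLUMNS = ["seqid", "source", "type", "start", "end", "score",
               "strand", "phase", "attributes"]


def read_gff_scores(path) -> pd.DataFrame:
    """Read a GFF3 score track into ``chrom, start, end, score [, attributes]``.

    GFF coordinates are 1-based inclusive; internal are 0-based half-open
    (start-1, end).  Score semantics (log2 vs -log10 P) are the caller's to
    tag.  An empty file yields an empty frame.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=GFF_COLUMNS, dtype={"seqid": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "score", "attributes"])
    try:
        start = df["start"].astype(np.int64) - 1
        end = df["end"].astype(np.int64)
        score = pd.to_numeric(df["score"].replace(".", np.nan))
    except (ValueError, TypeError) as exc:
        raise ParseError(f"malformed GFF coordinate or score field: {exc}") from exc
    if (start < 0).any() or (end <= start).any():
        raise ParseError("malformed GFF coordinates (need 1-based start <= end)")
    return pd.DataFrame(
        {"chrom": df["seqid"], "start": start, "end": end,
         "score": score, "attributes": df["attributes"]}
    )


def write_gff_scores(track: pd.DataFrame, path, source: str = "medipchip",
                     feature_type: str = "region") -> None:
    """Write a ``chrom, start, end, score`` frame as GFF3 (scores to 6 dp)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in track.itertuples(index=False):
            attrs = getattr(row, "attributes", None)
            if attrs is None or (isinstance(attrs, float) and np.isnan(attrs)):
                attrs = "."
            gene = getattr(row, "gene_id", None)
            if gene is not None and attrs == ".":
                attrs = f"ID={gene}"
            fh.write(
                f"{row.chrom}\t{source}\t{feature_type}\t{int(row.start) + 1}\t"
                f"{int(row.end)}\t{row.score:.6f}\t.\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# design / signal / truth tables


def write_design(design: ArrayDesign, probes_path, promoters_path) -> None:
    design.probes.to_csv(probes_path, sep="\t", index=False)
    design.promoters.to_csv(promoters_path, sep="\t", index=False)


def read_design(probes_path, promoters_path) -> ArrayDesign:
    return ArrayDesign(
        probes=pd.read_csv(probes_path, sep="\t"),
        promoters=pd.read_csv(promoters_path, sep="\t"),
    )


def write_design_gff(design: ArrayDesign, path) -> None:
    """Probe track as GFF3 (1-based inclusive)."""
    track = pd.DataFrame(
        {
            "chrom": design.probes["chrom"],
            "start": design.probes["start"],
            "end": design.probes["start"] + design.probes["length"],
            "score": 0.0,
            "attributes": "ID=" + design.probes["probe_id"].astype(str)
            + ";gene=" + design.probes["gene_id"].astype(str),
        }
    )
    write_gff_scores(track, path, feature_type="oligo")


def write_signal(signal: ProbeSignal, design: ArrayDesign, path,
                 centered: bool = False) -> None:
    """Two-column tab-delimited (probe_id, log2) signal export."""
    vals = signal.centered if centered else signal.log2
    if vals is None:
        raise ValueError("signal has no centered values yet")
    pd.DataFrame({"probe_id": design.probes["probe_id"], "log2": vals}).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_signal(path, design: ArrayDesign, condition: ArrayCondition
                ) -> ProbeSignal:
    df = pd.read_csv(path, sep="\t").set_index("probe_id")
    vals = df.loc[design.probes["probe_id"], "log2"].to_numpy(dtype=float)
    return ProbeSignal(condition=condition, log2=vals)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(sequences: list[str], ids: list[str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for s, i in zip(sequences, ids)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# interactive hit map


def write_hit_map(hit_table: HitTable, mv_records: dict | None, path) -> None:
    """Spreadsheet-style hit map: one row per gene, per-array 0/1 hits,
    per-set hit counts, MV per injury comparison.

    Counter header lines (prefix ``#``) above the data carry, per condition
    set, the counts of methylated / partly / unmethylated genes and the
    set's mean total hits — the "interactive counters" of the original
    spreadsheet, precomputed.
    """
    from .hits import classify_levels, global_methylation

    genes = hit_table.gene_ids
    data = pd.DataFrame(index=genes)
    for aid in hit_table.hits.columns:
        data[f"hit:{aid}"] = hit_table.hits[aid].astype(int)
    for label in hit_table.set_labels:
        data[f"count:{label}"] = hit_table.hit_counts(label)
    if mv_records:
        for (it, day), rec in mv_records.items():
            r = rec.set_index("gene_id")
            data[f"MV:{it}_d{day}"] = r["mv"].astype(str)
            data[f"verdict:{it}_d{day}"] = r["verdict"]

    with open(path, "w") as fh:
        for level in ("methylated", "partly", "unmethylated"):
            cells = []
            for label in hit_table.set_labels:
                k = hit_table.group_size(label)
                counts = hit_table.hit_counts(label)
                n = sum(classify_levels(int(c), k) == level for c in counts)
                cells.append(f"{label}={n}")
            fh.write(f"#counter\t{level}\t" + "\t".join(cells) + "\n")
        means = "\t".join(
            f"{label}={global_methylation(hit_table, label):.6g}"
            for label in hit_table.set_labels
        )
        fh.write(f"#counter\tmean_total_hits\t{means}\n")
        data.reset_index(names="gene_id").to_csv(fh, sep="\t", index=False)


def read_hit_map(path, arrays: pd.DataFrame) -> HitTable:
    """Rebuild a HitTable from a written hit map (per-array 0/1 columns)."""
    df = pd.read_csv(path, sep="\t", comment="#").set_index("gene_id")
    df.index.name = None
    hit_cols = [c for c in df.columns if c.startswith("hit:")]
    hits = df[hit_cols].astype(bool)
    hits.columns = [c.split(":", 1)[1] for c in hit_cols]
    hits = hits[list(arrays["array_id"])]
    return HitTable(hits=hits, arrays=arrays)
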
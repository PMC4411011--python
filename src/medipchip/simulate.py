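"""Synthetic tiling-array data with known ground truth.

Emulates the statistical structure the downstream analysis assumes: ~2.3 kb
promoter regions (1,500 bp upstream / 800 bp downstream of the TSS) tiled by
close-set probes, per-probe log2 IP/Input ratios as a centered Gaussian
baseline plus an additive enrichment at truly methylated promoters, and the
full 33-array replicate design (triplicate injury/naive, duplicate sham).

Ground truth distinguishes genes hypermethylated or hypomethylated upon injury
(optionally specific to one injury model, which is what makes a gene
"differentially methylated" between models) from constitutively methylated or
unmethylated genes.  Promoter sequences with embedded CpG islands are generated
separately for the CpG-island detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    ArrayCondition,
    ArrayDesign,
    ProbeSignal,
    full_design_conditions,
)

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the real design: triplicate injury and naive sets,
    duplicate shams, promoters spanning -1500/+800 bp around the TSS.
    ``effect_size`` is the mean log2 enrichment at a methylated promoter;
    ``noise_sd`` the per-probe Gaussian noise.  ``frac_hyper``/``frac_hypo``
    are the fractions of genes planted as injury-induced hyper-/hypomethylated;
    ``frac_both_injuries`` of those respond to both injury models (the rest
    split evenly between SNA-only and DCA-only, creating DM genes).
    ``frac_const_methylated`` of the remaining genes are methylated in every
    condition, like the small always-methylated gene group seen on real arrays.
    """

    n_genes: int = 1000
    probes_per_promoter: int = 20
    upstream: int = 1500
    downstream: int = 800
    probe_length: int = 50
    intergenic_gap: int = 1000
    effect_size: float = 1.5
    noise_sd: float = 0.3
    frac_hyper: float = 0.1
    frac_hypo: float = 0.1
    frac_both_injuries: float = 0.5
    frac_const_methylated: float = 0.02
    seed: int | None = None
    chrom: str = "chr1"

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        for name in ("n_genes", "probes_per_promoter", "upstream", "downstream"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.probes_per_promoter < 4:
            raise ValueError(
                "probes_per_promoter must be >= 4: window scoring needs at "
                "least 4 probes per window"
            )
        for name in ("frac_hyper", "frac_hypo", "frac_both_injuries",
                     "frac_const_methylated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_hyper + self.frac_hypo > 1.0:
            raise ValueError("frac_hyper + frac_hypo must not exceed 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def span(self) -> int:
        return self.upstream + self.downstream


def generate_design(config: SimulationConfig) -> ArrayDesign:
    """Lay out promoters on one chromosome and tile each with probes.

    Probes are spaced uniformly across the promoter span with +-10% jitter
    around the regular spacing, coordinates unique per chromosome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    span = config.span
    gap = config.intergenic_gap
    n = config.n_genes
    k = config.probes_per_promoter

    strands = np.where(np.arange(n) % 2 == 0, "+", "-")
    region_start = gap + np.arange(n, dtype=np.int64) * (span + gap)
    region_end = region_start + span
    # region covers [TSS-upstream, TSS+downstream) measured along the gene
    tss = np.where(strands == "+", region_start + config.upstream,
                   region_end - config.upstream)

    promoters = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n)],
            "chrom": config.chrom,
            "tss": tss,
            "strand": strands,
            "region_start": region_start,
            "region_end": region_end,
        }
    )

    spacing = span / k
    jitter = rng.uniform(-0.1 * spacing, 0.1 * spacing, size=(n, k))
    offsets = (np.arange(k) + 0.5) * spacing + jitter
    offsets = np.clip(offsets, 0, span - config.probe_length - 1)
    starts = (region_start[:, None] + offsets).astype(np.int64)
    # jitter < spacing/2, so per-promoter starts are strictly increasing
    probes = pd.DataFrame(
        {
            "probe_id": [
                f"gene{i:05d}_p{j:03d}" for i in range(n) for j in range(k)
            ],
            "chrom": config.chrom,
            "start": starts.ravel(),
            "length": config.probe_length,
            "gene_id": np.repeat(promoters["gene_id"].to_numpy(), k),
        }
    )
    return ArrayDesign(probes=probes, promoters=promoters)


def generate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Assign ground-truth methylation classes to genes.

    Returns a table with one row per gene:

    - ``label``: ``hyper`` / ``hypo`` / ``neutral``
    - ``scope``: which injury models respond (``SNA``, ``DCA`` or ``both``;
      ``none`` for neutral genes)
    - ``baseline_methylated``: state in naive and in all out-of-scope
      conditions (hyper genes start unmethylated, hypo genes methylated,
      neutral genes keep a constitutive state).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_genes
    n_hyper = round(n * config.frac_hyper)
    n_hypo = round(n * config.frac_hypo)
    gene_ids = [f"gene{i:05d}" for i in range(n)]
    order = rng.permutation(n)

    label = np.full(n, "neutral", dtype=object)
    label[order[:n_hyper]] = "hyper"
    label[order[n_hyper : n_hyper + n_hypo]] = "hypo"

    scope = np.full(n, "none", dtype=object)
    diff = order[: n_hyper + n_hypo]
    p_both = config.frac_both_injuries
    scope[diff] = rng.choice(
        ["both", "SNA", "DCA"], size=len(diff),
        p=[p_both, (1 - p_both) / 2, (1 - p_both) / 2],
    )

    baseline = np.zeros(n, dtype=bool)
    baseline[label == "hypo"] = True  # hypo: methylated until injured
    neutral = label == "neutral"
    baseline[neutral] = rng.random(neutral.sum()) < config.frac_const_methylated

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "label": label,
            "scope": scope,
            "baseline_methylated": baseline,
        }
    )


def methylation_state(truth: pd.DataFrame, condition: ArrayCondition) -> np.ndarray:
    """True per-gene methylation state (bool) under one array condition."""
    state = truth["baseline_methylated"].to_numpy().copy()
    if condition.arm == "injury":
        in_scope = (truth["scope"] == "both") | (
            truth["scope"] == condition.injury_type
        )
        flip = in_scope.to_numpy() & (truth["label"] != "neutral").to_numpy()
        state[flip] = ~state[flip]
    return state


def simulate_arrays(
    design: ArrayDesign,
    truth: pd.DataFrame,
    config: SimulationConfig,
    conditions: list[ArrayCondition] | None = None,
) -> list[ProbeSignal]:
    """Simulate per-probe log2 ratios for every array of the design.

    probe log2 = 0 + effect_size * [gene methylated in this condition]
    + Gaussian(0, noise_sd), with independent noise per replicate array.
    """
    config.validate()
    if set(design.promoters["gene_id"]) != set(truth["gene_id"]):
        raise ValueError("design and truth must share the same gene set")
    if conditions is None:
        conditions = full_design_conditions()

    truth = truth.set_index("gene_id").loc[design.promoters["gene_id"]].reset_index()
    gene_pos = {g: i for i, g in enumerate(truth["gene_id"])}
    probe_gene_idx = design.probes["gene_id"].map(gene_pos).to_numpy()

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    signals = []
    for cond in conditions:
        state = methylation_state(truth, cond)
        mean = config.effect_size * state[probe_gene_idx].astype(float)
        log2 = mean + rng.normal(0.0, config.noise_sd, size=design.n_probes)
        signals.append(ProbeSignal(condition=cond, log2=log2))
    return signals


# ---------------------------------------------------------------------------
# promoter sequences with embedded CpG islands


def _markov_sequence(
    rng: np.random.Generator,
    length: int,
    base_probs: np.ndarray,
    cpg_factor: float,
) -> np.ndarray:
    """First-order chain: after a C, the G probability is scaled by cpg_factor
    and the remainder renormalized over A/C/T.  cpg_factor < 1 depletes CpG
    (mammalian background), > stationary restores or enriches it."""
    p = base_probs / base_probs.sum()
    after_c = p.copy()
    after_c[2] = min(cpg_factor * p[2], 0.95)
    rest = 1.0 - after_c[2]
    other = np.array([0, 1, 3])
    after_c[other] = p[other] / p[other].sum() * rest

    u = rng.random(length)
    seq = np.empty(length, dtype=np.int8)
    cum_p = np.cumsum(p)
    cum_c = np.cumsum(after_c)
    prev_is_c = False
    for i in range(length):
        cum = cum_c if prev_is_c else cum_p
        b = int(np.searchsorted(cum, u[i], side="right"))
        b = min(b, 3)
        seq[i] = b
        prev_is_c = b == 1
    return seq


def _island_segment(
    rng: np.random.Generator, length: int, obs_exp: float, gc: float
) -> np.ndarray:
    """CpG-island segment with near-constant local CpG density.

    The target CpG count (obs_exp * gc^2 * length / 4, from the obs/exp
    definition with #C = #G = gc*length/2) is planted as evenly spaced CG
    dinucleotides — mimicking the regular CpG spacing of real islands — and
    the remaining positions are filled i.i.d. at the GC level that meets the
    overall target, suppressing G after C so no unplanned CpGs arise.  Even
    spacing keeps every 100 bp sub-window near the target obs/exp, which is
    what makes the island detectable by a sliding-window scan.
    """
    n_cpg = max(1, round(obs_exp * gc * gc / 4.0 * length))
    planted_bases = 2 * n_cpg
    if planted_bases >= length:
        raise ValueError("infeasible island composition: CpG target too dense")
    fill_len = length - planted_bases
    n_gc_fill = round(gc * length) - planted_bases
    if not 0 <= n_gc_fill <= fill_len:
        raise ValueError("infeasible island composition: GC target unreachable")

    # one CG unit per tile, fill bases dealt round-robin from the exact-count
    # multiset so every tile — hence every 100 bp sub-window — carries nearly
    # the same composition; only the within-tile order is random
    n_c = n_gc_fill // 2
    n_g = n_gc_fill - n_c
    n_a = (fill_len - n_gc_fill) // 2
    n_t = fill_len - n_gc_fill - n_a
    fill = np.repeat(np.int8([0, 1, 2, 3]), [n_a, n_c, n_g, n_t])
    tile_fills = sorted((fill[i::n_cpg] for i in range(n_cpg)), key=len)

    base_len, extra = divmod(length, n_cpg)
    tile_lens = sorted([base_len + (1 if i < extra else 0) for i in range(n_cpg)])
    parts = []
    is_planted_parts = []
    for tlen, tfill in zip(tile_lens, tile_fills):
        assert len(tfill) == tlen - 2
        parts.append(np.concatenate(([1, 2], rng.permutation(tfill))))
        is_planted_parts.append(
            np.concatenate(([True, True], np.zeros(tlen - 2, dtype=bool)))
        )
    order = rng.permutation(n_cpg)
    seq = np.concatenate([parts[i] for i in order]).astype(np.int8)
    is_planted = np.concatenate([is_planted_parts[i] for i in order])
    fill_pos = np.flatnonzero(~is_planted)

    # break accidental fill CpGs (only planted units may form CG pairs) by
    # swapping the offending base with a random A/T fill position
    at_pool = [int(p) for p in fill_pos if seq[p] in (0, 3)]
    for _ in range(50):
        bad = np.flatnonzero(
            (seq[:-1] == 1) & (seq[1:] == 2) & ~(is_planted[:-1] & is_planted[1:])
        )
        if bad.size == 0 or not at_pool:
            break
        for i in bad:
            pos = i + 1 if not is_planted[i + 1] else i
            j = at_pool[int(rng.integers(len(at_pool)))]
            seq[pos], seq[j] = seq[j], seq[pos]
            at_pool[at_pool.index(j)] = pos
    return seq


def generate_promoter_sequences(
    n: int,
    seq_length: int = 3000,
    island_length: int = 300,
    island_obs_exp: float = 0.8,
    island_gc: float = 0.6,
    background_gc: float = 0.42,
    cpg_depletion: float = 0.25,
    seed: int | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Random promoter-like sequences, each with one embedded CpG island.

    Background is CpG-depleted (G down-weighted after C by ``cpg_depletion``);
    the island segment is generated with elevated GC and a CpG transition
    tuned so its measured obs/exp ratio lands near ``island_obs_exp``.

    Returns the sequences and a table of true island intervals
    (``seq_id, start, end``, 0-based half-open).
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducibility")
    if n < 0:
        raise ValueError("n must be >= 0")
    if island_length < 1:
        raise ValueError("island length must be >= 1")
    if island_length > seq_length:
        raise ValueError("island must fit in the sequence")
    if not 0 < island_gc < 1 or not 0 < background_gc < 1:
        raise ValueError("GC targets must be in (0, 1)")

    rng = np.random.default_rng(seed)
    at = (1 - background_gc) / 2
    gc = background_gc / 2
    bg_probs = np.array([at, gc, gc, at])
    # composition check up front so errors surface even for n=0 requests
    _island_segment(np.random.default_rng(0), island_length if island_length >= 8
                    else 8, island_obs_exp, island_gc)

    seqs: list[str] = []
    rows = []
    for i in range(n):
        bg = _markov_sequence(rng, seq_length, bg_probs, cpg_depletion)
        start = int(rng.integers(0, seq_length - island_length + 1))
        island = _island_segment(rng, island_length, island_obs_exp, island_gc)
        bg[start : start + island_length] = island
        seqs.append("".join(BASES[bg]))
        rows.append((f"promoter{i:04d}", start, start + island_length))
    intervals = pd.DataFrame(rows, columns=["seq_id", "start", "end"])
    return seqs, intervals
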
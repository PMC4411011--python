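"""Biweight centering, KS window scoring, peak calling and gene hits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from medipchip import (
    SimulationConfig,
    biweight_center,
    biweight_mean,
    call_peaks,
    gene_hits,
    generate_design,
    generate_truth,
    ks_window_scores,
    simulate_arrays,
)
from medipchip.design import ArrayCondition, ProbeSignal
from medipchip.simulate import methylation_state


class TestBiweightCenter:
    def test_constant_vector_is_degenerate_but_allowed(self):
        centered, center = biweight_center(np.array([0.7, 0.7, 0.7]))
        assert center == pytest.approx(0.7)
        np.testing.assert_allclose(centered, 0.0)

    def test_symmetric_sample_equals_arithmetic_mean(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0]) + 3.0
        assert biweight_mean(x) == pytest.approx(x.mean(), abs=1e-9)

    def test_outlier_resistance(self):
        x = np.array([0.1, -0.2, 0.05, -0.1, 0.0, 99.0])
        assert abs(biweight_mean(x)) < abs(x.mean())
        assert abs(biweight_mean(x)) < 0.2

    def test_centered_output_has_zero_biweight_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.2, 0.4, 500)
        centered, _ = biweight_center(x)
        assert abs(biweight_mean(centered)) < 1e-6

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 0.3, 300)
        once, _ = biweight_center(x)
        twice, _ = biweight_center(once)
        np.testing.assert_allclose(twice, once, atol=1e-6)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            biweight_mean(np.array([1.0]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=50),
        st.floats(-5, 5),
    )
    def test_shift_equivariance(self, values, shift):
        x = np.asarray(values)
        if np.ptp(x) == 0:
            return
        assert biweight_mean(x + shift) == pytest.approx(
            biweight_mean(x) + shift, abs=1e-6
        )


def _signal_for(design, values):
    return ProbeSignal(
        condition=ArrayCondition("naive", "naive", None, 1),
        log2=np.asarray(values, float),
        centered=np.asarray(values, float),
        center_estimate=0.0,
    )


def _dense_design(probes_per_gene=30, n_genes=2):
    """Promoters tiled densely enough that 500 bp windows hold >=4 probes."""
    import pandas as pd

    from medipchip.design import ArrayDesign

    span, gap = 2300, 3000
    rows_p, rows_g = [], []
    for g in range(n_genes):
        r0 = gap + g * (span + gap)
        rows_g.append(
            {"gene_id": f"g{g}", "chrom": "chr1", "tss": r0 + 1500,
             "strand": "+", "region_start": r0, "region_end": r0 + span}
        )
        for j, off in enumerate(np.linspace(40, span - 90, probes_per_gene)):
            rows_p.append(
                {"probe_id": f"g{g}_p{j}", "chrom": "chr1",
                 "start": int(r0 + off), "length": 50, "gene_id": f"g{g}"}
            )
    return ArrayDesign(probes=pd.DataFrame(rows_p),
                       promoters=pd.DataFrame(rows_g))


class TestWindowScores:
    def test_null_windows_rarely_exceed_threshold(self):
        """Under the null the one-sided bound keeps P(score > 2) <= 1%."""
        design = _dense_design()
        rng = np.random.default_rng(7)
        n_high = 0
        n_windows = 0
        for _ in range(60):
            sig = _signal_for(design, rng.normal(0, 0.3, design.n_probes))
            sc = ks_window_scores(sig, design, min_probes=4)
            n_windows += len(sc)
            n_high += int((sc["score"] > 2).sum())
        assert n_windows > 1000
        assert n_high / n_windows <= 0.01

    def test_shifted_window_scores_high(self):
        """>=8 probes shifted by +1.5 against sd-0.3 noise clear score 2."""
        design = _dense_design()
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 0.3, design.n_probes)
        vals[:30] += 1.5  # all of gene g0's probes
        sig = _signal_for(design, vals)
        sc = ks_window_scores(sig, design, window_bp=750, min_probes=8)
        assert (sc["n_probes"] >= 8).all()
        assert (sc.loc[sc["gene_id"] == "g0", "score"] > 2).all()

    def test_min_probes_skips_sparse_windows(self, toy_design):
        sig = _signal_for(toy_design, np.zeros(12))
        # 6 probes per 2300 bp promoter -> a 500/750 bp window holds ~1-2
        sc = ks_window_scores(sig, toy_design, window_bp=500, min_probes=4)
        assert sc.empty
        sc2 = ks_window_scores(sig, toy_design, window_bp=500, min_probes=1)
        assert not sc2.empty

    def test_window_width_bounds(self, toy_design):
        sig = _signal_for(toy_design, np.zeros(12))
        for bad in (100, 800):
            with pytest.raises(ValueError):
                ks_window_scores(sig, toy_design, window_bp=bad)

    def test_matches_brute_force_scipy_statistic_on_every_window(self):
        """Oracle: per window, the D+ statistic equals scipy's two-sample KS
        statistic computed brute-force on (window, all other probes), and the
        score is the documented one-sided bound exp(-2 n_eff D+^2) of it."""
        design = _dense_design()
        rng = np.random.default_rng(9)
        vals = rng.normal(0, 0.5, design.n_probes)
        vals[10:20] += 1.0
        sig = _signal_for(design, vals)
        sc = ks_window_scores(sig, design, window_bp=500, min_probes=2)
        assert len(sc) > 10
        probes = design.probes
        n = design.n_probes
        for row in sc.itertuples(index=False):
            inside = (
                (probes["gene_id"] == row.gene_id)
                & (probes["start"] >= row.start)
                & (probes["start"] < row.end)
            ).to_numpy()
            w, rest = vals[inside], vals[~inside]
            d_ref = stats.ks_2samp(w, rest, alternative="less").statistic
            m = inside.sum()
            n_eff = m * (n - m) / n
            p_ref = min(1.0, np.exp(-2 * n_eff * d_ref**2))
            assert row.n_probes == m
            assert row.score == pytest.approx(-np.log10(p_ref), abs=1e-9)


class TestCallPeaks:
    def _scores(self, score_list, start0=0):
        return pd.DataFrame(
            {
                "gene_id": "gA",
                "chrom": "chr1",
                "start": start0 + 100 * np.arange(len(score_list)),
                "end": start0 + 100 * np.arange(len(score_list)) + 500,
                "n_probes": 5,
                "score": score_list,
            }
        )

    def test_no_scores_above_threshold_no_peaks(self):
        assert call_peaks(self._scores([1.9, 0.5, 2.0])).empty
        assert call_peaks(pd.DataFrame(columns=["gene_id", "chrom", "start",
                                                "end", "n_probes", "score"])).empty

    def test_single_run_collapses_to_maximal_window(self):
        peaks = call_peaks(self._scores([2.5, 3.1, 2.2]), min_run=1)
        assert len(peaks) == 1
        assert peaks.loc[0, "score"] == pytest.approx(3.1)
        assert peaks.loc[0, "position"] == 100 + 250

    def test_two_runs_give_two_peaks(self):
        sc = self._scores([2.5, 2.6, 2.4, 0.1, 0.2, 2.2, 2.9, 2.3])
        peaks = call_peaks(sc, min_run=3)
        assert len(peaks) == 2
        assert list(peaks["score"]) == pytest.approx([2.6, 2.9])

    def test_short_runs_discarded_by_min_run(self):
        sc = self._scores([0.1, 2.5, 0.1, 2.2, 2.9, 2.3, 0.1])
        assert len(call_peaks(sc, min_run=3)) == 1
        assert len(call_peaks(sc, min_run=1)) == 2

    def test_matches_brute_force_run_enumeration(self):
        """Oracle: peaks equal an independent enumeration of maximal runs."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            scores = rng.uniform(0, 4, 19)
            sc = self._scores(scores)
            got = call_peaks(sc, threshold=2.0, min_run=3)
            runs, cur = [], []
            for i, s in enumerate(scores):
                if s > 2.0:
                    cur.append(i)
                else:
                    if len(cur) >= 3:
                        runs.append(cur)
                    cur = []
            if len(cur) >= 3:
                runs.append(cur)
            assert len(got) == len(runs)
            for peak, run in zip(got.itertuples(index=False), runs):
                assert peak.score == pytest.approx(max(scores[i] for i in run))

    def test_threshold_monotonicity(self, small_design, small_signals):
        sig = biweight_center(small_signals[0])
        sc = ks_window_scores(sig, small_design)
        n_hits = [
            gene_hits(call_peaks(sc, threshold=t), small_design).sum()
            for t in (1.0, 2.0, 3.0, 5.0)
        ]
        assert n_hits == sorted(n_hits, reverse=True)


class TestGeneHits:
    def test_no_peaks_all_false(self, toy_design):
        hits = gene_hits(call_peaks(pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "n_probes", "score"]
        )), toy_design)
        assert len(hits) == 2 and not hits.any()

    def test_peak_inside_region_hits_only_that_gene(self, toy_design):
        peaks = pd.DataFrame(
            [{"gene_id": "gA", "chrom": "chr1", "position": 1000,
              "start": 750, "end": 1250, "score": 3.0}]
        )
        hits = gene_hits(peaks, toy_design)
        assert hits["gA"] and not hits["gB"]

    def test_unknown_peak_ignored_with_warning(self, toy_design):
        peaks = pd.DataFrame(
            [{"gene_id": "nope", "chrom": "chr1", "position": 99999,
              "start": 0, "end": 1, "score": 3.0}]
        )
        with pytest.warns(UserWarning, match="outside"):
            hits = gene_hits(peaks, toy_design)
        assert not hits.any()


def test_recovery_on_simulated_array():
    """Effect 1.5 / sd 0.3 / 20 probes: >=95% of methylated promoters hit,
    <=2% of unmethylated promoters falsely hit, on one array."""
    from medipchip import array_hits

    cfg = SimulationConfig(n_genes=300, probes_per_promoter=20,
                           effect_size=1.5, noise_sd=0.3, seed=77)
    design, truth = generate_design(cfg), generate_truth(cfg)
    sig = simulate_arrays(design, truth, cfg)[0]
    hits = array_hits(sig, design)
    state = methylation_state(truth, sig.condition)
    meth = pd.Series(state, index=truth["gene_id"])
    sens = hits[meth[hits.index]].mean()
    fpr = hits[~meth[hits.index]].mean()
    assert sens >= 0.95
    assert fpr <= 0.02


def test_sensitivity_increases_with_effect_size():
    from medipchip import array_hits

    rates = []
    for effect in (0.0, 0.75, 1.5):
        cfg = SimulationConfig(n_genes=150, effect_size=effect, noise_sd=0.3,
                               seed=31)
        design, truth = generate_design(cfg), generate_truth(cfg)
        sig = simulate_arrays(design, truth, cfg)[0]
        hits = array_hits(sig, design)
        state = methylation_state(truth, sig.condition)
        meth = pd.Series(state, index=truth["gene_id"])
        if effect == 0.0:
            rates.append(hits.mean())  # pure false-positive rate
        else:
            rates.append(hits[meth[hits.index]].mean())
    assert rates[0] < 0.02
    assert rates[0] <= rates[1] <= rates[2]
    assert rates[2] >= 0.95
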
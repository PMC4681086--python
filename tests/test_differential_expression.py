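"""Normalization, NB Wald testing, and BH thresholding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from regulonseq.differential_expression import (CountMatrix, DEGRecord,
                                                call_degs, rpkm,
                                                run_deg_analysis,
                                                size_factors)
from regulonseq.differential_expression import \
    test_differential as nb_wald_test  # renamed so pytest does not collect it


def make_cm(arr, lengths=None, n_wt=None):
    arr = np.asarray(arr)
    n = arr.shape[1]
    n_wt = n // 2 if n_wt is None else n_wt
    cols = [f"wt_{i}" for i in range(n_wt)] + \
           [f"mut_{i}" for i in range(n - n_wt)]
    idx = [f"g{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=pd.Index(idx, name="locus_id"), columns=cols)
    lengths = pd.Series(1000 if lengths is None else lengths, index=df.index)
    return CountMatrix(df, lengths,
                       {c: ("wt" if c.startswith("wt") else "mutant")
                        for c in cols})


def bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg step-up."""
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, pvals[i] * m / rank)
        q[i] = prev
    return q


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = make_cm([[10] * 4, [50] * 4, [7] * 4, [100] * 4])
        assert np.allclose(size_factors(cm), 1.0)

    def test_doubled_library_hand_matrix(self):
        base = np.array([12, 40, 7, 101, 55])
        cm = make_cm(np.column_stack([base, base, 2 * base, 2 * base]))
        f = size_factors(cm)
        # closed form: factors proportional to (1, 1, 2, 2), geomean 1
        assert f.iloc[2] / f.iloc[0] == pytest.approx(2.0)
        assert f.iloc[0] == pytest.approx(f.iloc[1])
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(0)
        arr = rng.integers(1, 500, size=(30, 4))
        f1 = size_factors(make_cm(arr)).to_numpy()
        f2 = size_factors(make_cm(arr[rng.permutation(30)])).to_numpy()
        assert np.allclose(f1, f2)

    def test_no_all_positive_gene_errors(self):
        cm = make_cm([[0, 0, 5, 5], [5, 5, 0, 0]])
        with pytest.raises(ValueError, match="filter"):
            size_factors(cm)


class TestRPKM:
    def test_closed_form(self):
        arr = np.zeros((2, 4), dtype=int)
        arr[0] = 100
        arr[1] = 10 ** 6 - 100
        cm = make_cm(arr, lengths=[1000, 10 ** 6])
        assert rpkm(cm).iloc[0, 0] == pytest.approx(100.0)

    def test_zero_counts_zero_rpkm_and_length_scaling(self):
        cm = make_cm([[0] * 4, [100] * 4, [100] * 4],
                     lengths=[500, 1000, 2000])
        r = rpkm(cm)
        assert (r.iloc[0] == 0).all()
        assert r.iloc[1, 0] == pytest.approx(2 * r.iloc[2, 0])


class TestWaldTest:
    def test_equal_means_zero_lfc(self):
        cm = make_cm([[100, 100, 100, 100, 100, 100]] * 3)
        recs = nb_wald_test(cm)
        assert all(r.log2fc == 0 for r in recs)

    def test_large_effect_matches_mean_ratio_oracle(self):
        wt, mut = [800, 820, 790], [100, 95, 110]
        arr = np.array([wt + mut, [500] * 6, [300] * 6])
        recs = nb_wald_test(make_cm(arr))
        oracle = np.log2(np.mean(mut) / np.mean(wt))
        assert recs[0].log2fc == pytest.approx(oracle, abs=0.1)
        assert recs[0].log2fc == pytest.approx(-3.0, abs=0.1)

    def test_low_count_genes_not_tested(self):
        arr = np.array([[2, 3, 1, 2, 2, 3], [500] * 6])
        recs = nb_wald_test(make_cm(arr))
        assert recs[0].p == 1.0 and recs[0].log2fc == 0.0 and not recs[0].tested
        assert recs[1].tested

    def test_single_replicate_condition_errors(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            make_cm(np.ones((3, 3), dtype=int), n_wt=1)

    def test_null_pvalues_calibrated(self):
        """At 2000 null NB genes the p<0.05 fraction stays near nominal."""
        rng = np.random.default_rng(1)
        mu = rng.lognormal(np.log(300), 1.0, 2000)
        sf = rng.uniform(0.7, 1.3, 6)
        lam = rng.gamma(1 / 0.05, (mu[:, None] * sf[None, :]) * 0.05)
        cm = make_cm(rng.poisson(lam))
        p = np.array([r.p for r in nb_wald_test(cm) if r.tested])
        assert 0.03 <= (p < 0.05).mean() <= 0.08


class TestCallDegs:
    def test_bh_hand_example(self):
        recs = [DEGRecord("a", 2.0, 0.01), DEGRecord("b", 2.0, 0.02),
                DEGRecord("c", 2.0, 0.04)]
        out = call_degs(recs)
        assert [r.q for r in out] == pytest.approx([0.03, 0.03, 0.04])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50))
    def test_bh_matches_brute_force_oracle(self, pvals):
        recs = [DEGRecord(f"g{i}", 2.0, p) for i, p in enumerate(pvals)]
        out = call_degs(recs)
        q = np.array([r.q for r in out])
        assert np.allclose(q, bh_oracle(np.array(pvals)))
        assert (q >= np.array(pvals) - 1e-12).all()

    def test_threshold_boundary_excludes_131(self):
        recs = [DEGRecord("a", 1.31, 1e-6), DEGRecord("b", -1.32, 1e-6),
                DEGRecord("c", 5.0, 0.9)]
        out = call_degs(recs)
        assert out[0].mode == "none"          # |lfc| below 1.32
        assert out[1].mode == "activated"     # lower in the deletion strain
        assert out[2].mode == "none"          # q too high

    def test_fold_change_equivalence(self):
        # the log2 threshold corresponds to a 2.5-fold change
        assert round(2 ** 1.32, 1) == 2.5

    def test_modes_partition_all_genes(self, default_count_matrix):
        recs = run_deg_analysis(default_count_matrix)
        assert all(r.mode in ("activated", "repressed", "none") for r in recs)
        assert len(recs) == default_count_matrix.counts.shape[0]


class TestPlantedRecovery:
    def test_recall_and_fdr_on_planted_effects(self):
        """Planted |log2FC|=2 at 150 genes / 20 planted DEGs."""
        from regulonseq.synthetic_data import (SimulationConfig,
                                               generate_genome,
                                               simulate_counts)
        cfg = SimulationConfig(seed=1, genome_length=250_000, n_genes=150,
                               n_sites=10, direct_fraction=1.0,
                               n_indirect=10, lfc_direct=2.0)
        ann, truth = generate_genome(cfg)
        counts = simulate_counts(ann, truth, cfg)
        samples = [c for c in counts.columns if c != "length_bp"]
        cm = CountMatrix(counts[samples], counts["length_bp"],
                         {s: ("wt" if s.startswith("wt") else "mutant")
                          for s in samples})
        called = {r.locus_id for r in run_deg_analysis(cm)
                  if r.mode != "none"}
        planted = set(truth.all_planted)
        recall = len(called & planted) / len(planted)
        fdr = len(called - planted) / max(len(called), 1)
        assert recall >= 0.9
        assert fdr <= 0.10

    def test_mode_sign_convention(self):
        # activated = lower in the mutant (negative lfc)
        wt, mut = [1000] * 3, [100] * 3
        recs = run_deg_analysis(make_cm(np.array([wt + mut, [500] * 6,
                                                  [400] * 6])))
        assert recs[0].mode == "activated"
        recs = run_deg_analysis(make_cm(np.array([mut + wt, [500] * 6,
                                                  [400] * 6])))
        assert recs[0].mode == "repressed"
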
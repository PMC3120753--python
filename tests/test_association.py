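import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from salivaclock import (
    default_config,
    island_enrichment,
    overlap_with_probe_list,
    pearson_age_test,
    probe_age_association,
    select_significant,
    simulate_dataset,
    storey_qvalues,
    tss_offset_summary,
)
from salivaclock.io import ProbeAnnotation, ValidationError
from tests.conftest import make_beta


def _ann(probe_ids, island, tss=None):
    n = len(probe_ids)
    return ProbeAnnotation(pd.DataFrame({
        "probe_id": probe_ids, "chrom": ["1"] * n, "position": np.arange(1, n + 1),
        "gene_symbol": [f"G{i}" for i in range(n)],
        "tss_offset": tss if tss is not None else [0] * n,
        "in_cpg_island": island,
    }))


class TestPearsonAgeTest:
    def test_zero_correlation_gives_unit_p(self):
        assert pearson_age_test(0.0, 20).p == pytest.approx(1.0)

    def test_exact_fit_flagged_with_zero_p(self):
        res = pearson_age_test(1.0, 10)
        assert res.p == 0.0 and res.exact_fit

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValidationError):
            pearson_age_test(0.5, 2)

    def test_symmetry_in_sign(self):
        assert pearson_age_test(-0.6, 30).p == pytest.approx(pearson_age_test(0.6, 30).p)


class TestProbeAgeAssociation:
    AGES = [20.0, 30.0, 40.0, 50.0]

    def test_exactly_linear_probe_is_an_exact_fit(self):
        bm = make_beta([[0.2, 0.3, 0.4, 0.5]])
        tab = probe_age_association(bm, self.AGES)
        assert tab["exact_fit"].iloc[0] and tab["r"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_correlation(self):
        # centered products sum to 4.0; sqrt(500 * 0.05) = 5.0 -> r = 0.8
        bm = make_beta([[0.2, 0.3, 0.5, 0.4]])
        tab = probe_age_association(bm, self.AGES)
        assert tab["r"].iloc[0] == pytest.approx(0.8)

    def test_beta_flip_negates_r_keeps_p(self):
        bm = make_beta([[0.2, 0.3, 0.5, 0.4]])
        flipped = make_beta([[0.8, 0.7, 0.5, 0.6]])
        t1 = probe_age_association(bm, self.AGES)
        t2 = probe_age_association(flipped, self.AGES)
        assert t2["r"].iloc[0] == pytest.approx(-t1["r"].iloc[0])
        assert t2["p"].iloc[0] == pytest.approx(t1["p"].iloc[0])
        assert t2["direction"].iloc[0] == "-"

    def test_constant_probe_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            probe_age_association(make_beta([[0.5, 0.5, 0.5, 0.5]]), self.AGES)


class TestStoreyQvalues:
    def test_single_p_with_null_proportion_one(self):
        assert storey_qvalues([0.05], pi0_method="one")[0] == pytest.approx(0.05)

    def test_step_up_arithmetic_matches_bh(self):
        q = storey_qvalues([0.01, 0.04, 0.03, 0.02], pi0_method="one")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_pi0_one_equals_bh_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = rng.integers(5, 400)
            p = rng.uniform(0, 1, m) ** rng.uniform(0.5, 3)
            q = storey_qvalues(p, pi0_method="one")
            bh = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            storey_qvalues([0.5, 1.2])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_q_monotone_in_p_order_and_bounded(self, pvals):
        q = storey_qvalues(pvals, pi0_method="one")
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1 + 1e-12)

    def test_smoother_pi0_near_one_on_uniform_nulls(self):
        rng = np.random.default_rng(1)
        from salivaclock.association import estimate_pi0

        pi0s = [estimate_pi0(rng.uniform(0, 1, 2000)) for _ in range(5)]
        assert np.mean(pi0s) == pytest.approx(1.0, abs=0.1)


class TestSelectSignificant:
    def _table(self, q, r=None):
        n = len(q)
        return pd.DataFrame({"r": r if r is not None else np.linspace(-0.9, 0.9, n),
                             "q": q}, index=[f"p{i}" for i in range(n)])

    def test_all_large_q_selects_nothing(self):
        _, s = select_significant(self._table([0.5] * 4))
        assert s.n_selected == 0

    def test_unit_cut_selects_everything(self):
        _, s = select_significant(self._table([0.5] * 4), q_cut=1.0)
        assert s.n_selected == 4

    def test_reports_min_abs_r_and_direction_split(self):
        tab = self._table([0.01, 0.01, 0.9], r=[0.6, -0.8, 0.1])
        _, s = select_significant(tab)
        assert s.min_abs_r == pytest.approx(0.6)
        assert (s.n_positive, s.n_negative) == (1, 1)


class TestIslandEnrichment:
    def test_diagonal_table_enumeration(self):
        ann = _ann(["a", "b", "c", "d"], island=[True, True, False, False])
        table, _, p = island_enrichment(["a", "b"], ann, ["a", "b", "c", "d"])
        np.testing.assert_array_equal(table, [[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 3)

    def test_matched_proportions_give_p_one(self):
        ids = [f"x{i}" for i in range(8)]
        ann = _ann(ids, island=[True, False] * 4)
        _, _, p = island_enrichment(ids[:4], ann, ids)
        assert p == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 12, 4)
            ids = [f"x{i}" for i in range(a + b + c + d)]
            island = [True] * a + [False] * b + [True] * c + [False] * d
            ann = _ann(ids, island=island)
            table, _, p = island_enrichment(ids[: a + b], ann, ids)
            # two-sided Fisher: sum of hypergeometric probabilities <= observed
            M, n, N = a + b + c + d, a + c, a + b
            probs = hypergeom.pmf(np.arange(max(0, N - (M - n)), min(n, N) + 1), M, n, N)
            obs = hypergeom.pmf(a, M, n, N)
            oracle = probs[probs <= obs * (1 + 1e-9)].sum()
            assert p == pytest.approx(oracle, abs=1e-12)

    def test_empty_selection_rejected(self):
        ann = _ann(["a"], island=[True])
        with pytest.raises(ValidationError):
            island_enrichment([], ann, ["a"])


class TestTssOffsetSummary:
    def test_median_of_three_upstream_offsets(self):
        ann = _ann(["a", "b", "c"], island=[True] * 3, tss=[-300, -238, -100])
        med, wording = tss_offset_summary(["a", "b", "c"], ann)
        assert med == -238 and wording == "238 bp upstream of the TSS"

    def test_single_probe_is_its_own_median(self):
        ann = _ann(["a"], island=[True], tss=[120])
        med, wording = tss_offset_summary(["a"], ann)
        assert med == 120 and "downstream" in wording

    def test_even_count_uses_midpoint_convention(self):
        ann = _ann(["a", "b"], island=[True] * 2, tss=[-100, -300])
        assert tss_offset_summary(["a", "b"], ann)[0] == -200


class TestOverlap:
    def test_basic_intersection(self):
        assert overlap_with_probe_list(["A", "B", "C"], ["B", "C", "D"])[0] == 2

    def test_disjoint_lists(self):
        assert overlap_with_probe_list(["A"], ["B"])[0] == 0

    def test_direction_matching_restricts(self):
        n, ids = overlap_with_probe_list(
            ["A", "B"], ["A", "B"],
            selected_directions={"A": "+", "B": "-"},
            external_directions={"A": "+", "B": "+"},
        )
        assert (n, ids) == (1, ["A"])

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(0)
        a = [f"x{i}" for i in rng.integers(0, 50, 30)]
        b = [f"x{i}" for i in rng.integers(0, 50, 30)]
        naive = {u for u in a for v in b if u == v}
        assert set(overlap_with_probe_list(a, b)[1]) == naive


class TestFdrProperties:
    def test_fully_null_data_yields_almost_no_calls(self):
        """FDR control: with no planted signal, q<0.05 calls are ~0."""
        good = 0
        for seed in range(10):
            cfg = default_config(seed=seed, n_probes=5000, module_sizes=(),
                                 n_age_probes=0, n_replicate_samples=0,
                                 batch_shift_sd=0.0, batch_scale_sd=0.0)
            bm, sheet, _, _ = simulate_dataset(cfg)
            tab = probe_age_association(bm, sheet.ages_for(bm.sample_ids))
            q = storey_qvalues(tab["p"].to_numpy())
            good += (q < 0.05).sum() <= 1
        assert good >= 9

    def test_selection_threshold_r_decreases_with_sample_size(self):
        """Power monotonicity: the min |r| among q<0.05 calls shrinks as n grows."""
        def min_r(n, seed=0):
            cfg = default_config(seed=seed, n_pairs=0, n_controls_m=n, n_controls_f=0,
                                 n_probes=1000, module_sizes=(), n_age_probes=60,
                                 n_replicate_samples=0, batch_shift_sd=0.0,
                                 batch_scale_sd=0.0)
            bm, sheet, _, _ = simulate_dataset(cfg)
            tab = probe_age_association(bm, sheet.ages_for(bm.sample_ids))
            tab["q"] = storey_qvalues(tab["p"].to_numpy())
            _, s = select_significant(tab)
            return s.min_abs_r
        assert min_r(60) < min_r(20)
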
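import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.metrics import adjusted_rand_score

from salivaclock import (
    NetworkConfig,
    detect_modules,
    module_age_stats,
    module_eigenloci,
    signed_adjacency,
    topological_overlap,
)
from salivaclock.io import ValidationError
from salivaclock.network import ModuleAssignment, ModuleDetector, linkage_to_text
from tests.conftest import make_beta


def brute_force_tom(A):
    """Independent triple-loop TOM oracle."""
    n = A.shape[0]
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            ki = sum(A[i, u] for u in range(n) if u != i)
            kj = sum(A[j, u] for u in range(n) if u != j)
            T[i, j] = (l + A[i, j]) / (min(ki, kj) + 1 - A[i, j])
    return T


def random_adjacency(n, seed):
    rng = np.random.default_rng(seed)
    A = rng.uniform(0, 1, (n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    return A


class TestSignedAdjacency:
    @pytest.mark.parametrize("c,beta,expected", [
        (1.0, 6, 1.0),
        (-1.0, 6, 0.0),
        (0.0, 6, 0.5**6),
    ])
    def test_closed_form_values(self, c, beta, expected):
        C = np.array([[1.0, c], [c, 1.0]])
        A = signed_adjacency(C, beta)
        assert A[0, 1] == pytest.approx(expected)
        assert A[0, 0] == 1.0

    def test_monotone_in_correlation(self):
        cs = np.linspace(-1, 1, 41)
        a = [(signed_adjacency(np.array([[1, c], [c, 1.0]]), 12))[0, 1] for c in cs]
        assert np.all(np.diff(a) >= 0)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValidationError):
            signed_adjacency(np.array([[1.0, 0.2], [0.5, 1.0]]), 6)


class TestTopologicalOverlap:
    def test_three_node_hand_computation(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 1.0)
        T = topological_overlap(A)
        assert T[0, 1] == pytest.approx((0.25 + 0.5) / (1 + 1 - 0.5))

    def test_clique_of_unit_adjacency_has_unit_tom(self):
        A = np.ones((4, 4))
        assert np.allclose(topological_overlap(A), 1.0)

    @pytest.mark.parametrize("n,seed", [(6, 0), (6, 1), (20, 2)])
    def test_matches_brute_force_oracle(self, n, seed):
        A = random_adjacency(n, seed)
        assert np.max(np.abs(topological_overlap(A) - brute_force_tom(A))) < 1e-12

    def test_tom_bounded_by_one(self):
        for seed in range(5):
            T = topological_overlap(random_adjacency(10, seed))
            assert T.max() <= 1 + 1e-12

    def test_equals_adjacency_without_shared_neighbours(self):
        # two disjoint edges: no common neighbours anywhere
        A = np.eye(4)
        A[0, 1] = A[1, 0] = 0.7
        A[2, 3] = A[3, 2] = 0.4
        T = topological_overlap(A)
        assert T[0, 1] == pytest.approx(0.7)
        assert T[2, 3] == pytest.approx(0.4)

    def test_out_of_range_adjacency_rejected(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 1.5
        with pytest.raises(ValidationError):
            topological_overlap(A)


def planted_blocks(seed, n_samples=60, block=50, within_sd=0.45):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b in range(2):
        f = rng.normal(0, 1, n_samples)
        for _ in range(block):
            rows.append(f + rng.normal(0, within_sd, n_samples))
            labels.append(b)
    return make_beta(expit(0.5 * np.array(rows))), labels


class TestDetectModules:
    def test_planted_two_block_recovery_is_exact(self):
        bm, truth = planted_blocks(seed=0)
        assignment, _ = detect_modules(bm, NetworkConfig())
        assert adjusted_rand_score(truth, list(assignment.labels)) == 1.0
        assert set(assignment.sizes) == {"turquoise", "blue"}

    def test_iid_noise_is_mostly_grey(self):
        grey = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            bm = make_beta(expit(rng.normal(0, 0.5, (200, 50))))
            assignment, _ = detect_modules(bm, NetworkConfig(min_module_size=30))
            grey.append(assignment.sizes.get("grey", 0) / 200)
        assert np.mean(grey) >= 0.8

    def test_perfectly_comethylated_probes_form_one_module(self):
        rng = np.random.default_rng(3)
        f = rng.normal(0, 1, 40)
        rows = [f] * 35  # identical profiles: correlation exactly 1
        bm = make_beta(expit(0.4 * np.array(rows)))
        assignment, _ = detect_modules(bm, NetworkConfig())
        assert assignment.sizes == {"turquoise": 35}

    def test_labels_invariant_to_probe_order(self):
        bm, _ = planted_blocks(seed=5)
        perm = np.random.default_rng(0).permutation(len(bm.probe_ids))
        shuffled = make_beta(bm.values[perm],
                             probe_ids=[bm.probe_ids[i] for i in perm])
        a1, _ = detect_modules(bm)
        a2, _ = detect_modules(shuffled)
        joined = a1.labels.to_frame("m1").join(a2.labels.rename("m2"))
        assert adjusted_rand_score(joined["m1"], joined["m2"]) == 1.0

    def test_constant_probe_instructs_to_filter(self):
        X = np.full((40, 10), 0.5)
        with pytest.raises(ValidationError, match="filter"):
            detect_modules(make_beta(X))

    def test_dendrogram_export_is_nested_text(self):
        bm, _ = planted_blocks(seed=1, block=20)
        _, Z = detect_modules(bm)
        text = linkage_to_text(Z, bm.probe_ids)
        assert text.endswith(";") and text.count("(") == len(bm.probe_ids) - 1


class TestEigenloci:
    def _assignment(self, bm, label="turquoise"):
        return ModuleAssignment(pd.Series(label, index=bm.probe_ids, name="module"))

    def test_identical_probes_give_variance_explained_one(self):
        rng = np.random.default_rng(0)
        profile = rng.uniform(0.2, 0.8, 20)
        bm = make_beta(np.tile(profile, (5, 1)))
        el = module_eigenloci(bm, self._assignment(bm))[0]
        assert el.variance_explained == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(el.scores, z / np.linalg.norm(z), atol=1e-10)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        bm = make_beta(expit(rng.normal(0, 0.5, (4, 15))))
        el = module_eigenloci(bm, self._assignment(bm))[0]
        X = bm.values
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        w, V = np.linalg.eigh(Z.T @ Z)       # sample-sample covariance (scaled)
        lead = V[:, -1]
        agree = min(np.max(np.abs(el.scores - lead)), np.max(np.abs(el.scores + lead)))
        assert agree < 1e-10
        assert el.variance_explained == pytest.approx(w[-1] / w.sum())

    def test_sign_convention_survives_global_flip(self):
        rng = np.random.default_rng(2)
        X = expit(rng.normal(0, 0.5, (6, 12)))
        el1 = module_eigenloci(make_beta(X), self._assignment(make_beta(X)))[0]
        el2 = module_eigenloci(make_beta(1 - X), self._assignment(make_beta(1 - X)))[0]
        # flipping beta flips every standardized profile; the mean-profile
        # sign rule flips the eigenlocus along with it
        np.testing.assert_allclose(el1.scores, -el2.scores, atol=1e-10)

    def test_zero_variance_probe_rejected(self):
        X = np.vstack([np.full(10, 0.5), np.linspace(0.2, 0.8, 10)])
        bm = make_beta(X)
        with pytest.raises(ValidationError, match="zero-variance"):
            module_eigenloci(bm, self._assignment(bm))

    def test_planted_one_factor_module_tracks_latent_factor(self):
        rng = np.random.default_rng(4)
        f = rng.normal(0, 1, 40)
        rows = [f * rng.uniform(0.6, 1.4) + rng.normal(0, 0.3, 40) for _ in range(50)]
        bm = make_beta(expit(0.4 * np.array(rows)))
        el = module_eigenloci(bm, self._assignment(bm))[0]
        assert abs(np.corrcoef(el.scores, f)[0, 1]) > 0.95


class TestModuleAgeStats:
    def test_eigenlocus_equal_to_age_has_unit_correlation(self):
        from salivaclock.network import Eigenlocus

        ages = np.linspace(20, 60, 10)
        scores = (ages - ages.mean()) / np.linalg.norm(ages - ages.mean())
        el = Eigenlocus("turquoise", [f"s{i}" for i in range(10)], scores, 0.8)
        stats = module_age_stats([el], ages)
        assert stats.loc["turquoise", "r"] == pytest.approx(1.0)

    def test_bonferroni_multiplies_by_module_count(self):
        from salivaclock.network import Eigenlocus

        rng = np.random.default_rng(0)
        ages = np.linspace(20, 60, 30)
        els = [Eigenlocus(m, [f"s{i}" for i in range(30)],
                          rng.normal(0, 1, 30), 0.5)
               for m in ["turquoise", "blue", "brown", "yellow", "green"]]
        stats = module_age_stats(els, ages)
        for m in stats.index:
            assert stats.loc[m, "p_bonferroni"] == pytest.approx(
                min(1.0, stats.loc[m, "p"] * 5))

    def test_planted_age_module_recovered_at_study_scale(self):
        """A module whose factor is linear in age at target r=0.6, n=34."""
        from salivaclock import calibrate_slope

        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 34
            ages = rng.uniform(21, 55, n)
            slope = calibrate_slope(0.6, ages.std(), 1.0)
            f = slope * ages + rng.normal(0, 1.0, n)
            rows = [f * rng.uniform(0.8, 1.2) + rng.normal(0, 0.4, n)
                    for _ in range(40)]
            bm = make_beta(expit(0.4 * np.array(rows)))
            asg = ModuleAssignment(pd.Series("green", index=bm.probe_ids))
            el = module_eigenloci(bm, asg)[0]
            r = module_age_stats([el], ages).loc["green", "r"]
            hits += 0.4 <= r <= 0.8
        assert hits >= 18
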
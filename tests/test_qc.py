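"""Missingness/MAF filters, IBS distances, dendrogram, VIF pruning and the
trio Mendelian-error audit."""

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

from wgva.containers import MISSING, CohortDesign, GenotypeMatrix
from wgva.qc import (PruneConfig, dendrogram, filter_maf, filter_missingness,
                     ibs_distance, mendel_errors, vif_prune)
from wgva.simulate import SimulationConfig, simulate_cohort


def toy_matrix(dosages, chrom=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n = dosages.shape[0]
    variants = pd.DataFrame({
        "CHROM": chrom if chrom is not None else ["chr1"] * n,
        "POS": np.arange(1, n + 1) * 1000,
        "REF": ["A"] * n, "ALT": ["T"] * n, "IS_INDEL": [False] * n,
    })
    return GenotypeMatrix(dosages=dosages, variants=variants,
                          samples=[f"s{i}" for i in range(dosages.shape[1])])


class TestMarginalFilters:
    def test_missingness_boundary_at_ten_percent(self):
        row_10 = np.r_[np.full(10, MISSING), np.ones(90, dtype=int)]
        row_11 = np.r_[np.full(11, MISSING), np.ones(89, dtype=int)]
        d = np.vstack([row_10, row_11]).astype(np.int8)
        assert list(filter_missingness(d, 0.10)) == [0]

    def test_no_missing_keeps_everything(self):
        d = np.ones((5, 20), dtype=np.int8)
        assert len(filter_missingness(d)) == 5

    def test_zero_tolerance_removes_any_missing(self):
        d = np.ones((2, 10), dtype=np.int8)
        d[1, 0] = MISSING
        assert list(filter_missingness(d, 0.0)) == [0]

    def test_maf_boundary_inclusive(self):
        # 100 samples: 1 het = MAF 0.005 (dropped), 2 het = 0.01 (kept)
        low = np.r_[np.ones(1, dtype=int), np.zeros(99, dtype=int)]
        edge = np.r_[np.ones(2, dtype=int), np.zeros(98, dtype=int)]
        d = np.vstack([low, edge]).astype(np.int8)
        assert list(filter_maf(d, 0.01)) == [1]

    def test_monomorphic_always_removed(self):
        d = np.zeros((1, 50), dtype=np.int8)
        assert len(filter_maf(d, 0.01)) == 0

    def test_all_het_kept_at_any_threshold(self):
        d = np.ones((1, 50), dtype=np.int8)
        assert len(filter_maf(d, 0.5)) == 1


class TestIbsDistance:
    def test_identical_vectors_distance_zero(self):
        dist = ibs_distance(np.array([[1, 1], [2, 2], [0, 0]], dtype=np.int8))
        assert dist.iloc[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        d = np.array([[0, 2]] * 7, dtype=np.int8)
        assert ibs_distance(d).iloc[0, 1] == 1.0

    def test_single_site_het_vs_hom(self):
        d = np.array([[1, 2]], dtype=np.int8)
        assert ibs_distance(d).iloc[0, 1] == 0.5

    def test_symmetry_zero_diagonal_and_range(self, rng):
        d = rng.integers(0, 3, size=(100, 12)).astype(np.int8)
        dist = ibs_distance(d).to_numpy()
        assert np.allclose(dist, dist.T)
        assert np.all(np.diag(dist) == 0)
        assert dist.min() >= 0 and dist.max() <= 1

    def test_triangle_inequality_without_missing(self, rng):
        d = rng.integers(0, 3, size=(60, 8)).astype(np.int8)
        m = ibs_distance(d).to_numpy()
        n = m.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-12

    def test_zero_overlap_pair_reported(self):
        d = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
        with pytest.raises(ValueError, match="s0.*s1"):
            ibs_distance(d, ["s0", "s1"])

    def test_missing_cells_use_pairwise_overlap(self):
        d = np.array([[0, 2], [2, MISSING], [1, 1]], dtype=np.int8)
        # only sites 0 and 2 count: (|0-2| + |1-1|) / (2*2) = 0.5
        assert ibs_distance(d).iloc[0, 1] == 0.5


class TestDendrogram:
    def test_two_samples_form_cherry_with_half_distance_branches(self):
        dist = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["a", "b"],
                            columns=["a", "b"])
        newick, _ = dendrogram(dist)
        tree = skbio.TreeNode.read([newick])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"a": pytest.approx(0.2), "b": pytest.approx(0.2)}

    def test_duplicate_samples_merge_first_at_height_zero(self):
        m = np.array([[0.0, 0.0, 0.5], [0.0, 0.0, 0.5], [0.5, 0.5, 0.0]])
        dist = pd.DataFrame(m, index=list("abc"), columns=list("abc"))
        _, Z = dendrogram(dist)
        assert Z[0, 2] == 0.0 and {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_breed_partition_recovered_exactly(self):
        """Clustering the IBS tree of three diverged breeds recovers the
        breed labels (adjusted Rand index 1)."""
        cfg = SimulationConfig(seed=21, n_variants=2000, n_breeds=3,
                               breed_sizes=(10, 10, 10), case_breeds=(0,),
                               n_trios=0, causal=None, breed_fst=0.2,
                               missing_rate=0.0, ld_rho=0.0)
        matrix, design = simulate_cohort(cfg)
        dist = ibs_distance(matrix.dosages, list(matrix.samples))
        _, Z = dendrogram(dist)
        found = fcluster(Z, t=3, criterion="maxclust")
        truth = [design.breed_of[s] for s in matrix.samples]
        assert adjusted_rand_score(truth, found) == 1.0

    def test_single_sample_rejected(self):
        dist = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            dendrogram(dist)


# ---------------------------------------------------------------------------
# VIF pruning vs a brute-force least-squares oracle
# ---------------------------------------------------------------------------

def _oracle_r2(y, others):
    """R^2 of y on [1, others] by explicit normal-equation least squares."""
    A = np.column_stack([np.ones(len(y))] + [o for o in others])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        return 0.0
    return 1.0 - (resid @ resid) / sst


def oracle_prune(X, threshold):
    """Single-window pruning by explicit least squares at every iteration."""
    kept = list(range(X.shape[0]))
    while len(kept) > 1:
        vifs = []
        for j in kept:
            others = [X[k] for k in kept if k != j]
            r2 = min(_oracle_r2(X[j], others), 1.0)
            vifs.append(np.inf if r2 > 1 - 1e-12 else 1.0 / (1.0 - r2))
        worst = max(vifs)
        if not worst > threshold:
            break
        drop = max(i for i, v in enumerate(vifs)
                   if v == worst or (np.isinf(v) and np.isinf(worst)))
        del kept[drop]
    return kept


def random_window(rng, n_var=8, n_obs=60):
    """Random dosage window with planted correlation and duplicates."""
    X = rng.integers(0, 3, size=(n_var, n_obs)).astype(np.int8)
    style = rng.integers(3)
    if style == 1:       # duplicate one variant exactly
        X[rng.integers(1, n_var)] = X[0]
    elif style == 2:     # noisy copies of a core variant
        for j in range(1, n_var, 2):
            mask = rng.random(n_obs) < 0.85
            X[j] = np.where(mask, X[0], X[j])
    return X


class TestVifPrune:
    def test_uncorrelated_window_keeps_everything(self, rng):
        X = rng.integers(0, 3, size=(8, 500)).astype(np.int8)
        kept = vif_prune(toy_matrix(X), PruneConfig(8, 1, 2.0))
        assert len(kept) == 8

    def test_exact_duplicate_removes_one_copy_keeping_lower_index(self, rng):
        X = rng.integers(0, 3, size=(4, 80)).astype(np.int8)
        X[2] = X[0]
        kept = vif_prune(toy_matrix(X), PruneConfig(4, 1, 2.0))
        assert 0 in kept and 2 not in kept

    def test_matches_least_squares_oracle_on_random_windows(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = random_window(rng)
            kept = vif_prune(toy_matrix(X), PruneConfig(8, 1, 2.0))
            assert list(kept) == oracle_prune(X.astype(float), 2.0), f"seed {seed}"

    def test_idempotent_when_window_covers_the_variants(self, rng):
        """Within one window, every survivor has VIF <= threshold given the
        other survivors, so re-pruning the kept set removes nothing.  (The
        global sliding-window procedure is not idempotent in general: removal
        is global while VIF acceptance is window-local.)"""
        X = rng.integers(0, 3, size=(30, 100)).astype(np.int8)
        X[5] = X[0]
        for j in range(10, 30, 3):
            mask = rng.random(100) < 0.9
            X[j] = np.where(mask, X[j - 1], X[j])
        cfg = PruneConfig(window_size=30, step_size=5, vif_threshold=2.0)
        matrix = toy_matrix(X)
        kept = vif_prune(matrix, cfg)
        assert len(kept) < 30
        again = vif_prune(matrix.take_variants(kept), cfg)
        assert len(again) == len(kept)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PruneConfig(window_size=3, step_size=5)
        with pytest.raises(ValueError):
            PruneConfig(vif_threshold=1.0)


class TestMendelErrors:
    def _design(self, n_samples=3):
        ids = ["o", "s", "d"]
        return CohortDesign(sample_ids=ids,
                            breed_of={i: "b" for i in ids},
                            status_of={i: "control" for i in ids},
                            trios=[("o", "s", "d")])

    @pytest.mark.parametrize("offspring,sire,dam,errors", [
        (1, 0, 2, 0),   # forced heterozygote
        (2, 0, 0, 1),   # impossible
        (1, 0, 0, 1),   # impossible
        (0, 0, 2, 1),   # impossible
        (2, 1, 2, 0),
        (2, 0, 1, 1),
        (0, 2, 2, 1),
    ])
    def test_single_site_classification(self, offspring, sire, dam, errors):
        m = toy_matrix(np.array([[offspring, sire, dam]], dtype=np.int8))
        out = mendel_errors(m, self._design())
        assert out.loc[0, "n_errors"] == errors
        assert out.loc[0, "per_meiosis_rate"] == errors / 2.0

    def test_sites_with_missing_member_are_skipped(self):
        m = toy_matrix(np.array([[2, MISSING, 0], [1, 0, 2]], dtype=np.int8))
        out = mendel_errors(m, self._design())
        assert out.loc[0, "n_sites"] == 1 and out.loc[0, "n_errors"] == 0

    def test_error_free_simulation_is_mendel_clean(self, clean_cohort):
        matrix, design = clean_cohort
        out = mendel_errors(matrix, design)
        assert (out["n_errors"] == 0).all()
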
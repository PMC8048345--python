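import numpy as np
import pytest

from trajsurv.gak import (GAKParams, NoAlignmentError, cross_distance_matrix,
                          gak_distance, gak_log_kernel, local_cost,
                          pam_cluster, select_k, sigma_heuristic)
from trajsurv.imputation import CompleteSeriesSet, TimeGrid
from trajsurv.survival import SurvivalTable
from _oracles import gak_kernel_enumerated, gak_local_log_kernel, pam_exhaustive_k2


def make_series_set(arr, patients=None):
    arr = np.asarray(arr, dtype=float)
    n, q, p = arr.shape
    if patients is None:
        patients = tuple(f"P{i:02d}" for i in range(n))
    return CompleteSeriesSet(arr, np.zeros(arr.shape, dtype=np.int8),
                             tuple(patients), tuple(f"G{j}" for j in range(p)),
                             TimeGrid(tuple(range(q))))


# ---------------------------------------------------------------------------
# local cost
# ---------------------------------------------------------------------------

def test_local_cost_zero_diagonal_and_univariate_abs():
    rng = np.random.default_rng(0)
    s = rng.normal(size=(5, 3))
    assert np.allclose(np.diag(local_cost(s, s)), 0.0)
    a, b = rng.normal(size=(4, 1)), rng.normal(size=(6, 1))
    np.testing.assert_allclose(local_cost(a, b),
                               np.abs(a[:, 0][:, None] - b[:, 0][None, :]))


def test_local_cost_matches_double_loop_oracle():
    rng = np.random.default_rng(1)
    a, b = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
    lcm = local_cost(a, b)
    for q in range(4):
        for r in range(5):
            assert lcm[q, r] == pytest.approx(np.linalg.norm(a[q] - b[r]))


def test_local_cost_rejects_gene_mismatch():
    with pytest.raises(ValueError):
        local_cost(np.zeros((3, 2)), np.zeros((3, 4)))


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

def test_single_pair_kernel_is_local_log_kernel():
    rng = np.random.default_rng(2)
    a, b = rng.normal(size=(1, 3)), rng.normal(size=(1, 3))
    params = GAKParams(sigma=1.3)
    expected = gak_local_log_kernel(a[0], b[0], 1.3, 0, 0, 0)
    assert gak_log_kernel(a, b, params) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("window_order", [0, 2, 3])
def test_dp_kernel_equals_exhaustive_enumeration(window_order):
    rng = np.random.default_rng(3)
    params = GAKParams(sigma=0.9, window_order=window_order)
    for _ in range(30):
        qa, qb = rng.integers(1, 5, size=2)
        p = rng.integers(1, 4)
        a, b = rng.normal(size=(qa, p)), rng.normal(size=(qb, p))
        ref = gak_kernel_enumerated(a, b, 0.9, window_order)
        if not np.isfinite(ref):
            with pytest.raises(NoAlignmentError):
                gak_log_kernel(a, b, params)
            continue
        assert gak_log_kernel(a, b, params) == pytest.approx(ref, abs=1e-10)


def test_kernel_symmetry_on_random_pairs():
    rng = np.random.default_rng(4)
    params = GAKParams(sigma=1.1)
    for _ in range(20):
        a = rng.normal(size=(rng.integers(2, 8), 3))
        b = rng.normal(size=(rng.integers(2, 8), 3))
        assert gak_log_kernel(a, b, params) == pytest.approx(
            gak_log_kernel(b, a, params), rel=1e-12)


def test_too_tight_window_raises_distinctly():
    params = GAKParams(sigma=1.0, window_order=1)
    with pytest.raises(NoAlignmentError):
        gak_log_kernel(np.zeros((1, 2)), np.ones((5, 2)), params)


def test_invalid_sigma_rejected():
    with pytest.raises(ValueError):
        GAKParams(sigma=0.0)


# ---------------------------------------------------------------------------
# distance
# ---------------------------------------------------------------------------

def test_distance_zero_on_identical_series():
    rng = np.random.default_rng(5)
    s = rng.normal(size=(6, 4))
    assert gak_distance(s, s, GAKParams(sigma=1.0)) == pytest.approx(0.0, abs=1e-12)


def test_distance_axioms_on_random_pairs():
    rng = np.random.default_rng(6)
    params = GAKParams(sigma=1.5)
    for _ in range(50):
        a = rng.normal(size=(rng.integers(2, 8), 2))
        b = rng.normal(size=(rng.integers(2, 8), 2))
        d_ab = gak_distance(a, b, params)
        d_ba = gak_distance(b, a, params)
        assert 0.0 <= d_ab <= 1.0
        assert d_ab == pytest.approx(d_ba, abs=1e-12)


# ---------------------------------------------------------------------------
# sigma heuristic
# ---------------------------------------------------------------------------

def test_sigma_heuristic_errors_on_constant_data():
    ss = make_series_set(np.ones((5, 4, 2)))
    with pytest.raises(ValueError):
        sigma_heuristic(ss)


def test_sigma_heuristic_scales_homogeneously_and_is_reproducible():
    rng = np.random.default_rng(7)
    arr = rng.normal(size=(10, 5, 3))
    s1 = sigma_heuristic(make_series_set(arr), seed=3)
    s2 = sigma_heuristic(make_series_set(arr), seed=3)
    s_scaled = sigma_heuristic(make_series_set(arr * 4.0), seed=3)
    assert s1 == s2
    assert s_scaled == pytest.approx(4.0 * s1, rel=1e-12)


# ---------------------------------------------------------------------------
# cross-distance matrix
# ---------------------------------------------------------------------------

def test_cross_distance_matrix_contract():
    rng = np.random.default_rng(8)
    arr = rng.normal(size=(7, 5, 3))
    ss = make_series_set(arr)
    params = GAKParams(sigma=2.0)
    dm = cross_distance_matrix(ss, params)
    assert np.allclose(np.diag(dm), 0.0)
    assert np.allclose(dm, dm.T)
    for i, j in [(0, 3), (2, 6), (1, 4)]:
        assert dm[i, j] == pytest.approx(
            gak_distance(arr[i], arr[j], params), abs=1e-12)


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

def test_pam_k_equals_n_gives_zero_objective():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(6, 2))
    dm = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    part = pam_cluster(dm, k=6, seed=0)
    assert part.objective == 0.0
    assert sorted(part.medoid_indices.tolist()) == list(range(6))


def test_pam_recovers_two_well_separated_blobs():
    n = 10
    dm = np.full((2 * n, 2 * n), 10.0)
    rng = np.random.default_rng(10)
    for blk in (slice(0, n), slice(n, 2 * n)):
        sub = rng.uniform(0, 0.5, size=(n, n))
        dm[blk, blk] = (sub + sub.T) / 2
    np.fill_diagonal(dm, 0.0)
    for seed in range(5):
        part = pam_cluster(dm, k=2, seed=seed)
        labels = part.labels
        assert len(set(labels[:n])) == 1
        assert len(set(labels[n:])) == 1
        assert labels[0] != labels[-1]


def test_pam_matches_exhaustive_search_on_tiny_instance():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(8, 2))
    dm = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    part = pam_cluster(dm, k=2, seed=1, n_init=20)
    assert part.objective == pytest.approx(pam_exhaustive_k2(dm), abs=1e-12)


def test_pam_objective_matches_recomputation_and_medoids_are_members():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(20, 3))
    dm = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    part = pam_cluster(dm, k=3, seed=2)
    obj = 0.0
    for i, lab in enumerate(part.labels):
        med = part.medoid_indices[lab - 1]
        assert part.labels[med] == lab
        obj += dm[i, med]
    assert part.objective == pytest.approx(obj)


def test_pam_invariant_under_reordering():
    rng = np.random.default_rng(13)
    X = rng.normal(size=(15, 2))
    dm = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    perm = rng.permutation(15)
    part_a = pam_cluster(dm, k=3, seed=5, n_init=10)
    part_b = pam_cluster(dm[np.ix_(perm, perm)], k=3, seed=5, n_init=10)
    assert part_a.objective == pytest.approx(part_b.objective, abs=1e-9)


def test_pam_rejects_bad_k():
    dm = np.zeros((4, 4))
    with pytest.raises(ValueError):
        pam_cluster(dm, k=5, seed=0)


# ---------------------------------------------------------------------------
# k selection
# ---------------------------------------------------------------------------

def _planted_survival_clusters(rng, n, k, q=7, p=4, sep=4.0, noise=0.5):
    labels = rng.integers(0, k, size=n)
    centers = rng.normal(scale=sep, size=(k, q, p))
    arr = centers[labels] + rng.normal(scale=noise, size=(n, q, p))
    scales = np.geomspace(2.0, 20.0, k)[labels]
    t = rng.exponential(scales)
    surv = SurvivalTable(np.array([f"P{i:02d}" for i in range(n)], dtype=object),
                         t, np.ones(n, dtype=int))
    return make_series_set(arr), surv, labels + 1


def test_select_k_recovers_planted_cluster_count():
    hits = 0
    for seed in range(6):
        rng = np.random.default_rng(400 + seed)
        ss, surv, labels = _planted_survival_clusters(rng, 45, 3)
        k_opt, part, table = select_k(ss, surv, range(2, 6), seed=seed)
        hits += k_opt == 3
    assert hits >= 4


def test_select_k_reports_inadmissible_k():
    rng = np.random.default_rng(14)
    ss, surv, _ = _planted_survival_clusters(rng, 12, 2)
    with pytest.raises(ValueError):
        select_k(ss, surv, range(2, 4), min_cluster_size=10, seed=0)


def test_select_k_table_structure():
    rng = np.random.default_rng(15)
    ss, surv, _ = _planted_survival_clusters(rng, 30, 2)
    k_opt, part, table = select_k(ss, surv, range(2, 5), seed=1)
    assert set(table.columns) >= {"k", "admissible", "logrank_p", "wald_p"}
    assert list(table["k"]) == [2, 3, 4]
    admissible = table[table["admissible"]]
    assert (admissible["logrank_p"] >= 0).all()
    assert k_opt in set(admissible["k"])
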
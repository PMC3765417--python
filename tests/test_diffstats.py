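"""Weir-Cockerham differentiation statistics, resampling and ordination."""

import numpy as np
import pandas as pd
import pytest

from introgress.diffstats import (
    fst_permutation_test,
    global_fst_bootstrap,
    mantel_ibd,
    pairwise_fst_matrix,
    pca_fst,
    pca_individuals,
    panel_power_resampling,
    temporal_fst_ci,
    theta_from_components,
    wc_theta,
    wc_variance_components,
)
from introgress.genodata import DataError, GenotypeMatrix

from conftest import make_matrix, make_sample, random_dosage


# ---------------------------------------------------------------------------
# Independent scalar oracle for the 1984 variance components
# ---------------------------------------------------------------------------

def _oracle_components(dosages):
    """Textbook per-locus Weir-Cockerham components, scalar loops only."""
    L = dosages[0].shape[1]
    out = []
    for j in range(L):
        cols = [d[:, j][~np.isnan(d[:, j])] for d in dosages]
        cols = [c for c in cols if c.size >= 1]
        r = len(cols)
        if r < 2:
            out.append((np.nan, np.nan, np.nan))
            continue
        n_i = [len(c) for c in cols]
        N = sum(n_i)
        nbar = N / r
        if nbar <= 1:
            out.append((np.nan, np.nan, np.nan))
            continue
        n_c = (N - sum(n * n for n in n_i) / N) / (r - 1)
        p_i = [c.sum() / (2 * n) for c, n in zip(cols, n_i)]
        h_i = [(c == 1).sum() / n for c, n in zip(cols, n_i)]
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / N
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / N
        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        out.append((a, b, c))
    return (np.array([o[0] for o in out]), np.array([o[1] for o in out]),
            np.array([o[2] for o in out]))


def test_theta_matches_scalar_oracle_with_missing_data(rng):
    for _ in range(50):
        n1, n2 = rng.integers(4, 15, size=2)
        L = int(rng.integers(3, 8))
        d1 = random_dosage(rng, n1, L, missing_rate=0.15)
        d2 = random_dosage(rng, n2, L, missing_rate=0.15)
        a, b, c = wc_variance_components([d1, d2])
        oa, ob, oc = _oracle_components([d1, d2])
        np.testing.assert_allclose(a, oa, atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(b, ob, atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(c, oc, atol=1e-12, equal_nan=True)


def test_theta_one_for_fixed_difference():
    a = make_sample(np.zeros((6, 4)))
    b = make_sample(np.full((5, 4), 2.0), ids=[f"b{i}" for i in range(5)])
    assert wc_theta(a, b).theta == pytest.approx(1.0)


def test_theta_near_zero_for_self_split(rng):
    d = random_dosage(rng, 60, 30)
    a = make_sample(d[:30])
    b = make_sample(d[30:], ids=[f"b{i}" for i in range(30)])
    est = wc_theta(a, b)
    assert abs(est.theta) < 0.01


def test_theta_is_symmetric(rng):
    a = make_sample(random_dosage(rng, 12, 8))
    b = make_sample(random_dosage(rng, 9, 8), ids=[f"b{i}" for i in range(9)])
    assert wc_theta(a, b).theta == pytest.approx(wc_theta(b, a).theta)


def test_multilocus_theta_is_ratio_of_sums(rng):
    d1 = random_dosage(rng, 15, 10)
    d2 = random_dosage(rng, 15, 10)
    a, b, c = wc_variance_components([d1, d2])
    tot = a + b + c
    use = np.isfinite(tot) & (tot != 0)
    expected = a[use].sum() / tot[use].sum()
    assert theta_from_components(a, b, c) == pytest.approx(expected)
    # and NOT the mean of per-locus ratios when loci are heterogeneous
    per_locus = a[use] / tot[use]
    if not np.allclose(per_locus, per_locus[0]):
        assert theta_from_components(a, b, c) != pytest.approx(per_locus.mean())


def test_theta_errors_without_usable_loci():
    a = make_sample(np.zeros((4, 2)))
    b = make_sample(np.zeros((4, 2)), ids=[f"b{i}" for i in range(4)])
    with pytest.raises(DataError):
        wc_theta(a, b)


def test_permutation_p_minimal_for_fixed_difference():
    a = make_sample(np.zeros((8, 5)))
    b = make_sample(np.full((8, 5), 2.0), ids=[f"b{i}" for i in range(8)])
    p = fst_permutation_test(a, b, n_perm=199, seed=5)
    assert p == pytest.approx(1.0 / 200.0)
    assert p == fst_permutation_test(a, b, n_perm=199, seed=5)  # deterministic


def test_global_bootstrap_ci_covers_zero_for_identical_populations(rng):
    d = random_dosage(rng, 90, 20)
    samples = [
        make_sample(d[i * 30:(i + 1) * 30], river=f"R{i}",
                    ids=[f"r{i}_{k}" for k in range(30)])
        for i in range(3)
    ]
    est = global_fst_bootstrap(samples, n_boot=200, seed=3)
    assert est.ci_low <= 0.0 <= max(est.ci_high, 1e-9)
    assert est.sd is not None and est.sd >= 0


def test_temporal_ci_brackets_point_estimate(rng):
    h = make_sample(random_dosage(rng, 40, 25))
    c = make_sample(random_dosage(rng, 40, 25), era="contemporary",
                    years=(2005, 2008), ids=[f"c{i}" for i in range(40)])
    point, lo, hi = temporal_fst_ci(h, c, n_boot=300, seed=9)
    assert lo < hi
    assert lo - 0.01 <= point <= hi + 0.01


def test_pairwise_matrix_symmetry(small_study):
    data, _ = small_study
    theta, _ = pairwise_fst_matrix(data, panel="all")
    m = theta.values
    np.testing.assert_allclose(m, m.T, atol=1e-12)
    assert np.allclose(np.diag(m), 0.0)


def test_pcoa_recovers_one_dimensional_layout():
    # three collinear points: distances 0-1-3 along a line
    d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
    coords, explained = pca_fst(d)
    x = coords["PCo1"].values
    gaps = np.abs(np.diff(np.sort(x)))
    assert gaps.max() / gaps.min() == pytest.approx(2.0, rel=0.05)
    assert explained[0] > 0.99


def test_pca_individuals_separates_divergent_groups():
    a = make_sample(np.zeros((10, 12)))
    b = make_sample(np.full((10, 12), 2.0), river="Other",
                    ids=[f"b{i}" for i in range(10)])
    coords, centroids, explained = pca_individuals([a, b])
    g = coords.groupby("group")["PC1"].mean()
    assert abs(g.iloc[0] - g.iloc[1]) > 1.0
    assert explained[0] > 0.9
    assert len(centroids) == 2


def test_mantel_detects_perfect_distance_correlation(rng):
    pos = np.sort(rng.uniform(0, 100, 8))
    geo = np.abs(pos[:, None] - pos[None, :])
    gen = 0.001 * geo
    r, p = mantel_ibd(gen, geo, n_perm=999, seed=4)
    assert r == pytest.approx(1.0)
    assert p < 0.01


def test_panel_power_farmed_wild_exceeds_within_pool_null(small_study):
    data, _ = small_study
    wild = GenotypeMatrix.stack(
        [s.genotypes for s in data.samples if s.era == "historical"]
    )
    farmed = data.farmed.genotypes
    t = panel_power_resampling(wild, farmed, group_size=30, n_boot=100, seed=2)
    by = t.set_index(["panel", "comparison"])["mean"]
    for panel in ("diagnostic", "random"):
        # the farmed-wild contrast must stand out from both within-pool nulls
        assert by[(panel, "farmed_vs_wild")] > by[(panel, "wild_vs_wild")]
        assert by[(panel, "farmed_vs_wild")] > by[(panel, "farmed_vs_farmed")]
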
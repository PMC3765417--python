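"""Migration-rate estimators: regression ABC and the fixed-migration grid."""

import numpy as np
import pytest

import introgress.estimators as est_mod
from introgress.estimators import (
    AbcConfig,
    FixedGridConfig,
    SimTemplate,
    abc_estimate,
    build_template,
    default_grid,
    fixed_grid_estimate,
)
from introgress.genodata import DataError

from conftest import make_sample, random_dosage


@pytest.fixture(scope="module")
def template():
    rng = np.random.default_rng(77)
    p0 = rng.uniform(0.2, 0.8, 20)
    hist = make_sample(rng.binomial(2, p0, size=(50, 20)).astype(float))
    donor = np.clip(p0 + rng.choice([-0.35, 0.35], size=20), 0.05, 0.95)
    return SimTemplate(
        recipient_seed_sample=hist, donor_frequencies=donor, ne=100,
        generations=4, sample_size_out=50,
    )


def test_default_grid_layout():
    g = default_grid()
    assert len(g) == 32
    np.testing.assert_allclose(g[:20], np.arange(1, 21) / 100.0)
    np.testing.assert_allclose(g[20:], np.arange(25, 81, 5) / 100.0)
    assert np.all(np.diff(g) > 0)


def test_grid_config_rejects_unsorted_grid():
    with pytest.raises(ValueError):
        FixedGridConfig(grid=np.array([0.2, 0.1]))
    with pytest.raises(ValueError):
        FixedGridConfig(grid=np.array([0.5, 1.5]))


def test_abc_config_validation():
    with pytest.raises(ValueError):
        AbcConfig(prior_sd=0.0)
    with pytest.raises(ValueError):
        AbcConfig(tol=0.0)


def test_abc_estimate_is_deterministic(template):
    cfg = AbcConfig(n_sim_per_iter=100, max_iter=3, seed=5)
    e1, t1 = abc_estimate(0.03, template, cfg)
    e2, t2 = abc_estimate(0.03, template, cfg)
    assert e1.m_per_gen_mean == e2.m_per_gen_mean
    assert t1.alphas == t2.alphas


def test_abc_estimate_monotone_in_observed_theta(template):
    cfg = AbcConfig(n_sim_per_iter=150, max_iter=4, seed=1)
    ms = [abc_estimate(t, template, cfg)[0].m_per_gen_mean
          for t in (0.01, 0.04, 0.09)]
    assert ms == sorted(ms)
    assert all(0.0 <= m <= 1.0 for m in ms)


def test_abc_rejects_degenerate_regression(template, monkeypatch):
    monkeypatch.setattr(est_mod, "_simulate_theta", lambda tpl, m, rng: (0.02, 0.0))
    with pytest.raises(DataError, match="degenerate"):
        abc_estimate(0.02, template, AbcConfig(n_sim_per_iter=100, max_iter=2))


def test_abc_rejects_nonfinite_observed(template):
    with pytest.raises(ValueError):
        abc_estimate(float("nan"), template, AbcConfig())


def test_abc_trace_records_every_iteration(template):
    cfg = AbcConfig(n_sim_per_iter=100, max_iter=3, tol=1e-12, seed=2)
    est, trace = abc_estimate(0.04, template, cfg)
    assert est.n_iterations == 3 and not trace.converged
    assert len(trace.alphas) == len(trace.betas) == len(trace.alpha_ses) == 3
    assert all(len(s) == 100 for s in trace.s_vectors)


def test_fixed_grid_single_qualifying_stratum(template):
    # Pre-simulate three well-separated grid values; pick a CI containing only
    # results from the middle value, so every selected draw carries M = 0.30.
    grid = np.array([0.01, 0.30, 0.80])
    sims = {}
    for m in grid:
        rng = np.random.default_rng(901)
        sims[m] = [est_mod._simulate_theta(template, m, rng)[0] for _ in range(30)]
    mid = np.sort(sims[0.30])
    lo, hi = mid[10], mid[20]
    assert max(sims[0.01]) < lo and min(sims[0.80]) > hi
    cfg = FixedGridConfig(grid=grid, replicates_per_value=30, n_select=200, seed=901)
    est = fixed_grid_estimate((lo, hi), template, cfg)
    assert est.m_per_gen_mean == pytest.approx(0.30)
    assert est.m_per_gen_sd == pytest.approx(0.0, abs=1e-12)
    assert est.n_accepted > 0


def test_fixed_grid_empty_qualifying_set_reports_nearest(template):
    cfg = FixedGridConfig(grid=np.array([0.5, 0.8]), replicates_per_value=5, seed=3)
    with pytest.raises(DataError, match="nearest"):
        fixed_grid_estimate((-0.002, -0.001), template, cfg)


def test_build_template_uses_metadata(small_study):
    data, truth = small_study
    river = data.rivers[0]
    tpl = build_template(data, river, "farmed")
    contemp = data.get(river, "contemporary")
    assert tpl.sample_size_out == min(contemp.n, tpl.ne)
    assert tpl.ne <= 200
    assert tpl.generations >= 1
    assert len(tpl.donor_frequencies) == len(data.loci)
    tpl_n = build_template(data, river, "neighbour")
    neighbour = data.nearest_neighbour(river)
    from introgress.genodata import allele_frequencies
    np.testing.assert_allclose(
        tpl_n.donor_frequencies,
        allele_frequencies(data.get(neighbour, "historical"))["freq"].values,
    )


def test_build_template_rejects_unknown_scenario(small_study):
    data, _ = small_study
    with pytest.raises(ValueError):
        build_template(data, data.rivers[0], "weird")
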
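"""Forward gamete-sampling introgression simulator."""

import numpy as np
import pytest

from introgress.genodata import DataError
from introgress.introsim import (
    SimulationConfig,
    expected_total_admixture,
    generations_from_years,
    simulate_introgression,
    temporal_fst_of_simulation,
)

from conftest import make_sample, random_dosage


def _config(hist, donor, **kw):
    base = dict(ne=50, generations=3, m=0.1, donor_frequencies=donor,
                recipient_seed_sample=hist, sample_size_out=20, seed=7)
    base.update(kw)
    return SimulationConfig(**base)


def test_generations_from_midpoint_year_gap():
    # midpoints 1972 and 2010: 38 years / 5-year generations -> 8
    assert generations_from_years((1971, 1973), (2010, 2010)) == 8
    # sub-generation gaps floor at one generation
    assert generations_from_years((2000, 2000), (2002, 2002)) == 1
    # exact multiples
    assert generations_from_years((1980, 1980), (2005, 2005)) == 5
    with pytest.raises(ValueError):
        generations_from_years((2010, 2010), (1990, 1990))


def test_expected_total_admixture_closed_form():
    assert expected_total_admixture(0.0, 5) == 0.0
    assert expected_total_admixture(1.0, 3) == 1.0
    assert expected_total_admixture(0.077, 5.5) == pytest.approx(0.3564, abs=2e-3)
    with pytest.raises(ValueError):
        expected_total_admixture(-0.1, 5)


def test_config_validation(rng):
    hist = make_sample(random_dosage(rng, 10, 4))
    donor = np.full(4, 0.5)
    with pytest.raises((ValueError, DataError)):
        _config(hist, donor, m=1.5)
    with pytest.raises((ValueError, DataError)):
        _config(hist, donor, generations=0)
    with pytest.raises((ValueError, DataError)):
        _config(hist, donor, sample_size_out=51)  # exceeds ne
    with pytest.raises((ValueError, DataError)):
        _config(hist, donor, donor_frequencies=np.full(3, 0.5))  # wrong length


def test_no_migration_keeps_zero_ancestry(rng):
    hist = make_sample(random_dosage(rng, 20, 6))
    cohort = simulate_introgression(_config(hist, np.full(6, 0.5), m=0.0))
    assert cohort.realized_admixture == 0.0
    assert np.all(cohort.trajectory == 0.0)


def test_full_migration_fixes_donor_ancestry(rng):
    hist = make_sample(random_dosage(rng, 20, 6))
    cohort = simulate_introgression(_config(hist, np.full(6, 0.5), m=1.0))
    assert cohort.realized_admixture == 1.0


def test_ancestry_trajectory_ends_at_realized_value(rng):
    hist = make_sample(random_dosage(rng, 20, 6))
    cohort = simulate_introgression(_config(hist, np.full(6, 0.9), m=0.2))
    assert cohort.trajectory[-1] == pytest.approx(cohort.realized_admixture)
    assert len(cohort.trajectory) == 4  # generations + 1


def test_fixed_seed_reproduces_simulation(rng):
    hist = make_sample(random_dosage(rng, 15, 5))
    c1 = simulate_introgression(_config(hist, np.full(5, 0.8), seed=42))
    c2 = simulate_introgression(_config(hist, np.full(5, 0.8), seed=42))
    np.testing.assert_array_equal(c1.genotypes.dosage, c2.genotypes.dosage)
    assert c1.realized_admixture == c2.realized_admixture


def test_realized_admixture_tracks_recursion(rng):
    hist = make_sample(random_dosage(rng, 30, 4))
    donor = np.full(4, 0.5)
    m, G, reps = 0.15, 4, 300
    vals = np.empty(reps)
    for i in range(reps):
        vals[i] = simulate_introgression(
            _config(hist, donor, m=m, generations=G, ne=60, seed=10_000 + i)
        ).realized_admixture
    expected = expected_total_admixture(m, G)
    se = vals.std(ddof=1) / np.sqrt(reps)
    assert abs(vals.mean() - expected) < 3 * se + 1e-9


def test_final_frequencies_are_convex_combination(rng):
    p0 = np.array([0.2, 0.5, 0.8, 0.35])
    hist = make_sample(rng.binomial(2, p0, size=(200, 4)).astype(float))
    donor = np.array([0.9, 0.1, 0.3, 0.95])
    m, G, reps = 0.2, 3, 250
    freqs = np.zeros(4)
    for i in range(reps):
        c = simulate_introgression(
            _config(hist, donor, m=m, generations=G, ne=100,
                    sample_size_out=100, seed=20_000 + i)
        )
        freqs += np.nanmean(c.genotypes.dosage, axis=0) / 2.0
    freqs /= reps
    q = expected_total_admixture(m, G)
    p_hist = p0  # large seed sample, frequencies near truth
    expected = q * donor + (1 - q) * p_hist
    np.testing.assert_allclose(freqs, expected, atol=0.03)


def test_theta_monotone_in_migration_rate(rng):
    hist = make_sample(random_dosage(rng, 50, 20))
    donor = np.clip(np.nanmean(hist.genotypes.dosage, axis=0) / 2 + 0.4, 0.05, 0.95)
    means = []
    for m in (0.0, 0.05, 0.1, 0.2):
        thetas = [
            temporal_fst_of_simulation(
                _config(hist, donor, m=m, generations=4, ne=100,
                        sample_size_out=50, seed=30_000 + i)
            )
            for i in range(200)
        ]
        means.append(np.mean(thetas))
    assert means == sorted(means)


def test_matched_donor_creates_no_divergence_signal(rng):
    # donor frequencies equal to the recipient's: migration adds no
    # directional divergence, so theta must not shift above the m=0 drift
    # distribution.  (An unchanging matched donor pool actually stabilizes
    # frequencies, so theta can only shrink; exact distributional equality
    # holds only in the small-m limit.)
    from scipy import stats

    p0 = rng.uniform(0.2, 0.8, 12)
    hist = make_sample(rng.binomial(2, p0, size=(60, 12)).astype(float))
    donor = np.nanmean(hist.genotypes.dosage, axis=0) / 2.0
    t_m0, t_match = [], []
    for i in range(150):
        t_m0.append(temporal_fst_of_simulation(
            _config(hist, donor, m=0.0, generations=4, ne=80,
                    sample_size_out=40, seed=40_000 + i)))
        t_match.append(temporal_fst_of_simulation(
            _config(hist, donor, m=0.3, generations=4, ne=80,
                    sample_size_out=40, seed=50_000 + i)))
    # one-sided: matched-donor thetas are not stochastically larger
    p = stats.mannwhitneyu(t_match, t_m0, alternative="greater").pvalue
    assert p > 0.01


def test_individual_migration_unit_matches_recursion(rng):
    hist = make_sample(random_dosage(rng, 30, 4))
    donor = np.full(4, 0.5)
    vals = [
        simulate_introgression(
            _config(hist, donor, m=0.1, generations=5, ne=60,
                    migration_unit="individual", seed=60_000 + i)
        ).realized_admixture
        for i in range(300)
    ]
    vals = np.asarray(vals)
    expected = expected_total_admixture(0.1, 5)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - expected) < 3 * se + 1e-9
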
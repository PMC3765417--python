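"""Forward-in-time gamete-sampling simulator of introgression.

The model: a recipient Wright-Fisher population of constant diploid effective
size Ne receives gene flow from an externally maintained donor pool (the
farmed fish) at a per-generation migration rate m.  Each generation, every one
of the Ne offspring draws two gametes independently; a gamete is, with
probability m, a donor gamete (one allele per locus drawn at the donor's
allele frequency, ancestry tagged donor), otherwise it comes from a random
parent of the previous generation (one of the parent's two alleles per locus
at random, ancestry tag inherited as a fifty-fifty pick of the parent's two
ancestry copies).  Loci are unlinked; there is no selection, mutation or sex
structure.  Donor allele frequencies are held constant across generations.

Generation 0 is built by gamete resampling from the recipient seed sample
(rather than copying individuals), so small historical samples do not
artificially fix rare alleles.  The expected donor-ancestry fraction after G
generations is the recursion 1 - (1 - m)^G.

An alternative migration unit is exposed: ``migration_unit="individual"``
replaces whole spawners (both gametes of a migrant offspring are
donor-derived).  The expected ancestry recursion is identical; only the
variance differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genodata import DataError, GenotypeMatrix, Locus, PopulationSample


@dataclass
class SimulationConfig:
    """Parameters of one forward introgression simulation."""

    ne: int
    generations: int
    m: float
    donor_frequencies: np.ndarray
    recipient_seed_sample: PopulationSample
    sample_size_out: int
    seed: int = 0
    migration_unit: str = "gamete"

    def __post_init__(self):
        if not (0 <= self.m <= 1):
            raise ValueError("migration rate m must lie in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.ne < 2:
            raise ValueError("ne must be >= 2")
        if self.sample_size_out > self.ne:
            raise DataError("sample_size_out cannot exceed ne")
        if self.migration_unit not in ("gamete", "individual"):
            raise ValueError("migration_unit must be 'gamete' or 'individual'")
        df = np.asarray(self.donor_frequencies, dtype=float)
        if df.ndim != 1 or df.size != self.recipient_seed_sample.genotypes.n_loci:
            raise DataError("donor and recipient must share the locus set")
        self.donor_frequencies = df


@dataclass
class SimulatedCohort:
    """Output of one simulation: sampled genotypes + realized donor ancestry."""

    genotypes: GenotypeMatrix
    realized_admixture: float
    trajectory: np.ndarray  # mean donor ancestry after each generation (len G+1)


# ---------------------------------------------------------------------------
# Generation-time rule
# ---------------------------------------------------------------------------

def generations_from_years(
    historical: PopulationSample | tuple[int, int],
    contemporary: PopulationSample | tuple[int, int],
    generation_time: float = 5.0,
) -> int:
    """Number of generations separating two samples.

    G = round((contemporary midpoint - historical midpoint) / generation_time),
    floored at 1; the midpoint of a sample is the mean of its year range.
    """
    def midpoint(x):
        if isinstance(x, PopulationSample):
            return x.year_midpoint
        return 0.5 * (x[0] + x[1])

    gap = midpoint(contemporary) - midpoint(historical)
    if gap <= 0:
        raise ValueError("contemporary midpoint must postdate historical midpoint")
    return max(1, int(np.floor(gap / generation_time + 0.5)))


def expected_total_admixture(m: float, generations: float) -> float:
    """Deterministic total admixture after G generations at rate m: 1-(1-m)^G."""
    if not (0 <= m <= 1):
        raise ValueError("m must lie in [0, 1]")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    return 1.0 - (1.0 - m) ** generations


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

def _seed_gametes(
    rng: np.random.Generator,
    n_gametes: int,
    seed_dosage: np.ndarray,
    fallback_freq: np.ndarray,
) -> np.ndarray:
    """Draw gametes from the seed sample's individuals.

    Each gamete picks a random seed individual and, per locus, one of its two
    alleles at random (Bernoulli(dosage/2)); missing calls fall back to the
    seed sample's allele frequency at that locus.
    """
    n_ind, n_loci = seed_dosage.shape
    parents = rng.integers(n_ind, size=n_gametes)
    probs = seed_dosage[parents] / 2.0
    probs = np.where(np.isnan(probs), fallback_freq, probs)
    return (rng.random((n_gametes, n_loci)) < probs).astype(np.uint8)


def simulate_core(
    seed_dosage: np.ndarray,
    donor_freq: np.ndarray,
    ne: int,
    generations: int,
    m: float,
    sample_size_out: int,
    rng: np.random.Generator,
    migration_unit: str = "gamete",
) -> tuple[np.ndarray, float, np.ndarray]:
    """Run one simulation on raw arrays.

    Returns (output dosage matrix of shape (sample_size_out, L), realized
    donor-ancestry fraction over the 2*Ne gene copies of the final
    generation, per-generation mean-ancestry trajectory).
    """
    n_loci = seed_dosage.shape[1]
    called = (~np.isnan(seed_dosage)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        fallback = np.where(
            called > 0, np.nansum(seed_dosage, axis=0) / (2 * np.maximum(called, 1)), 0.5
        )
    donor_freq = np.where(np.isfinite(donor_freq), donor_freq, fallback)

    # generation 0: Ne diploids bootstrapped from the seed sample's gametes
    h1 = _seed_gametes(rng, ne, seed_dosage, fallback)
    h2 = _seed_gametes(rng, ne, seed_dosage, fallback)
    a1 = np.zeros(ne, dtype=np.uint8)
    a2 = np.zeros(ne, dtype=np.uint8)
    traj = np.empty(generations + 1)
    traj[0] = 0.0

    for g in range(1, generations + 1):
        if migration_unit == "individual":
            mig_ind = rng.random(ne) < m
        new_h, new_a = [], []
        for _slot in range(2):
            parents = rng.integers(ne, size=ne)
            which = rng.random((ne, n_loci)) < 0.5
            gam = np.where(which, h1[parents], h2[parents]).astype(np.uint8)
            ganc = np.where(rng.random(ne) < 0.5, a1[parents], a2[parents])
            mig = mig_ind if migration_unit == "individual" else rng.random(ne) < m
            k = int(mig.sum())
            if k:
                gam[mig] = (rng.random((k, n_loci)) < donor_freq).astype(np.uint8)
                ganc = ganc.copy()
                ganc[mig] = 1
            new_h.append(gam)
            new_a.append(ganc)
        h1, h2 = new_h
        a1, a2 = new_a
        traj[g] = 0.5 * (a1.mean() + a2.mean())

    realized = float(traj[-1])
    out_idx = rng.choice(ne, size=sample_size_out, replace=False)
    out = (h1[out_idx] + h2[out_idx]).astype(float)
    return out, realized, traj


def simulate_introgression(config: SimulationConfig) -> SimulatedCohort:
    """Run one forward introgression simulation from a configuration."""
    seed_sample = config.recipient_seed_sample
    if seed_sample.n < 2:
        raise DataError("recipient seed sample needs at least 2 individuals")
    rng = np.random.default_rng(config.seed)
    out, realized, traj = simulate_core(
        seed_sample.genotypes.dosage,
        config.donor_frequencies,
        config.ne,
        config.generations,
        config.m,
        config.sample_size_out,
        rng,
        config.migration_unit,
    )
    inds = [f"{seed_sample.river}_sim{i}" for i in range(out.shape[0])]
    gm = GenotypeMatrix(inds, seed_sample.genotypes.loci, out)
    return SimulatedCohort(gm, realized, traj)


def temporal_fst_of_simulation(config: SimulationConfig) -> float:
    """Theta between the recipient seed sample and one simulated cohort.

    Uses the same Weir-Cockerham estimator and locus set as the observed
    temporal F_ST it will be compared against.
    """
    from .diffstats import theta_from_dosages

    cohort = simulate_introgression(config)
    return theta_from_dosages(
        [config.recipient_seed_sample.genotypes.dosage, cohort.genotypes.dosage]
    )
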
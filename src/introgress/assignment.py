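"""Likelihood-based genetic assignment and exclusion from baseline samples.

The genotype likelihood of a query individual in a baseline population uses
the Bayesian posterior-predictive allele frequencies of Rannala & Mountain:
with a uniform Dirichlet(1, 1) prior over the two alleles and baseline counts
(x ref alleles, y alt alleles, n = x + y total), the probability of a query
genotype at one locus is Polya-urn sampling without replacement from the
posterior urn:

    hom ref:  (x+1)(x+2) / ((n+2)(n+3))
    het:    2 (x+1)(y+1) / ((n+2)(n+3))
    hom alt:  (y+1)(y+2) / ((n+2)(n+3))

The prior keeps likelihoods finite for alleles unseen in the baseline.  The
exclusion test simulates genotypes from the same posterior-predictive model
and reports the proportion of simulated composite log-likelihoods at or below
the observed one; an individual is excluded from the baseline at threshold t
when that proportion falls below t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .genodata import DataError, GenotypeMatrix, PopulationSample, StudyDataset, subset_panel


@dataclass
class ExclusionResult:
    individual: str
    baseline: str
    loglik: float
    p_value: float
    excluded_at: set


# ---------------------------------------------------------------------------
# Genotype log-probabilities under the baseline
# ---------------------------------------------------------------------------

def _genotype_logprobs(
    baseline: GenotypeMatrix, exclude_index: int | None = None
) -> np.ndarray:
    """(3, L) log-probabilities of dosages 0/1/2 per locus.

    ``exclude_index`` removes one baseline individual's alleles first
    (leave-one-out when the query belongs to the baseline).
    """
    dos = baseline.dosage
    if exclude_index is not None:
        keep = np.ones(dos.shape[0], dtype=bool)
        keep[exclude_index] = False
        dos = dos[keep]
    called = (~np.isnan(dos)).sum(axis=0)
    alt = np.nansum(dos, axis=0)
    n = 2.0 * called
    x = n - alt  # ref allele count
    y = alt.astype(float)
    denom = (n + 2) * (n + 3)
    p0 = (x + 1) * (x + 2) / denom
    p1 = 2 * (x + 1) * (y + 1) / denom
    p2 = (y + 1) * (y + 2) / denom
    return np.log(np.vstack([p0, p1, p2]))


def baseline_log_likelihood(
    query: np.ndarray | tuple[str, GenotypeMatrix],
    baseline: PopulationSample | GenotypeMatrix,
    query_id: str | None = None,
) -> float:
    """Composite log-likelihood of a query genotype in a baseline sample.

    ``query`` is a dosage vector over the baseline's loci (NaN = missing;
    missing loci are skipped).  If ``query_id`` matches a baseline individual,
    leave-one-out correction is applied.
    """
    gm = baseline.genotypes if isinstance(baseline, PopulationSample) else baseline
    q = np.asarray(query, dtype=float)
    if q.shape != (gm.n_loci,):
        raise DataError("query must be a dosage vector over the baseline loci")
    excl = None
    if query_id is not None and query_id in gm.individuals:
        excl = gm.individuals.index(query_id)
    logp = _genotype_logprobs(gm, excl)
    called = ~np.isnan(q)
    if not called.any():
        raise DataError("query has no usable loci")
    idx = q[called].astype(int)
    return float(logp[idx, np.where(called)[0]].sum())


# ---------------------------------------------------------------------------
# Exclusion test
# ---------------------------------------------------------------------------

def exclusion_test(
    query: np.ndarray,
    baseline: PopulationSample | GenotypeMatrix,
    n_mc: int = 10000,
    seed: int = 0,
    thresholds: tuple[float, ...] = (0.05, 0.001),
    query_id: str | None = None,
    baseline_label: str = "",
) -> ExclusionResult:
    """Monte-Carlo exclusion of one query genotype from a baseline.

    ``n_mc`` genotypes are simulated from the baseline's posterior-predictive
    genotype frequencies over the loci called in the query; the p-value is the
    proportion of simulated composite log-likelihoods less than or equal to
    the observed one.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000")
    gm = baseline.genotypes if isinstance(baseline, PopulationSample) else baseline
    q = np.asarray(query, dtype=float)
    excl = None
    if query_id is not None and query_id in gm.individuals:
        excl = gm.individuals.index(query_id)
    logp = _genotype_logprobs(gm, excl)
    called = ~np.isnan(q)
    if not called.any():
        raise DataError("query has no usable loci")
    lp = logp[:, called]  # (3, Lc)
    obs = float(lp[q[called].astype(int), np.arange(lp.shape[1])].sum())

    rng = np.random.default_rng(seed)
    probs = np.exp(lp)  # columns sum to 1
    cum = np.cumsum(probs, axis=0)
    u = rng.random((n_mc, lp.shape[1]))
    sim_dos = (u[:, None, :] > cum[None, :, :]).sum(axis=1)  # (n_mc, Lc) in {0,1,2}
    sim_ll = lp[sim_dos, np.arange(lp.shape[1])].sum(axis=1)
    p = float((sim_ll <= obs + 1e-12).mean())
    return ExclusionResult(
        individual=query_id or "query",
        baseline=baseline_label or getattr(baseline, "label", "baseline"),
        loglik=obs,
        p_value=p,
        excluded_at={t for t in thresholds if p < t},
    )


def exclusion_summary(
    data: StudyDataset,
    n_mc: int = 10000,
    seed: int = 0,
    thresholds: tuple[float, ...] = (0.05, 0.001),
    panel: str = "all",
    include_farmed: bool = True,
) -> pd.DataFrame:
    """Percent of individuals excluded from baselines, per river and panel.

    For each river: contemporary individuals are tested against the
    historical baseline.  With ``include_farmed``, the farmed pool is also
    tested against each river's historical and contemporary samples.
    """
    ds = subset_panel(data, panel)
    rows = []

    def pct_excluded(queries: GenotypeMatrix, baseline: PopulationSample, tag: str):
        if queries.n_individuals == 0:
            raise DataError(f"empty query sample vs {baseline.label}")
        ps = np.empty(queries.n_individuals)
        for i in range(queries.n_individuals):
            res = exclusion_test(
                queries.dosage[i], baseline, n_mc=n_mc,
                seed=child_seed(seed, tag, i),
                thresholds=thresholds, query_id=queries.individuals[i],
                baseline_label=baseline.label,
            )
            ps[i] = res.p_value
        row = {"comparison": tag, "baseline": baseline.label,
               "n_queries": queries.n_individuals, "panel": panel}
        for t in thresholds:
            row[f"pct_excluded_{t}"] = 100.0 * float((ps < t).mean())
        return row

    farmed = ds.farmed
    for river in ds.rivers:
        hist = ds.get(river, "historical")
        contemp = ds.get(river, "contemporary")
        rows.append(pct_excluded(contemp.genotypes, hist, f"{river}:contemp_vs_hist"))
        if include_farmed and farmed is not None:
            rows.append(pct_excluded(farmed.genotypes, hist, f"{river}:farmed_vs_hist"))
            rows.append(
                pct_excluded(farmed.genotypes, contemp, f"{river}:farmed_vs_contemp")
            )
    return pd.DataFrame(rows)
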
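"""Within-sample summary statistics.

Unbiased expected heterozygosity, Hardy-Weinberg exact tests and a pairwise
linkage-disequilibrium scan, plus a per-sample summary table.  These are the
first-line diagnostics for disturbance of a sample: a cohort recently admixed
with genetically distinct immigrants shows an excess of Hardy-Weinberg
deviations and of locus pairs in LD (the Wahlund effect), which is exactly the
signature expected in a pool of farmed fish mixed from multiple strains.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .genodata import GenotypeMatrix, PopulationSample, StudyDataset


# ---------------------------------------------------------------------------
# Unbiased expected heterozygosity
# ---------------------------------------------------------------------------

def unbiased_he(sample: PopulationSample | GenotypeMatrix) -> tuple[pd.Series, float]:
    """Per-locus and mean unbiased expected heterozygosity.

    uH_E = 2n/(2n-1) * (1 - p^2 - q^2) with n the number of non-missing
    individuals at the locus.  Loci with fewer than two called individuals are
    excluded from the mean and returned as NaN.
    """
    gm = sample.genotypes if isinstance(sample, PopulationSample) else sample
    called = (~np.isnan(gm.dosage)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(gm.dosage, axis=0) / (2 * called)
    he = 2 * p * (1 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        uhe = np.where(called >= 2, he * (2 * called) / (2 * called - 1), np.nan)
    per_locus = pd.Series(uhe, index=pd.Index(gm.locus_ids, name="locus"), name="uhe")
    mean = float(np.nanmean(uhe)) if np.isfinite(uhe).any() else float("nan")
    return per_locus, mean


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test for one biallelic locus.

    Given n genotyped individuals and the observed count of one allele, the
    conditional probability of h heterozygotes under HWE is

        P(h | n, n1) = n! 2^h / (nAA! h! naa!) / C(2n, n1)

    summed over all heterozygote counts h with the same parity as the minor
    allele count.  The p-value is the total probability of configurations no
    more probable than the observed one.  Monomorphic loci return p = 1.
    """
    counts = (int(n_hom_ref), int(n_het), int(n_hom_alt))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_alt = counts[1] + 2 * counts[2]
    n1 = min(n_alt, 2 * n - n_alt)  # minor allele count
    if n1 == 0:
        return 1.0
    hs = np.arange(n1 % 2, n1 + 1, 2)
    n_minor_hom = (n1 - hs) // 2
    n_major_hom = n - hs - n_minor_hom
    logp = (
        special.gammaln(n + 1)
        - special.gammaln(n_major_hom + 1)
        - special.gammaln(hs + 1)
        - special.gammaln(n_minor_hom + 1)
        + hs * np.log(2.0)
    )
    logp -= special.logsumexp(logp)
    probs = np.exp(logp)
    obs = probs[hs == counts[1]]
    if obs.size == 0:  # inconsistent counts cannot occur with valid input
        raise ValueError("heterozygote count inconsistent with allele count parity")
    return float(min(1.0, probs[probs <= obs[0] * (1 + 1e-12)].sum()))


def hwe_pvalues(sample: PopulationSample | GenotypeMatrix) -> pd.Series:
    """HWE exact p-value per locus of a sample (NaN when untestable)."""
    gm = sample.genotypes if isinstance(sample, PopulationSample) else sample
    out = np.full(gm.n_loci, np.nan)
    for j in range(gm.n_loci):
        d = gm.dosage[:, j]
        d = d[~np.isnan(d)]
        if d.size == 0:
            continue
        out[j] = hwe_exact(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
    return pd.Series(out, index=pd.Index(gm.locus_ids, name="locus"), name="hwe_p")


# ---------------------------------------------------------------------------
# LD scan
# ---------------------------------------------------------------------------

def ld_scan(
    sample: PopulationSample | GenotypeMatrix,
    alpha: float = 0.05,
    min_joint: int = 5,
) -> pd.DataFrame:
    """Composite-genotype LD scan over all locus pairs.

    For each pair, the Pearson correlation r between the dosage vectors over
    individuals with both loci called is tested via n*r^2 against chi-square
    with 1 df (the composite LD test for unphased biallelic genotypes).
    Returns all testable pairs; significant ones have ``significant=True``.
    Pairs with fewer than ``min_joint`` jointly called individuals, or with a
    monomorphic member, are skipped.
    """
    gm = sample.genotypes if isinstance(sample, PopulationSample) else sample
    d = gm.dosage
    ids = gm.locus_ids
    rows = []
    obs = ~np.isnan(d)
    for j in range(gm.n_loci):
        for k in range(j + 1, gm.n_loci):
            m = obs[:, j] & obs[:, k]
            n = int(m.sum())
            if n < min_joint:
                continue
            x, y = d[m, j], d[m, k]
            if x.std() == 0 or y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            statistic = n * r * r
            p = float(stats.chi2.sf(statistic, df=1))
            rows.append(
                {"locus_a": ids[j], "locus_b": ids[k], "n": n, "r": r,
                 "p": p, "significant": p < alpha}
            )
    return pd.DataFrame(
        rows, columns=["locus_a", "locus_b", "n", "r", "p", "significant"]
    )


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

def sample_summary_table(
    data: StudyDataset, alpha: float = 0.05, bonferroni: bool = False
) -> pd.DataFrame:
    """One row per sample: N, mean uH_E, HWE deviation count, LD pair count.

    With ``bonferroni=True`` the significance threshold for the HWE count is
    alpha divided by the number of testable loci, and for the LD count alpha
    divided by the number of testable pairs.
    """
    rows = []
    for s in data.samples:
        _, uhe = unbiased_he(s)
        hp = hwe_pvalues(s).dropna()
        hwe_thresh = alpha / max(len(hp), 1) if bonferroni else alpha
        ld = ld_scan(s, alpha=alpha)
        ld_thresh = alpha / max(len(ld), 1) if bonferroni else alpha
        rows.append(
            {
                "sample": s.label,
                "n": s.n,
                "uhe": round(uhe, 2) if np.isfinite(uhe) else np.nan,
                "hwe_count": int((hp < hwe_thresh).sum()),
                "ld_count": int((ld["p"] < ld_thresh).sum()) if len(ld) else 0,
                "type": s.life_stage,
                "alpha": hwe_thresh,
            }
        )
    return pd.DataFrame(rows)
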
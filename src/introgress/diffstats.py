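"""Between-sample differentiation statistics.

Weir & Cockerham's theta (the method-of-moments F_ST estimator from variance
components) with permutation significance and bootstrap confidence intervals,
pairwise F_ST matrices, principal-coordinate and individual-genotype PCA,
Mantel isolation-by-distance testing, and the marker-panel power resampling
comparison.

Theta is computed from per-locus variance components for r populations:
``a`` (among populations), ``b`` (among individuals within populations) and
``c`` (within individuals).  The multi-locus estimate is always the ratio of
sums, sum(a)/sum(a+b+c), never the mean of per-locus ratios.  Negative
estimates are reported as-is: around zero true differentiation the estimator
is unbiased and small negatives are expected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import rng_for
from .genodata import DataError, GenotypeMatrix, PopulationSample, StudyDataset


@dataclass
class FstEstimate:
    """A Weir-Cockerham theta with optional uncertainty measures."""

    theta: float
    per_locus_a: np.ndarray
    per_locus_b: np.ndarray
    per_locus_c: np.ndarray
    locus_ids: list[str]
    locus_set: str = "all"
    p_value: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    sd: float | None = None
    n_permutations: int = 0
    n_bootstraps: int = 0

    @property
    def per_locus_theta(self) -> np.ndarray:
        tot = self.per_locus_a + self.per_locus_b + self.per_locus_c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot != 0, self.per_locus_a / tot, np.nan)


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

def wc_variance_components(dosages: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components for r populations.

    ``dosages`` is a list of (n_i, L) alt-dosage arrays (NaN = missing).
    Returns arrays (a, b, c) of length L; loci usable by fewer than two
    populations, or with mean sample size <= 1, come back NaN.
    """
    n = np.stack([(~np.isnan(d)).sum(axis=0) for d in dosages]).astype(float)  # (r, L)
    alt = np.stack([np.nansum(d, axis=0) for d in dosages])
    het = np.stack([np.nansum(d == 1, axis=0) for d in dosages]).astype(float)

    valid = n >= 1
    r = valid.sum(axis=0).astype(float)  # populations with data, per locus
    N = n.sum(axis=0)
    usable = (r >= 2) & (N / np.maximum(r, 1) > 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * np.maximum(n, 1)), 0.0)
        h = np.where(n > 0, het / np.maximum(n, 1), 0.0)
        nbar = N / r
        n_c = (N - (n**2).sum(axis=0) / N) / (r - 1)
        pbar = alt.sum(axis=0) / (2 * N)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = het.sum(axis=0) / N

        inner = (
            pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
        )
        a = nbar / n_c * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0

    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    return a, b, c


def theta_from_components(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Multi-locus theta: ratio of summed components over usable loci."""
    tot = a + b + c
    use = np.isfinite(tot) & (tot != 0)
    if not use.any():
        return float("nan")
    return float(a[use].sum() / tot[use].sum())


def theta_from_dosages(dosages: list[np.ndarray]) -> float:
    """Fast path: multi-locus theta straight from dosage arrays."""
    return theta_from_components(*wc_variance_components(dosages))


def _dosage(s: PopulationSample | GenotypeMatrix | np.ndarray) -> np.ndarray:
    if isinstance(s, PopulationSample):
        return s.genotypes.dosage
    if isinstance(s, GenotypeMatrix):
        return s.dosage
    return np.asarray(s, dtype=float)


def wc_theta(
    a: PopulationSample | GenotypeMatrix,
    b: PopulationSample | GenotypeMatrix,
    loci: list[str] | None = None,
    locus_set: str = "all",
) -> FstEstimate:
    """Weir-Cockerham theta between two samples.

    ``loci`` optionally restricts the shared locus set by id.  Raises if no
    locus yields defined variance components.
    """
    gma = a.genotypes if isinstance(a, PopulationSample) else a
    gmb = b.genotypes if isinstance(b, PopulationSample) else b
    if gma.locus_ids != gmb.locus_ids:
        raise DataError("samples do not share a locus set")
    da, db = gma.dosage, gmb.dosage
    ids = gma.locus_ids
    if loci is not None:
        idx = [ids.index(l) for l in loci]
        da, db, ids = da[:, idx], db[:, idx], [ids[i] for i in idx]
    ca, cb, cc = wc_variance_components([da, db])
    theta = theta_from_components(ca, cb, cc)
    if not np.isfinite(theta):
        raise DataError("no usable loci for theta estimation")
    return FstEstimate(theta, ca, cb, cc, ids, locus_set=locus_set)


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

def fst_permutation_test(
    a: PopulationSample | GenotypeMatrix,
    b: PopulationSample | GenotypeMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for theta > 0.

    Individuals are shuffled between the two samples preserving sizes;
    p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    da, db = _dosage(a), _dosage(b)
    pooled = np.vstack([da, db])
    if np.unique(pooled[~np.isnan(pooled).any(axis=1)], axis=0).shape[0] <= 1:
        return 1.0
    na = da.shape[0]
    obs = theta_from_dosages([da, db])
    if not np.isfinite(obs):
        return 1.0
    rng = np.random.default_rng(seed)
    n_tot = pooled.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        t = theta_from_dosages([pooled[perm[:na]], pooled[perm[na:]]])
        if np.isfinite(t) and t >= obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Global F_ST with bootstrap CI
# ---------------------------------------------------------------------------

def global_fst_bootstrap(
    samples: list[PopulationSample],
    frac: float = 0.35,
    n_boot: int = 1000,
    seed: int = 0,
    locus_set: str = "all",
) -> FstEstimate:
    """Global multi-population theta with a resampling CI.

    Each bootstrap replicate recomputes theta after randomly re-sampling a
    fraction ``frac`` of the individuals (without replacement, at least 2)
    from every population.  The CI is the 2.5/97.5 percentile of the replicate
    distribution and ``sd`` its standard deviation.
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must lie in (0, 1]")
    dosages = [_dosage(s) for s in samples]
    ca, cb, cc = wc_variance_components(dosages)
    point = theta_from_components(ca, cb, cc)
    rng = np.random.default_rng(seed)
    sizes = []
    for d in dosages:
        k = int(round(frac * d.shape[0]))
        if k < 2:
            warnings.warn("resample fraction yields <2 individuals; using 2")
            k = 2
        sizes.append(min(k, d.shape[0]))
    if n_boot == 1:
        warnings.warn("n_boot=1 gives a degenerate CI")
    boots = np.empty(n_boot)
    for i in range(n_boot):
        sub = [
            d[rng.choice(d.shape[0], size=k, replace=False)]
            for d, k in zip(dosages, sizes)
        ]
        boots[i] = theta_from_dosages(sub)
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return FstEstimate(
        point, ca, cb, cc, samples[0].genotypes.locus_ids
        if isinstance(samples[0], PopulationSample) else [],
        locus_set=locus_set, ci_low=float(lo), ci_high=float(hi),
        sd=float(boots.std(ddof=1)) if boots.size > 1 else 0.0,
        n_bootstraps=n_boot,
    )


def temporal_fst_ci(
    hist: PopulationSample,
    contemp: PopulationSample,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(theta, ci_low, ci_high) for one temporal pair.

    The 95% CI comes from bootstrapping individuals with replacement within
    each of the two samples.  Duplicated individuals inflate the
    among-sample variance, so the raw percentile interval sits above the
    point estimate; the interval is therefore recentred by the bootstrap
    bias (bias-corrected percentile), keeping its width.  Used by the
    fixed-grid migration estimator.
    """
    da, db = _dosage(hist), _dosage(contemp)
    point = theta_from_dosages([da, db])
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = da[rng.integers(da.shape[0], size=da.shape[0])]
        rb = db[rng.integers(db.shape[0], size=db.shape[0])]
        boots[i] = theta_from_dosages([ra, rb])
    boots = boots[np.isfinite(boots)]
    bias = boots.mean() - point
    lo, hi = np.percentile(boots, [2.5, 97.5]) - bias
    return float(point), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Pairwise matrix
# ---------------------------------------------------------------------------

def pairwise_fst_matrix(
    data: StudyDataset,
    panel: str = "all",
    n_perm: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Symmetric matrix of pairwise theta over all samples (+ p-values).

    Negative theta values are retained.  Permutation p-values are computed
    when ``n_perm`` > 0.
    """
    from .genodata import subset_panel

    ds = subset_panel(data, panel) if panel != "all" else data
    labels = [s.label for s in ds.samples]
    k = len(labels)
    if k < 2:
        raise DataError("need at least two samples")
    theta = np.zeros((k, k))
    pmat = np.full((k, k), np.nan) if n_perm else None
    for i in range(k):
        for j in range(i + 1, k):
            est = wc_theta(ds.samples[i], ds.samples[j], locus_set=panel)
            theta[i, j] = theta[j, i] = est.theta
            if n_perm:
                p = fst_permutation_test(
                    ds.samples[i], ds.samples[j], n_perm=n_perm,
                    seed=seed + i * k + j,
                )
                pmat[i, j] = pmat[j, i] = p
    tdf = pd.DataFrame(theta, index=labels, columns=labels)
    pdf = pd.DataFrame(pmat, index=labels, columns=labels) if n_perm else None
    return tdf, pdf


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_fst(matrix: pd.DataFrame | np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates (classical MDS) of an F_ST distance matrix.

    Distances are taken as max(theta, 0); the Gower-centred matrix is
    eigendecomposed and tiny negative eigenvalues (F_ST matrices need not be
    Euclidean) are clamped to zero.  Returns (coordinates, explained-variance
    fractions); axis signs are arbitrary.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index)
        m = matrix.values.astype(float)
    else:
        m = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(m.shape[0])]
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-10):
        raise DataError("PCoA requires a symmetric matrix")
    d = np.maximum(m, 0.0)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    coords = evecs * np.sqrt(evals)
    total = evals.sum()
    explained = evals / total if total > 0 else np.zeros_like(evals)
    cols = [f"PCo{i + 1}" for i in range(n)]
    return pd.DataFrame(coords, index=labels, columns=cols), explained


def pca_individuals(
    samples: list[PopulationSample],
    group_labels: list[str] | None = None,
    n_axes: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of centred individual dosages, with group centroids and ellipses.

    Missing dosages are mean-imputed per locus for the decomposition only.
    Returns (individual coordinates with a ``group`` column, a table of group
    centroids and 95% confidence-ellipse parameters, explained-variance
    fractions).
    """
    if group_labels is None:
        group_labels = [s.label for s in samples]
    mats = [_dosage(s) for s in samples]
    x = np.vstack(mats)
    if x.shape[0] < 3:
        raise DataError("need at least 3 individuals for PCA")
    groups = np.repeat(group_labels, [m.shape[0] for m in mats])
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    x = np.where(np.isnan(x), col_mean, x) - col_mean
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_axes, sv.size)
    coords = u[:, :k] * sv[:k]
    var = sv**2
    explained = var / var.sum() if var.sum() > 0 else var
    cols = [f"PC{i + 1}" for i in range(k)]
    cdf = pd.DataFrame(coords, columns=cols)
    cdf.insert(0, "group", groups)

    # 95% ellipse per group from the 2x2 covariance of its scores
    rows = []
    chi2_95 = stats.chi2.ppf(0.95, df=2)
    for g in dict.fromkeys(group_labels):
        pts = coords[groups == g][:, :2]
        cen = pts.mean(axis=0)
        row = {"group": g, "cx": cen[0], "cy": cen[1] if k > 1 else 0.0,
               "semi_major": 0.0, "semi_minor": 0.0, "angle_rad": 0.0}
        if pts.shape[0] > 2 and k > 1:
            cov = np.cov(pts.T)
            ev, evec = np.linalg.eigh(cov)
            ev = np.clip(ev, 0, None)
            row["semi_major"] = float(np.sqrt(chi2_95 * ev[1]))
            row["semi_minor"] = float(np.sqrt(chi2_95 * ev[0]))
            row["angle_rad"] = float(np.arctan2(evec[1, 1], evec[0, 1]))
        rows.append(row)
    return cdf, pd.DataFrame(rows), explained[:k]


# ---------------------------------------------------------------------------
# Mantel isolation by distance
# ---------------------------------------------------------------------------

def mantel_ibd(
    genetic: pd.DataFrame | np.ndarray,
    geographic: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test of genetic vs geographic distances.

    r is the Pearson correlation of the off-diagonal (upper-triangle)
    vectors; the one-sided p-value comes from joint random row/column
    permutations of the genetic matrix.
    """
    g = genetic.values if isinstance(genetic, pd.DataFrame) else np.asarray(genetic, float)
    d = geographic.values if isinstance(geographic, pd.DataFrame) else np.asarray(geographic, float)
    if g.shape != d.shape or g.shape[0] != g.shape[1]:
        raise DataError("Mantel matrices must be square and aligned")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = g.shape[0]
    iu = np.triu_indices(n, k=1)
    obs = float(np.corrcoef(g[iu], d[iu])[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        if np.corrcoef(gp[iu], d[iu])[0, 1] >= obs:
            hits += 1
    return obs, (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Panel power resampling
# ---------------------------------------------------------------------------

def resampled_fst_distribution(
    pool_a: GenotypeMatrix,
    pool_b: GenotypeMatrix | None,
    group_size: int = 100,
    n_boot: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Distribution of theta between random groups drawn from pools.

    With ``pool_b=None`` both groups are drawn disjointly from ``pool_a``
    (the within-pool null); otherwise one group is drawn from each pool.
    """
    rng = np.random.default_rng(seed)
    da = pool_a.dosage
    if pool_b is None:
        if da.shape[0] < 2 * group_size:
            raise DataError(
                f"pool of {da.shape[0]} too small for two disjoint groups of "
                f"{group_size}; reduce group_size"
            )
    else:
        db = pool_b.dosage
        if da.shape[0] < group_size or db.shape[0] < group_size:
            raise DataError("pool smaller than group_size; reduce group_size")
    out = np.empty(n_boot)
    for i in range(n_boot):
        if pool_b is None:
            perm = rng.permutation(da.shape[0])
            g1, g2 = da[perm[:group_size]], da[perm[group_size: 2 * group_size]]
        else:
            g1 = da[rng.choice(da.shape[0], group_size, replace=False)]
            g2 = db[rng.choice(db.shape[0], group_size, replace=False)]
        out[i] = theta_from_dosages([g1, g2])
    return out


def panel_power_resampling(
    wild_pool: GenotypeMatrix,
    farmed_pool: GenotypeMatrix,
    group_size: int = 100,
    n_boot: int = 1000,
    panels: tuple[str, ...] = ("diagnostic", "random"),
    seed: int = 0,
) -> pd.DataFrame:
    """Marker-panel power comparison via resampled F_ST distributions.

    For each panel, draws ``n_boot`` theta values for farmed-vs-wild,
    wild-vs-wild and farmed-vs-farmed group pairs of ``group_size`` fish and
    summarizes each distribution (mean, SD, quartiles).
    """
    rows = []
    for panel in panels:
        idx = [i for i, l in enumerate(wild_pool.loci) if l.panel == panel or panel == "all"]
        if not idx:
            raise DataError(f"no loci in panel {panel!r}")
        wp = wild_pool.subset_loci(idx)
        fp = farmed_pool.subset_loci(idx)
        for name, (a, b) in {
            "farmed_vs_wild": (fp, wp),
            "wild_vs_wild": (wp, None),
            "farmed_vs_farmed": (fp, None),
        }.items():
            dist = resampled_fst_distribution(
                a, b, group_size, n_boot,
                seed=rng_for(seed, "power", panel, name).integers(2**31),
            )
            rows.append(
                {"panel": panel, "comparison": name, "mean": dist.mean(),
                 "sd": dist.std(ddof=1), "q25": np.percentile(dist, 25),
                 "median": np.median(dist), "q75": np.percentile(dist, 75),
                 "n_boot": n_boot}
            )
    return pd.DataFrame(rows)
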
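"""Synthetic temporal introgression studies with known truth.

The generator emulates the design of a 20-river temporal SNP study: each
river has a historical and a contemporary sample (13-96 fish), there is one
pool of farmed fish (375 by default), and the 72-locus panel splits into 47
"diagnostic" loci with elevated farmed-wild divergence and 25 random loci.
Wild population structure follows a one-dimensional stepping-stone drift
process along the coastline, which induces isolation by distance; the farmed
pool is founded from mid-coast rivers and given extra drift, more on the
diagnostic panel, so that farmed-vs-wild F_ST on the diagnostic panel is
about twice that on the random panel.  Contemporary samples are produced by
the forward gamete-sampling simulator at a known per-river migration rate
from the farmed pool, so every downstream estimator can be validated against
the generating truth.

Drift steps use the Balding-Nichols parameterization: a step of scale F moves
frequency p to a Beta draw with mean p and variance F * p(1-p).  The step
scales are tuned by bisection, at the allele-frequency level, to hit the
global wild F_ST target and the farmed-panel divergence targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import child_seed, rng_for
from .genodata import (
    DataError,
    GenotypeMatrix,
    Locus,
    PopulationSample,
    StudyDataset,
    write_study,
)
from .introsim import SimulationConfig, generations_from_years, simulate_introgression

_HIST_YEARS = [(1972, 1975), (1977, 1980), (1983, 1986), (1980, 1983), (1986, 1990)]
_CONTEMP_YEARS = (2005, 2008)


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic study.

    Defaults reproduce the emulated study design: 20 rivers, 47 diagnostic +
    25 random loci, samples of 13-96 fish per era, a farmed pool of 375, a
    global wild F_ST around 0.055, farmed-vs-wild divergence roughly twice as
    large on the diagnostic panel as on the random panel, Ne = 200 and true
    per-generation migration rates spanning 0-0.10 across rivers.
    """

    n_rivers: int = 20
    n_diagnostic: int = 47
    n_random: int = 25
    sample_size_range: tuple[int, int] = (13, 96)
    farmed_n: int = 375
    ancestral_beta: tuple[float, float] = (0.8, 0.8)
    freq_bounds: tuple[float, float] = (0.05, 0.95)
    wild_fst_target: float = 0.055
    farm_fst_random_target: float = 0.05
    farm_panel_ratio: float = 2.0
    coastline_km: float = 2500.0
    ne: int = 200
    generation_time: float = 5.0
    true_m: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.true_m is None:
            m = np.linspace(0.0, 0.10, self.n_rivers)
            # deterministic shuffle decouples true m from coastline position
            rng_for(self.seed, "true_m").shuffle(m)
            self.true_m = m
        else:
            self.true_m = np.asarray(self.true_m, dtype=float)
        if self.true_m.size != self.n_rivers:
            raise DataError("true_m must have one entry per river")
        if ((self.true_m < 0) | (self.true_m > 1)).any():
            raise DataError("true_m entries must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.n_diagnostic + self.n_random

    @property
    def rivers(self) -> list[str]:
        return [f"River{i + 1:02d}" for i in range(self.n_rivers)]

    @property
    def positions(self) -> np.ndarray:
        return np.linspace(0.0, self.coastline_km, self.n_rivers)

    def loci(self) -> list[Locus]:
        out = []
        for j in range(self.n_loci):
            panel = "diagnostic" if j < self.n_diagnostic else "random"
            out.append(Locus(id=f"L{j + 1:03d}", panel=panel, ref="A", alt="C"))
        return out


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A pytest-sized study: 4 rivers, 16 + 8 loci, small samples."""
    base = dict(
        n_rivers=4, n_diagnostic=16, n_random=8, sample_size_range=(20, 40),
        farmed_n=60, ne=100, coastline_km=900.0, seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@dataclass
class SyntheticBaseline:
    """Output of the baseline stage: allele frequencies and historical samples."""

    cfg: SyntheticConfig
    river_freqs: np.ndarray  # (n_rivers, n_loci)
    farmed_freqs: np.ndarray  # (n_loci,)
    historical_samples: list[PopulationSample]
    farmed_sample: PopulationSample


# ---------------------------------------------------------------------------
# Frequency-level helpers
# ---------------------------------------------------------------------------

def _drift(p: np.ndarray, scale: float, u: np.ndarray) -> np.ndarray:
    """One Balding-Nichols drift step: Beta with mean p, variance scale*p(1-p).

    Sampling is by inverse CDF from pre-drawn uniforms ``u`` so that, for
    fixed uniforms, the step is a smooth monotone function of ``scale`` --
    which is what lets the calibration bisection hit its target precisely.
    """
    if scale <= 0:
        return p.copy()
    scale = min(scale, 0.95)
    p = np.clip(p, 0.01, 0.99)
    nu = (1 - scale) / scale
    out = stats.beta.ppf(u, p * nu, (1 - p) * nu)
    return np.clip(out, 1e-3, 1 - 1e-3)


def fst_from_freqs(freqs: np.ndarray) -> float:
    """Infinite-sample-size Weir-Cockerham theta from population frequencies.

    For r populations with equal weights, theta = sum_l s2_l / sum_l
    (pbar*qbar + s2_l / r) with s2 the among-population variance (ddof=1).
    """
    p = np.asarray(freqs, dtype=float)
    r = p.shape[0]
    pbar = p.mean(axis=0)
    s2 = p.var(axis=0, ddof=1)
    denom = pbar * (1 - pbar) + s2 / r
    use = denom > 0
    if not use.any():
        return 0.0
    return float(s2[use].sum() / denom[use].sum())


def _bisect(fn, target: float, lo: float, hi: float, tol: float = 1e-4, max_iter: int = 40) -> float:
    """Bisection for an increasing deterministic function; errors if unattainable."""
    if target <= 0:
        return 0.0
    f_hi = fn(hi)
    if f_hi < target:
        raise DataError(
            f"divergence target {target:.4g} unattainable; achieved {f_hi:.4g} "
            f"at maximal drift scale {hi:.3g}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if fn(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * hi:
            break
    return 0.5 * (lo + hi)


def _hw_sample(freqs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Hardy-Weinberg genotype dosages for n individuals at given frequencies."""
    return rng.binomial(2, freqs, size=(n, freqs.size)).astype(float)


# ---------------------------------------------------------------------------
# Baseline generation
# ---------------------------------------------------------------------------

def generate_wild_baseline(cfg: SyntheticConfig) -> SyntheticBaseline:
    """Historical samples for every river plus the farmed pool.

    Ancestral frequencies are drawn from a truncated symmetric Beta; river
    frequencies follow a stepping-stone chain along the coastline whose
    per-step drift scale is bisected to hit the global wild F_ST target; the
    farmed pool is founded from mid-coast rivers with extra drift, larger on
    the diagnostic panel so the diagnostic/random divergence ratio matches
    the configured target.
    """
    loci = cfg.loci()
    rng = rng_for(cfg.seed, "ancestral")
    a, b = cfg.ancestral_beta
    ancestral = np.clip(rng.beta(a, b, size=cfg.n_loci), *cfg.freq_bounds)

    pos = cfg.positions
    steps = np.diff(pos)
    rel_steps = steps / steps.mean() if cfg.n_rivers > 1 else np.array([])

    u_chain = np.random.default_rng(child_seed(cfg.seed, "chain")).random(
        (cfg.n_rivers, cfg.n_loci)
    )

    def chain(c: float) -> np.ndarray:
        freqs = np.empty((cfg.n_rivers, cfg.n_loci))
        freqs[0] = _drift(ancestral, c, u_chain[0])
        for k in range(1, cfg.n_rivers):
            freqs[k] = _drift(freqs[k - 1], c * rel_steps[k - 1], u_chain[k])
        return freqs

    if cfg.n_rivers > 1:
        c = _bisect(lambda x: fst_from_freqs(chain(x)), cfg.wild_fst_target, 1e-6, 0.6)
    else:
        c = cfg.wild_fst_target
    river_freqs = chain(c)

    # farmed pool: founders from mid-coast rivers, then panel-specific drift
    lo_i = cfg.n_rivers // 3
    hi_i = max(lo_i + 1, 2 * cfg.n_rivers // 3)
    founder = river_freqs[lo_i:hi_i].mean(axis=0)
    diag = np.array([l.panel == "diagnostic" for l in loci])

    u_farm = np.random.default_rng(child_seed(cfg.seed, "farm")).random(cfg.n_loci)

    def farm_fst(scale: float, mask: np.ndarray) -> float:
        f = _drift(founder[mask], scale, u_farm[mask])
        vals = [
            fst_from_freqs(np.vstack([f, river_freqs[k][mask]]))
            for k in range(cfg.n_rivers)
        ]
        return float(np.mean(vals))

    target_rand = cfg.farm_fst_random_target
    target_diag = cfg.farm_panel_ratio * target_rand
    s_rand = _bisect(lambda x: farm_fst(x, ~diag), target_rand, 1e-6, 0.9)
    s_diag = _bisect(lambda x: farm_fst(x, diag), target_diag, 1e-6, 0.9)
    farmed = founder.copy()
    farmed[~diag] = _drift(founder[~diag], s_rand, u_farm[~diag])
    farmed[diag] = _drift(founder[diag], s_diag, u_farm[diag])

    # draw genotype samples
    hist_samples = []
    for k, river in enumerate(cfg.rivers):
        r = rng_for(cfg.seed, "hist", river)
        n = int(r.integers(cfg.sample_size_range[0], cfg.sample_size_range[1] + 1))
        dos = _hw_sample(river_freqs[k], n, r)
        gm = GenotypeMatrix([f"{river}_H{i:03d}" for i in range(n)], loci, dos)
        ys, ye = _HIST_YEARS[k % len(_HIST_YEARS)]
        hist_samples.append(PopulationSample(river, "historical", ys, ye, "adult", gm))

    rf = rng_for(cfg.seed, "farmedpool")
    fdos = _hw_sample(farmed, cfg.farmed_n, rf)
    fgm = GenotypeMatrix([f"Farmed_F{i:03d}" for i in range(cfg.farmed_n)], loci, fdos)
    farmed_sample = PopulationSample("FarmedPool", "farmed", 2005, 2010, "farmed", fgm)

    return SyntheticBaseline(cfg, river_freqs, farmed, hist_samples, farmed_sample)


# ---------------------------------------------------------------------------
# Temporal dataset
# ---------------------------------------------------------------------------

def generate_temporal_dataset(
    cfg: SyntheticConfig, baseline: SyntheticBaseline | None = None
) -> tuple[StudyDataset, pd.DataFrame]:
    """Full study: contemporary samples simulated at the known true m.

    Each river's contemporary sample is produced by the forward simulator
    seeded from the river's historical sample, with the farmed pool as donor,
    at the river's configured (true) migration rate.  Returns the dataset and
    a truth table (river, true_m, generations, ne, realized_admixture).
    """
    if baseline is None:
        baseline = generate_wild_baseline(cfg)
    samples: list[PopulationSample] = []
    truth_rows = []
    pop_meta = {}
    pos = cfg.positions
    for k, river in enumerate(cfg.rivers):
        hist = baseline.historical_samples[k]
        samples.append(hist)
        g = generations_from_years(
            (hist.year_start, hist.year_end), _CONTEMP_YEARS, cfg.generation_time
        )
        r = rng_for(cfg.seed, "contemp", river)
        n_out = int(r.integers(cfg.sample_size_range[0], cfg.sample_size_range[1] + 1))
        n_out = min(n_out, cfg.ne)
        sim = simulate_introgression(
            SimulationConfig(
                ne=cfg.ne, generations=g, m=float(cfg.true_m[k]),
                donor_frequencies=baseline.farmed_freqs,
                recipient_seed_sample=hist, sample_size_out=n_out,
                seed=child_seed(cfg.seed, "sim", river),
            )
        )
        gm = sim.genotypes
        gm = GenotypeMatrix(
            [f"{river}_C{i:03d}" for i in range(gm.n_individuals)], gm.loci, gm.dosage
        )
        samples.append(
            PopulationSample(river, "contemporary", *_CONTEMP_YEARS, "adult", gm)
        )
        pop_meta[river] = {"ne": cfg.ne, "coastal_position_km": float(pos[k])}
        truth_rows.append(
            {"river": river, "true_m": float(cfg.true_m[k]), "generations": g,
             "ne": cfg.ne, "realized_admixture": sim.realized_admixture}
        )
    samples.append(baseline.farmed_sample)
    rivers = cfg.rivers
    distances = pd.DataFrame(
        np.abs(pos[:, None] - pos[None, :]), index=rivers, columns=rivers
    )
    dataset = StudyDataset(samples, pop_meta, distances, name=f"synthetic_seed{cfg.seed}")
    return dataset, pd.DataFrame(truth_rows)


def generate_study(cfg: SyntheticConfig) -> tuple[StudyDataset, pd.DataFrame]:
    """Convenience wrapper: baseline + temporal dataset in one call."""
    return generate_temporal_dataset(cfg, generate_wild_baseline(cfg))


def write_fixtures(
    dataset: StudyDataset, truth: pd.DataFrame, out_dir: str | Path
) -> dict:
    """Write the study files (CSV + Genepop + panel + distances) and truth TSV."""
    paths = write_study(dataset, out_dir, stem="synthetic")
    truth_path = Path(out_dir) / "synthetic_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
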
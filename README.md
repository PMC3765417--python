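# introgress

Quantify genetic introgression of farmed Atlantic salmon escapees into wild
river populations from temporally spaced SNP samples.

Farmed salmon escape from aquaculture pens and interbreed with wild
populations. Given a *historical* sample of a river (taken before large-scale
farming), a *contemporary* sample of the same river, and a sample of the
candidate donor population (a pooled farmed stock, or a neighbouring river),
this package estimates the per-generation gene-flow rate *m* — and the
cumulative admixture proportion 1 − (1 − m)^G — that best explains the
observed temporal shift in allele frequencies over and above genetic drift.

The method simulates the river forward in time under a Wright–Fisher model
with immigration and matches the simulated temporal F_ST (Weir–Cockerham θ)
to the observed one, using either iterative regression ABC or a fixed-grid
rejection sampler. Supporting modules provide genotype I/O and QC, summary
statistics (expected heterozygosity, Hardy–Weinberg and linkage
disequilibrium tests), differentiation statistics (θ with permutation tests
and bootstrap CIs, PCoA, isolation by distance), genotype-likelihood
exclusion tests, a calibrated synthetic-study generator, and an end-to-end
pipeline CLI. See [docs/methods.md](docs/methods.md) for the statistical
details and the known information limits of the estimators.

## Quick start (Python)

```python
from introgress.synthdata import SyntheticConfig, generate_study
from introgress.genodata import subset_panel
from introgress.diffstats import wc_theta, fst_permutation_test
from introgress.estimators import AbcConfig, build_template, abc_estimate

# a full synthetic 20-river study with known per-river truth
data, truth = generate_study(SyntheticConfig(seed=7))
diag = subset_panel(data, "diagnostic")   # the high-divergence locus panel

river = "River10"                          # true m = 0.100/generation
hist = diag.get(river, "historical")
contemp = diag.get(river, "contemporary")

res = wc_theta(hist, contemp)
p = fst_permutation_test(hist, contemp, n_perm=999, seed=1)
# temporal theta = 0.0064, permutation p = 0.006

tpl = build_template(diag, river, scenario="farmed")
est, trace = abc_estimate(res.theta, tpl, AbcConfig(seed=1))
# estimated m/generation = 0.081 (G = 4), total admixture = 0.29
# truth: m = 0.100, realized admixture = 0.32
```

## Quick start (CLI)

```bash
# generate a synthetic study with known truth
introgress-abc synth --preset study --seed 7 --out-dir synthetic

# per-sample summary statistics (uHE, HWE, LD)
introgress-abc sumstats synthetic/synthetic_genotypes.csv --out summary.tsv

# full pipeline: QC, summary stats, temporal/pairwise/global F_ST, IBD,
# PCA coordinates, exclusion tests, introgression estimates, manifest
introgress-abc run synthetic/synthetic_genotypes.csv \
    --panel-file synthetic/synthetic_panel.csv \
    --distances synthetic/synthetic_distances.csv \
    --pop-meta synthetic/synthetic_pop_meta.csv \
    --out-dir results --seed 0
```

Other subcommands: `fst`, `ibd`, `power`, `simulate`, `estimate`, `assign`.
All accept `--format csv|genepop` plus sidecar files for locus panels,
inter-river distances and population metadata; run any subcommand with
`--help` for details.

## Input formats

* **Genotype CSV** — one row per individual with columns `sample_id`,
  `river`, `era` (`historical`/`contemporary`/`farmed`), `year_from`,
  `year_to`, then one column per locus with nucleotide genotypes (e.g.
  `A/C`) or dosages. Genepop files are also read and written.
* **Panel CSV** — locus → `diagnostic`/`random` assignment.
* **Distance CSV** — symmetric inter-river coastal distances (km), used for
  isolation-by-distance tests and nearest-neighbour donor scenarios.
* **Population metadata** — optional per-river `ne` estimates.

## Testing

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

`tests/test_acceptance.py` contains end-to-end scientific-property checks
(estimator correctness against an independent oracle, Wright–Fisher drift
and admixture closed forms, parameter recovery, p-value calibration, panel
contrast). Two checks are expected to fail and document known information
limits of the method rather than defects: the ABC's reported SD understates
posterior uncertainty at the null, and rank recovery across a 20-river study
is capped by drift/sampling noise in single temporal θ realizations. Both
are analysed in [docs/methods.md](docs/methods.md).

## Reproduction

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the principal computations on a freshly generated synthetic study —
QC, global and temporal differentiation, isolation by distance, panel
contrast, exclusion tests, and both introgression estimators against known
truth — and writes the headline quantities as JSON. Every stochastic stage
derives its seed deterministically from the master seed, so outputs are
bit-reproducible for a given `--seed`.
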
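"""Shared fixtures: small genotype builders and a pytest-sized synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from introgress.genodata import GenotypeMatrix, Locus, PopulationSample
from introgress.synthdata import generate_study, small_config


def make_loci(n, panel="other"):
    return [Locus(id=f"L{j:03d}", panel=panel, ref="A", alt="C") for j in range(n)]


def make_matrix(dosage, ids=None, loci=None, panel="other"):
    dosage = np.asarray(dosage, dtype=float)
    if ids is None:
        ids = [f"ind{i}" for i in range(dosage.shape[0])]
    if loci is None:
        loci = make_loci(dosage.shape[1], panel=panel)
    return GenotypeMatrix(ids, loci, dosage)


def make_sample(dosage, river="TestRiver", era="historical", years=(1980, 1983),
                ids=None, loci=None):
    return PopulationSample(
        river, era, years[0], years[1], "adult", make_matrix(dosage, ids, loci)
    )


def random_dosage(rng, n, loci, missing_rate=0.0):
    p = rng.uniform(0.1, 0.9, size=loci)
    d = rng.binomial(2, p, size=(n, loci)).astype(float)
    if missing_rate:
        d[rng.random(d.shape) < missing_rate] = np.nan
    return d


@pytest.fixture(scope="session")
def small_study():
    """One deterministic pytest-sized synthetic study with its truth table."""
    return generate_study(small_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(321)
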
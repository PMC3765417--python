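"""Genotype data model, nucleotide recoding, file round-trips and QC filters."""

import numpy as np
import pandas as pd
import pytest

from introgress.genodata import (
    DataError,
    GenotypeMatrix,
    Locus,
    StudyDataset,
    allele_frequencies,
    qc_filter,
    read_genotype_csv,
    read_genepop,
    subset_panel,
    write_genepop,
    write_genotype_csv,
)

from conftest import make_loci, make_matrix, make_sample


def test_nucleotide_recoding_uses_alphabetical_ref(tmp_path):
    # calls AC/CC/AA at one locus: ref=A (alphabetically first), alt=C
    path = tmp_path / "g.csv"
    path.write_text(
        "individual,river,era,year_start,year_end,life_stage,snp1\n"
        "i1,R,historical,1980,1982,adult,AC\n"
        "i2,R,historical,1980,1982,adult,CC\n"
        "i3,R,historical,1980,1982,adult,AA\n"
        "i4,R,historical,1980,1982,adult,\n"
    )
    (sample,) = read_genotype_csv(path)
    loc = sample.genotypes.loci[0]
    assert (loc.ref, loc.alt) == ("A", "C")
    d = sample.genotypes.dosage[:, 0]
    assert d[0] == 1 and d[1] == 2 and d[2] == 0 and np.isnan(d[3])


def test_non_biallelic_locus_rejected(tmp_path):
    path = tmp_path / "g.csv"
    path.write_text(
        "individual,river,era,year_start,year_end,life_stage,snp1\n"
        "i1,R,historical,1980,1982,adult,AC\n"
        "i2,R,historical,1980,1982,adult,GT\n"
    )
    with pytest.raises(DataError, match="biallelic"):
        read_genotype_csv(path)


def test_duplicate_individual_ids_rejected():
    loci = make_loci(2)
    with pytest.raises(DataError):
        GenotypeMatrix(["a", "a"], loci, np.zeros((2, 2)))


def test_allele_frequencies_hand_example():
    gm = make_matrix([[0.0], [1.0], [2.0], [np.nan]])
    af = allele_frequencies(gm)
    assert af["freq"].iloc[0] == pytest.approx(0.5)
    assert af["n_called"].iloc[0] == 3
    assert af["n_alt"].iloc[0] == 3 and af["n_ref"].iloc[0] == 3
    assert not af["monomorphic"].iloc[0]


def test_qc_drops_loci_before_individuals():
    # Locus 0 is missing in half the individuals and is removed first; the
    # individual whose missing calls are concentrated in that locus then
    # passes the 75% coverage rule over the retained loci.
    d_contemp = np.ones((4, 3))
    d = np.ones((4, 3))
    d[0, 0] = np.nan
    d[1, 0] = np.nan
    d[0, 1] = np.nan  # ind0: 1/3 coverage overall, 1/2 over retained loci
    hist = make_sample(d)
    contemp = make_sample(d_contemp, era="contemporary", years=(2005, 2008),
                          ids=[f"c{i}" for i in range(4)])
    # pooled coverage: locus0 6/8 = 0.75 (removed), locus1 7/8 = 0.875 (kept)
    ds = StudyDataset([hist, contemp])
    filtered, report = qc_filter(ds, locus_min_coverage=0.85,
                                 individual_min_coverage=0.45)
    assert filtered.loci[0].id != "L000"
    assert len(filtered.loci) == 2
    locus_rows = report[report["type"] == "locus"]
    assert (locus_rows.set_index("entity").loc["L000", "action"]) == "removed"
    # ind0 kept: coverage over retained loci (1/2) >= 0.45, though its overall
    # coverage (1/3) is below threshold — loci are filtered first
    assert filtered.samples[0].genotypes.n_individuals == 4
    assert 0 < report.attrs["overall_call_rate"] <= 1


def test_qc_is_idempotent(small_study):
    data, _ = small_study
    once, _ = qc_filter(data)
    twice, _ = qc_filter(once)
    assert [l.id for l in once.loci] == [l.id for l in twice.loci]
    for s1, s2 in zip(once.samples, twice.samples):
        assert s1.genotypes.individuals == s2.genotypes.individuals
        np.testing.assert_array_equal(s1.genotypes.dosage, s2.genotypes.dosage)


def test_csv_round_trip(small_study, tmp_path):
    data, _ = small_study
    path = tmp_path / "study.csv"
    write_genotype_csv(data, path)
    back = read_genotype_csv(path)
    assert len(back) == len(data.samples)
    for orig, rt in zip(data.samples, back):
        assert (orig.river, orig.era, orig.year_start, orig.year_end) == (
            rt.river, rt.era, rt.year_start, rt.year_end)
        assert orig.genotypes.individuals == rt.genotypes.individuals
        # recoding fixes ref alphabetically; dosage either matches or is flipped
        # consistently per locus (2 - d) when the original alt sorts first
        for j in range(orig.genotypes.n_loci):
            o, r = orig.genotypes.dosage[:, j], rt.genotypes.dosage[:, j]
            same = np.allclose(o, r, equal_nan=True)
            flipped = np.allclose(o, 2 - r, equal_nan=True)
            assert same or flipped


def test_genepop_round_trip(small_study, tmp_path):
    data, _ = small_study
    path = tmp_path / "study.gen"
    write_genepop(data, path)
    back = read_genepop(path)
    assert len(back) == len(data.samples)
    for orig, rt in zip(data.samples, back):
        assert (orig.river, orig.era) == (rt.river, rt.era)
        assert orig.genotypes.individuals == rt.genotypes.individuals
        np.testing.assert_allclose(
            orig.genotypes.dosage, rt.genotypes.dosage, equal_nan=True
        )


def test_subset_panel_restricts_loci(small_study):
    data, _ = small_study
    diag = subset_panel(data, "diagnostic")
    assert all(l.panel == "diagnostic" for l in diag.loci)
    rand = subset_panel(data, "random")
    assert len(diag.loci) + len(rand.loci) == len(data.loci)
    with pytest.raises(DataError):
        subset_panel(data, "nonexistent")


def test_nearest_neighbour_on_three_river_line():
    d = np.ones((3, 2))
    samples = []
    for r in ("A", "B", "C"):
        samples.append(make_sample(d, river=r, ids=[f"{r}{i}" for i in range(3)]))
        samples.append(make_sample(d, river=r, era="contemporary",
                                   years=(2005, 2008),
                                   ids=[f"{r}c{i}" for i in range(3)]))
    km = pd.DataFrame(
        [[0, 10, 100], [10, 0, 90], [100, 90, 0]],
        index=["A", "B", "C"], columns=["A", "B", "C"], dtype=float,
    )
    ds = StudyDataset(samples, distances=km)
    assert ds.nearest_neighbour("C") == "B"
    assert ds.nearest_neighbour("A") == "B"
    assert ds.nearest_neighbour("B") == "A"


def test_year_midpoint_and_labels():
    s = make_sample(np.ones((2, 2)), river="Vosso", years=(1980, 1986))
    assert s.year_midpoint == pytest.approx(1983.0)
    assert "Vosso" in s.label and "historical" in s.label
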
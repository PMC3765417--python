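"""Genotype data model, file I/O and quality-control filters.

The substrate of every statistic in the package is a diploid, biallelic SNP
genotype table.  Genotypes are stored as alt-allele dosages (0, 1, 2; NaN for
missing calls) inside a :class:`GenotypeMatrix`; a :class:`PopulationSample`
wraps one matrix with its sampling metadata (river, era, year range, life
stage), and a :class:`StudyDataset` collects all samples of a temporal study
together with per-river metadata (effective size, coastal position) and the
pairwise distance matrix between river mouths.

Two on-disk formats are supported: a CSV dialect carrying sample metadata in
columns, and classic Genepop (4-digit genotype codes, ``0000`` = missing).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PANELS = ("diagnostic", "random", "other")
ERAS = ("historical", "contemporary", "farmed")
LIFE_STAGES = ("adult", "parr", "smolt", "farmed")


class DataError(ValueError):
    """Raised for malformed or inconsistent genotype data."""


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP locus.

    ``ref`` is, by convention, the alphabetically first nucleotide observed at
    the locus, so the ref/alt recoding is deterministic and independent of
    sample order. ``panel`` records membership in the diagnostic vs random
    marker panels used throughout the analysis.
    """

    id: str
    panel: str = "other"
    chromosome: str | None = None
    position: int | None = None
    ref: str = "A"
    alt: str = "C"

    def __post_init__(self):
        if self.panel not in PANELS:
            raise DataError(f"unknown panel {self.panel!r} for locus {self.id}")


class GenotypeMatrix:
    """Individuals x loci alt-allele dosages with missingness.

    Parameters
    ----------
    individuals : sequence of str
        Unique individual identifiers (rows).
    loci : sequence of Locus
        Locus definitions (columns); ids must be unique.
    dosage : ndarray of shape (n_individuals, n_loci)
        Alt-allele dosage per call: 0, 1, 2 or NaN (missing).
    """

    def __init__(self, individuals: Sequence[str], loci: Sequence[Locus], dosage: np.ndarray):
        individuals = list(individuals)
        loci = list(loci)
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(individuals), len(loci)):
            raise DataError(
                f"dosage shape {dosage.shape} inconsistent with "
                f"{len(individuals)} individuals x {len(loci)} loci"
            )
        if len(set(individuals)) != len(individuals):
            dup = pd.Series(individuals).value_counts()
            raise DataError(f"duplicated individual ids: {list(dup[dup > 1].index)}")
        ids = [l.id for l in loci]
        if len(set(ids)) != len(ids):
            raise DataError("duplicated locus ids")
        ok = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise DataError("dosages must be 0, 1, 2 or NaN")
        self.individuals = individuals
        self.loci = loci
        self.dosage = dosage

    # -- basic introspection -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    def locus_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per locus."""
        if self.n_individuals == 0:
            return np.zeros(self.n_loci)
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per individual."""
        if self.n_loci == 0:
            return np.zeros(self.n_individuals)
        return 1.0 - np.isnan(self.dosage).mean(axis=1)

    # -- subsetting ----------------------------------------------------------
    def subset_loci(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.individuals, [self.loci[i] for i in keep], self.dosage[:, keep]
        )

    def subset_individuals(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            [self.individuals[i] for i in keep], self.loci, self.dosage[keep, :]
        )

    @staticmethod
    def stack(matrices: Sequence["GenotypeMatrix"]) -> "GenotypeMatrix":
        """Row-stack matrices sharing an identical locus set."""
        first = matrices[0]
        for m in matrices[1:]:
            if m.locus_ids != first.locus_ids:
                raise DataError("cannot stack matrices with different locus sets")
        inds = [i for m in matrices for i in m.individuals]
        dos = np.vstack([m.dosage for m in matrices])
        return GenotypeMatrix(inds, first.loci, dos)


@dataclass
class PopulationSample:
    """A labelled cohort: one river in one era, wrapping a genotype matrix."""

    river: str
    era: str
    year_start: int
    year_end: int
    life_stage: str
    genotypes: GenotypeMatrix

    def __post_init__(self):
        if self.era not in ERAS:
            raise DataError(f"unknown era {self.era!r}")
        if self.life_stage not in LIFE_STAGES:
            raise DataError(f"unknown life stage {self.life_stage!r}")
        if self.year_start > self.year_end:
            raise DataError(f"{self.river}: year_start > year_end")

    @property
    def label(self) -> str:
        return f"{self.river}:{self.era}"

    @property
    def n(self) -> int:
        return self.genotypes.n_individuals

    @property
    def year_midpoint(self) -> float:
        return 0.5 * (self.year_start + self.year_end)


@dataclass
class StudyDataset:
    """All samples of a temporal introgression study plus river metadata.

    ``pop_meta`` maps river name to ``{"ne": int, "coastal_position_km": float}``;
    ``distances`` is a symmetric DataFrame of km between river mouths.
    """

    samples: list[PopulationSample]
    pop_meta: dict = field(default_factory=dict)
    distances: pd.DataFrame | None = None
    name: str = "study"

    def __post_init__(self):
        if self.distances is not None:
            d = self.distances
            if not np.allclose(d.values, d.values.T) or not np.allclose(np.diag(d.values), 0):
                raise DataError("distance matrix must be symmetric with zero diagonal")
        seen: set[str] = set()
        for s in self.samples:
            for ind in s.genotypes.individuals:
                if ind in seen:
                    raise DataError(f"duplicated individual id across samples: {ind}")
                seen.add(ind)

    # -- lookup helpers ------------------------------------------------------
    @property
    def rivers(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.era != "farmed" and s.river not in out:
                out.append(s.river)
        return out

    @property
    def loci(self) -> list[Locus]:
        return self.samples[0].genotypes.loci

    def get(self, river: str, era: str) -> PopulationSample:
        for s in self.samples:
            if s.river == river and s.era == era:
                return s
        raise KeyError(f"no sample {river}:{era}")

    @property
    def farmed(self) -> PopulationSample | None:
        for s in self.samples:
            if s.era == "farmed":
                return s
        return None

    def nearest_neighbour(self, river: str) -> str:
        """River with minimal coastal distance to ``river``."""
        if self.distances is None:
            raise DataError("no distance matrix available")
        row = self.distances.loc[river].drop(river)
        row = row[[r for r in row.index if r in self.rivers]]
        if row.empty:
            raise DataError(f"river {river} has no neighbour")
        return str(row.idxmin())


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(sample: PopulationSample | GenotypeMatrix) -> pd.DataFrame:
    """Per-locus alt-allele frequency and allele counts.

    Frequency is the alt-dosage sum divided by twice the number of non-missing
    individuals (pairwise deletion of missing calls). Loci with no calls get
    NaN frequency and ``available=False``; monomorphic loci are flagged but
    kept.
    """
    gm = sample.genotypes if isinstance(sample, PopulationSample) else sample
    called = (~np.isnan(gm.dosage)).sum(axis=0)
    alt = np.nansum(gm.dosage, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, alt / (2.0 * np.maximum(called, 1)), np.nan)
    freq = np.where(called > 0, freq, np.nan)
    return pd.DataFrame(
        {
            "freq": freq,
            "n_called": called.astype(int),
            "n_alt": alt.astype(int),
            "n_ref": (2 * called - alt).astype(int),
            "available": called > 0,
            "monomorphic": (called > 0) & ((freq <= 0) | (freq >= 1)),
        },
        index=pd.Index(gm.locus_ids, name="locus"),
    )


# ---------------------------------------------------------------------------
# Panel subsetting
# ---------------------------------------------------------------------------

def subset_panel(data: StudyDataset, panel: str) -> StudyDataset:
    """Restrict the dataset to loci of one panel (diagnostic/random/other)."""
    if panel == "all":
        return data
    if panel not in PANELS:
        raise DataError(f"unknown panel {panel!r}")
    idx = [i for i, l in enumerate(data.loci) if l.panel == panel]
    if not idx:
        raise DataError(f"no loci in panel {panel!r}")
    samples = [replace(s, genotypes=s.genotypes.subset_loci(idx)) for s in data.samples]
    return StudyDataset(samples, data.pop_meta, data.distances, data.name)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_filter(
    data: StudyDataset,
    locus_min_coverage: float = 0.90,
    individual_min_coverage: float = 0.75,
) -> tuple[StudyDataset, pd.DataFrame]:
    """Two-stage QC: drop low-coverage loci, then low-coverage individuals.

    Locus coverage is computed over the entire pooled dataset (all samples);
    loci below ``locus_min_coverage`` are removed first.  Individual coverage
    is then computed over the *retained* loci, and individuals below
    ``individual_min_coverage`` are removed.  Returns the filtered dataset and
    a report table with columns ``entity, type, coverage, action``.
    """
    for t in (locus_min_coverage, individual_min_coverage):
        if not (0 < t <= 1):
            raise DataError("coverage thresholds must lie in (0, 1]")
    pooled = GenotypeMatrix.stack([s.genotypes for s in data.samples])
    loc_cov = pooled.locus_call_rate()
    keep_loci = np.where(loc_cov >= locus_min_coverage)[0]
    if keep_loci.size == 0:
        raise DataError("all loci removed by QC filter")

    rows = [
        {"entity": pooled.locus_ids[i], "type": "locus", "coverage": loc_cov[i],
         "action": "kept" if loc_cov[i] >= locus_min_coverage else "removed"}
        for i in range(pooled.n_loci)
    ]

    new_samples = []
    for s in data.samples:
        gm = s.genotypes.subset_loci(keep_loci)
        ind_cov = gm.individual_call_rate()
        keep_ind = np.where(ind_cov >= individual_min_coverage)[0]
        for j in range(gm.n_individuals):
            rows.append(
                {"entity": gm.individuals[j], "type": "individual",
                 "coverage": ind_cov[j],
                 "action": "kept" if ind_cov[j] >= individual_min_coverage else "removed"}
            )
        if keep_ind.size == 0:
            raise DataError(f"sample {s.label} empty after QC filtering")
        new_samples.append(replace(s, genotypes=gm.subset_individuals(keep_ind)))

    filtered = StudyDataset(new_samples, data.pop_meta, data.distances, data.name)
    report = pd.DataFrame(rows, columns=["entity", "type", "coverage", "action"])
    overall = GenotypeMatrix.stack([s.genotypes for s in filtered.samples])
    report.attrs["overall_call_rate"] = float(1 - np.isnan(overall.dosage).mean())
    return filtered, report


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_META_COLS = ["individual", "river", "era", "year_start", "year_end", "life_stage"]


def _recode_calls(calls: pd.Series, locus_id: str) -> tuple[np.ndarray, str, str]:
    """Map two-character nucleotide call strings to alt dosages.

    The two observed nucleotides become ref/alt with ref the alphabetically
    first; more than two observed alleles is an error.
    """
    alleles: set[str] = set()
    for c in calls:
        if isinstance(c, str) and c:
            if len(c) != 2:
                raise DataError(f"locus {locus_id}: malformed call {c!r}")
            alleles.update(c)
    if len(alleles) > 2:
        raise DataError(f"locus {locus_id} not biallelic: alleles {sorted(alleles)}")
    ordered = sorted(alleles)
    ref = ordered[0] if ordered else "A"
    alt = ordered[1] if len(ordered) > 1 else ref
    dos = np.full(len(calls), np.nan)
    for i, c in enumerate(calls):
        if isinstance(c, str) and c:
            dos[i] = sum(1 for a in c if a == alt) if alt != ref else 0.0
    return dos, ref, alt


def read_genotype_csv(path: str | Path) -> list[PopulationSample]:
    """Read the CSV genotype dialect into population samples.

    Header: ``individual,river,era,year_start,year_end,life_stage,<locus...>``;
    calls are two-character nucleotide strings (``AC``), empty = missing.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise DataError(f"CSV missing metadata columns: {missing}")
    locus_cols = [c for c in df.columns if c not in _META_COLS]
    if df["individual"].duplicated().any():
        dup = df["individual"][df["individual"].duplicated()].tolist()
        raise DataError(f"duplicated individual ids: {dup}")

    dosage = np.empty((len(df), len(locus_cols)))
    loci = []
    for j, lc in enumerate(locus_cols):
        dos, ref, alt = _recode_calls(df[lc], lc)
        dosage[:, j] = dos
        loci.append(Locus(id=lc, ref=ref, alt=alt))

    samples = []
    for (river, era, ys, ye, stage), grp in df.groupby(
        ["river", "era", "year_start", "year_end", "life_stage"], sort=False
    ):
        gm = GenotypeMatrix(grp["individual"].tolist(), loci, dosage[grp.index.values])
        samples.append(PopulationSample(river, era, int(ys), int(ye), stage, gm))
    return samples


def write_genotype_csv(data: StudyDataset, path: str | Path) -> None:
    """Write all samples in the CSV genotype dialect (inverse of the reader)."""
    loci = data.loci
    rows = []
    for s in data.samples:
        gm = s.genotypes
        for i, ind in enumerate(gm.individuals):
            row = {
                "individual": ind, "river": s.river, "era": s.era,
                "year_start": s.year_start, "year_end": s.year_end,
                "life_stage": s.life_stage,
            }
            for j, loc in enumerate(loci):
                d = gm.dosage[i, j]
                if np.isnan(d):
                    row[loc.id] = ""
                else:
                    k = int(d)
                    row[loc.id] = "".join(sorted(loc.ref * (2 - k) + loc.alt * k))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genepop format
# ---------------------------------------------------------------------------
# Allele codes: ref=01, alt=02, missing genotype "0000".  Sample metadata is
# carried in the individual labels as river|era|year_start|year_end|stage|id,
# since Genepop itself has no metadata fields.

def write_genepop(data: StudyDataset, path: str | Path) -> None:
    loci = data.loci
    buf = io.StringIO()
    buf.write(f"{data.name}\n")
    for loc in loci:
        buf.write(f"{loc.id}\n")
    for s in data.samples:
        buf.write("POP\n")
        gm = s.genotypes
        for i, ind in enumerate(gm.individuals):
            label = f"{s.river}|{s.era}|{s.year_start}|{s.year_end}|{s.life_stage}|{ind}"
            codes = []
            for d in gm.dosage[i]:
                if np.isnan(d):
                    codes.append("0000")
                else:
                    k = int(d)
                    a = ["01"] * (2 - k) + ["02"] * k
                    codes.append("".join(a))
            buf.write(f"{label} ,  " + " ".join(codes) + "\n")
    Path(path).write_text(buf.getvalue())


def read_genepop(path: str | Path) -> list[PopulationSample]:
    """Read a Genepop file written by :func:`write_genepop`.

    Generic Genepop files parse too, but sample metadata (river, era, years)
    is only recovered when individual labels follow the pipe-delimited
    convention of the writer; otherwise samples are named pop1, pop2, ... and
    tagged era=historical.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    if not lines:
        raise DataError("empty Genepop file")
    # locus names: one per line (or comma-separated on one line) until POP
    i = 1
    locus_names: list[str] = []
    while i < len(lines) and lines[i].strip().upper() != "POP":
        locus_names.extend([x.strip() for x in lines[i].split(",") if x.strip()])
        i += 1
    pops: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] | None = None
    for ln in lines[i:]:
        if ln.strip().upper() == "POP":
            current = []
            pops.append(current)
            continue
        if not ln.strip():
            continue
        if current is None:
            raise DataError("Genepop data before first POP")
        name, _, rest = ln.partition(",")
        codes = rest.split()
        if len(codes) != len(locus_names):
            raise DataError(f"individual {name.strip()}: {len(codes)} genotypes "
                            f"for {len(locus_names)} loci")
        current.append((name.strip(), codes))

    samples = []
    all_ids: set[str] = set()
    for p_idx, pop in enumerate(pops):
        n = len(pop)
        dosage = np.full((n, len(locus_names)), np.nan)
        inds = []
        meta = None
        for r, (label, codes) in enumerate(pop):
            parts = label.split("|")
            if len(parts) == 6:
                river, era, ys, ye, stage, ind = parts
                meta = (river, era, int(ys), int(ye), stage)
            else:
                ind = label
                meta = meta or (f"pop{p_idx + 1}", "historical", 0, 0, "adult")
            inds.append(ind)
            for j, code in enumerate(codes):
                if code == "0000":
                    continue
                a1, a2 = code[:2], code[2:]
                dosage[r, j] = (a1 != "01") + (a2 != "01")
        if any(ind in all_ids for ind in inds):
            raise DataError("duplicated individual ids across POPs")
        all_ids.update(inds)
        loci = [Locus(id=nm, ref="1", alt="2") for nm in locus_names]
        gm = GenotypeMatrix(inds, loci, dosage)
        river, era, ys, ye, stage = meta
        samples.append(PopulationSample(river, era, ys, ye, stage, gm))
    return samples


# ---------------------------------------------------------------------------
# Assembling a StudyDataset from files
# ---------------------------------------------------------------------------

def read_panel_csv(path: str | Path) -> pd.DataFrame:
    """Locus panel table: ``locus,panel,chromosome,position``."""
    df = pd.read_csv(path)
    if "locus" not in df.columns or "panel" not in df.columns:
        raise DataError("panel CSV needs 'locus' and 'panel' columns")
    return df.set_index("locus")


def read_distance_csv(path: str | Path) -> pd.DataFrame:
    """Square km distance matrix with river names as header row/column."""
    df = pd.read_csv(path, index_col=0)
    df.columns = [str(c) for c in df.columns]
    return df


def read_genotype_table(
    path: str | Path,
    format: str = "csv",
    panel_path: str | Path | None = None,
    distance_path: str | Path | None = None,
    pop_meta_path: str | Path | None = None,
    name: str = "study",
) -> StudyDataset:
    """Read genotypes (+ optional panel / distance / metadata tables).

    ``format`` is ``csv`` or ``genepop``.  The panel CSV attaches
    diagnostic/random labels to loci; the pop-meta CSV
    (``river,ne,coastal_position_km``) supplies per-river effective sizes and
    coastal positions, from which a distance matrix is derived when no
    explicit one is given.
    """
    if format == "csv":
        samples = read_genotype_csv(path)
    elif format == "genepop":
        samples = read_genepop(path)
    else:
        raise DataError(f"unknown format {format!r}")

    if panel_path is not None:
        panel = read_panel_csv(panel_path)
        new_loci = []
        for loc in samples[0].genotypes.loci:
            if loc.id in panel.index:
                row = panel.loc[loc.id]
                chrom = row.get("chromosome")
                pos = row.get("position")
                loc = replace(
                    loc,
                    panel=str(row["panel"]),
                    chromosome=None if pd.isna(chrom) else str(chrom),
                    position=None if pd.isna(pos) else int(pos),
                )
            new_loci.append(loc)
        for s in samples:
            s.genotypes.loci = new_loci

    pop_meta: dict = {}
    if pop_meta_path is not None:
        pm = pd.read_csv(pop_meta_path).set_index("river")
        for river, row in pm.iterrows():
            pop_meta[str(river)] = {
                "ne": int(row["ne"]),
                "coastal_position_km": float(row["coastal_position_km"]),
            }

    distances = None
    if distance_path is not None:
        distances = read_distance_csv(distance_path)
    elif pop_meta:
        rivers = list(pop_meta)
        pos = np.array([pop_meta[r]["coastal_position_km"] for r in rivers])
        distances = pd.DataFrame(
            np.abs(pos[:, None] - pos[None, :]), index=rivers, columns=rivers
        )
    return StudyDataset(samples, pop_meta, distances, name)


def write_study(data: StudyDataset, out_dir: str | Path, stem: str = "study") -> dict:
    """Write genotypes (CSV + Genepop), panel, distances and pop metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "csv": out / f"{stem}_genotypes.csv",
        "genepop": out / f"{stem}.gen",
        "panel": out / f"{stem}_panel.csv",
    }
    write_genotype_csv(data, paths["csv"])
    write_genepop(data, paths["genepop"])
    pd.DataFrame(
        [
            {"locus": l.id, "panel": l.panel, "chromosome": l.chromosome,
             "position": l.position}
            for l in data.loci
        ]
    ).to_csv(paths["panel"], index=False)
    if data.distances is not None:
        paths["distances"] = out / f"{stem}_distances.csv"
        data.distances.to_csv(paths["distances"])
    if data.pop_meta:
        paths["pop_meta"] = out / f"{stem}_pop_meta.csv"
        pd.DataFrame(
            [
                {"river": r, "ne": m["ne"],
                 "coastal_position_km": m["coastal_position_km"]}
                for r, m in data.pop_meta.items()
            ]
        ).to_csv(paths["pop_meta"], index=False)
    return paths
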
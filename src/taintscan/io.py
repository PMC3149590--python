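"""Readers and writers for the on-disk formats, and the detection-limit
log transform applied to all trait values before model fitting.

Formats:

* PLINK text ``.ped``/``.map`` for unphased genotypes (alleles recoded to
  0/1/2 dosages of the minor allele);
* TSV tables for pedigree (id, sire, dam; ``0`` = unknown), phenotypes
  (id, trait_ppm, station, age_entry, days_test, litter_alive) and phased
  haplotypes (individual, chrom, hap, alleles);
* results/regions TSV handled by the scan and significance modules.

Readers validate and reject malformed rows rather than coercing them;
every writer/reader pair round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genmap import MAP_COLUMNS, validate_map
from .relationship import UNKNOWN, _toposort

MISSING = -1  # missing genotype code in dosage matrices

#: Assay floors (ppm) added to every measurement before log transformation.
DETECTION_LIMITS = {
    "androstenone": 0.05,
    "skatole": 0.01,
    "indole": 0.01,
    "testosterone": 0.5,
    "estrone_sulphate": 0.5,
    "estradiol": 0.04,
}

PHENOTYPE_COLUMNS = [
    "id",
    "trait_ppm",
    "station",
    "age_entry",
    "days_test",
    "litter_alive",
]


@dataclass
class GenotypeMatrix:
    """Unphased dosage matrix: individuals x SNPs, entries 0/1/2 or -1.

    Entry counts copies of the '1' allele; ``counted_allele`` records,
    per SNP, which input allele symbol is counted (orientation is
    arbitrary in the source data, minor-within-cohort by default).
    """

    samples: list[str]
    snp_ids: list[str]
    values: np.ndarray  # int8, shape (n_samples, n_snps)
    counted_allele: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.samples), len(self.snp_ids)):
            raise ValueError("genotype matrix shape mismatch")
        if not self.counted_allele:
            self.counted_allele = ["1"] * len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, sample_mask=None, snp_mask=None) -> "GenotypeMatrix":
        sm = np.ones(self.n_samples, bool) if sample_mask is None else sample_mask
        km = np.ones(self.n_snps, bool) if snp_mask is None else snp_mask
        return GenotypeMatrix(
            [s for s, keep in zip(self.samples, sm) if keep],
            [s for s, keep in zip(self.snp_ids, km) if keep],
            self.values[np.ix_(sm, km)],
            [a for a, keep in zip(self.counted_allele, km) if keep],
        )


@dataclass
class HaplotypeSet:
    """Phased alleles: shape (n_individuals, 2, n_snps), entries 0/1."""

    samples: list[str]
    marker_map: pd.DataFrame
    alleles: np.ndarray  # int8 (n, 2, m)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        n, two, m = self.alleles.shape
        if two != 2 or n != len(self.samples) or m != len(self.marker_map):
            raise ValueError("haplotype array shape mismatch")

    def dosages(self) -> GenotypeMatrix:
        """Unphased 0/1/2 matrix (sum of the two haplotypes)."""
        return GenotypeMatrix(
            list(self.samples),
            list(self.marker_map["snp_id"]),
            self.alleles.sum(axis=1),
        )

    def subset_samples(self, ids) -> "HaplotypeSet":
        idx = {s: k for k, s in enumerate(self.samples)}
        rows = [idx[str(i)] for i in ids]
        return HaplotypeSet([str(i) for i in ids], self.marker_map, self.alleles[rows])


def log_transform(ppm, detection_limit: float):
    """ln(ppm + detection limit).

    Values below the assay detection limit are recorded as 0 in the raw
    data; adding the limit before taking logs keeps them (finite) in the
    analysis instead of dropping them.
    """
    ppm = np.asarray(ppm, dtype=float)
    if np.any(ppm < 0):
        raise ValueError("trait values (ppm) must be non-negative")
    if detection_limit <= 0:
        raise ValueError("detection limit must be positive")
    out = np.log(ppm + detection_limit)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------- PLINK


def write_plink(g: GenotypeMatrix, marker_map: pd.DataFrame, ped_path, map_path):
    """Write text PLINK; dosage d is emitted as d copies of allele '2'.

    (Allele '2' is the counted allele so that a round-trip through
    :func:`read_plink`, which counts the minor allele, is the identity
    whenever the counted allele is minor.)
    """
    with open(map_path, "w") as fh:
        for r in marker_map.itertuples():
            fh.write(f"{r.chrom}\t{r.snp_id}\t{r.cM:.6f}\t{r.bp}\n")
    code = {MISSING: ("0", "0"), 0: ("1", "1"), 1: ("1", "2"), 2: ("2", "2")}
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(g.samples):
            fields = [sample, sample, "0", "0", "0", "-9"]
            for d in g.values[i]:
                fields.extend(code[int(d)])
            fh.write(" ".join(fields) + "\n")


def read_plink(ped_path, map_path, minor_as_one: bool = True):
    """Read text PLINK into a dosage matrix and marker map.

    Alleles are recoded to 0/1/2 counting the minor allele within the
    file (ties broken by symbol order); '0 0' is missing. A SNP with more
    than two distinct alleles is a format error.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{map_path}:{ln}: expected 4 columns")
            chrom, snp_id, cm, bp = parts
            map_rows.append((snp_id, int(chrom), int(bp), float(cm)))
    marker_map = pd.DataFrame(map_rows, columns=MAP_COLUMNS)
    validate_map(marker_map)
    m = len(marker_map)

    samples, raw = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            samples.append(parts[1])
            raw.append(parts[6:])
    alleles = np.array(raw, dtype="U8").reshape(len(samples), m, 2)

    values = np.full((len(samples), m), MISSING, dtype=np.int8)
    counted = []
    for j, snp_id in enumerate(marker_map["snp_id"]):
        col = alleles[:, j, :]
        called = col != "0"
        if (called.sum(axis=1) == 1).any():
            raise ValueError(f"half-missing genotype at SNP {snp_id}")
        symbols, counts = np.unique(col[called], return_counts=True)
        if len(symbols) > 2:
            raise ValueError(f"SNP {snp_id} has >2 alleles: {list(symbols)}")
        if len(symbols) == 0:
            counted.append("?")
            continue
        if len(symbols) == 1:
            # monomorphic: count the observed allele; the MAF filter flags it
            one = symbols[0]
        else:
            order = np.argsort(counts, kind="stable")
            one = symbols[order[0]] if minor_as_one else symbols[order[1]]
        counted.append(str(one))
        full = called.all(axis=1)
        values[full, j] = (col[full] == one).sum(axis=1)
    g = GenotypeMatrix(samples, list(marker_map["snp_id"]), values, counted)
    return g, marker_map


# ---------------------------------------------------------------- TSV tables


def write_pedigree(ped: pd.DataFrame, path):
    ped[["id", "sire", "dam"]].to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    """Read and validate a 3-column pedigree (id, sire, dam; 0 unknown)."""
    ped = pd.read_csv(path, sep="\t", dtype=str).fillna(UNKNOWN)
    missing = [c for c in ("id", "sire", "dam") if c not in ped.columns]
    if missing:
        raise ValueError(f"pedigree missing columns: {missing}")
    if ped["id"].duplicated().any():
        dup = ped.loc[ped["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate pedigree id: {dup}")
    _toposort(ped)  # raises on cycles
    return ped


def write_phenotypes(phen: pd.DataFrame, path):
    phen[PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_phenotypes(path, ped: pd.DataFrame | None = None) -> pd.DataFrame:
    phen = pd.read_csv(path, sep="\t", dtype={"id": str, "station": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in phen.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if (phen["trait_ppm"] < 0).any():
        bad = phen.loc[phen["trait_ppm"] < 0].index[0]
        raise ValueError(f"negative trait value at row {bad}")
    if ped is not None:
        known = set(ped["id"].astype(str))
        orphan = set(phen["id"]) - known
        if orphan:
            raise ValueError(f"phenotype ids absent from pedigree: {sorted(orphan)[:5]}")
    return phen


def write_phased_haplotypes(haps: HaplotypeSet, path):
    """One row per (individual, chromosome, haplotype): allele string."""
    chroms = haps.marker_map["chrom"].to_numpy()
    with open(path, "w") as fh:
        fh.write("individual\tchrom\thap\talleles\n")
        for chrom in np.unique(chroms):
            cols = np.where(chroms == chrom)[0]
            for i, sample in enumerate(haps.samples):
                for h in (0, 1):
                    s = "".join(map(str, haps.alleles[i, h, cols]))
                    fh.write(f"{sample}\t{chrom}\t{h}\t{s}\n")


def read_phased_haplotypes(path, marker_map: pd.DataFrame) -> HaplotypeSet:
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "alleles": str})
    chroms = marker_map["chrom"].to_numpy()
    samples = list(dict.fromkeys(df["individual"]))
    idx = {s: k for k, s in enumerate(samples)}
    alleles = np.full((len(samples), 2, len(marker_map)), -1, dtype=np.int8)
    for r in df.itertuples():
        cols = np.where(chroms == r.chrom)[0]
        if len(r.alleles) != len(cols):
            raise ValueError(
                f"haplotype length {len(r.alleles)} != {len(cols)} markers "
                f"on chromosome {r.chrom} (individual {r.individual})"
            )
        alleles[idx[r.individual], r.hap, cols] = np.frombuffer(
            r.alleles.encode(), dtype=np.uint8
        ) - ord("0")
    if (alleles < 0).any():
        raise ValueError("incomplete phased haplotypes: some markers unassigned")
    return HaplotypeSet(samples, marker_map, alleles)


def write_marker_map(marker_map: pd.DataFrame, path):
    marker_map[MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> pd.DataFrame:
    mm = pd.read_csv(path, sep="\t")
    validate_map(mm)
    return mm


def write_genotype_tsv(g: GenotypeMatrix, path):
    df = pd.DataFrame(g.values, index=g.samples, columns=g.snp_ids)
    df.replace(MISSING, pd.NA).to_csv(path, sep="\t", index_label="id")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
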
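"""Synthetic half-sib study generator.

Emulates a boar test-station design: unrelated sires each mated to several
unrelated dams (one offspring per dam, so paternal half-sib families),
phased founder haplotypes drawn from a finite template pool (which induces
linkage disequilibrium), gene-drop inheritance with Haldane/Poisson
recombination, and a censored log-normal trait controlled by known QTL,
polygenic and fixed effects. Every run records the ground truth so that
downstream scans can be scored against it.

Scale defaults mirror the Landrace arm of the study design this package
targets: 92 half-sib families of 7-24 offspring, 18 autosomes, ~52 k SNPs,
a trait with heritability 0.5 whose QTL each explain a few percent of the
genetic variance, and a 0.05 ppm assay detection limit (androstenone).
Tests use scaled-down configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genmap import MAP_COLUMNS
from .io import (
    GenotypeMatrix,
    HaplotypeSet,
    MISSING,
    ensure_dir,
    write_marker_map,
    write_pedigree,
    write_phased_haplotypes,
    write_phenotypes,
    write_plink,
)
from .relationship import UNKNOWN


@dataclass(frozen=True)
class QTLSpec:
    """A simulated QTL: placed at the marker nearest ``pos_cM`` on
    ``chrom``, explaining ``frac_genetic`` of the genetic variance."""

    chrom: int
    pos_cM: float
    frac_genetic: float


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study (one trait per run)."""

    n_sires: int = 92
    offspring_low: int = 7
    offspring_high: int = 24
    n_chrom: int = 18
    snps_per_chrom: int = 2886
    chrom_length_cM: float = 100.0
    founder_pool_size: int = 64
    founder_mutation_rate: float = 0.02
    founder_block_cM: float = 5.0  # ancestral-block length in the pool
    founder_block_variants: int = 4  # distinct variants per block
    qtl_specs: tuple[QTLSpec, ...] = (QTLSpec(1, 50.0, 0.06),)
    mu: float = 0.0  # log-ppm intercept
    sigma2_poly: float = 0.5  # polygenic variance, log-ppm^2
    sigma2_e: float = 0.5  # residual variance, log-ppm^2
    n_stations: int = 3
    station_effects: tuple[float, ...] = (0.0, 0.1, -0.1)
    beta_age: float = 0.01  # per day at entering test
    beta_days: float = 0.005  # per day in test
    beta_litter: float = -0.02  # per litter mate born alive
    detection_limit: float = 0.05  # ppm (androstenone assay floor)
    trait: str = "androstenone"
    missing_rate: float = 0.005
    genotype_error_rate: float = 0.0005
    seed: int = 0

    def __post_init__(self):
        if min(self.n_sires, self.offspring_low, self.n_chrom, self.snps_per_chrom) < 1:
            raise ValueError("counts must be positive")
        if self.offspring_low > self.offspring_high:
            raise ValueError("offspring_low must be <= offspring_high")
        if self.sigma2_poly < 0 or self.sigma2_e < 0:
            raise ValueError("variances must be non-negative")
        fracs = [q.frac_genetic for q in self.qtl_specs]
        if any(f < 0 or f >= 1 for f in fracs) or sum(fracs) >= 1:
            raise ValueError("QTL variance fractions must lie in [0,1) and sum < 1")
        if not 0 <= self.missing_rate < 1 or not 0 <= self.genotype_error_rate < 1:
            raise ValueError("rates must be in [0, 1)")
        if len(self.station_effects) != self.n_stations:
            raise ValueError("need one station effect per station")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimTruth:
    """Ground truth retained for scoring; never consumed by the analysis."""

    polygenic: pd.Series  # per individual breeding value u
    qtl_markers: list[str]  # marker snp_id hosting each QTL
    qtl_positions: list[tuple[int, float]]  # (chrom, cM)
    qtl_effects: list[float]  # allele substitution effect per copy
    qtl_dosages: pd.DataFrame  # individuals x QTLs
    log_values: pd.Series  # uncensored log-scale trait per phenotyped id


@dataclass
class SimResult:
    config: SimConfig
    pedigree: pd.DataFrame
    marker_map: pd.DataFrame
    haplotypes: HaplotypeSet  # truth-phased, all individuals
    genotypes: GenotypeMatrix  # degraded unphased matrix
    phenotypes: pd.DataFrame
    truth: SimTruth

    @property
    def offspring_ids(self) -> list[str]:
        ped = self.pedigree
        return list(ped.loc[ped["sire"] != UNKNOWN, "id"])


# ------------------------------------------------------------- pedigree


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One generation of paternal half-sib families.

    Each sire is mated to as many distinct unrelated dams as it has
    offspring (uniform in [offspring_low, offspring_high]), one offspring
    per dam. Parents precede offspring in record order.
    """
    sizes = rng.integers(cfg.offspring_low, cfg.offspring_high + 1, cfg.n_sires)
    sires = [f"S{i + 1}" for i in range(cfg.n_sires)]
    n_off = int(sizes.sum())
    dams = [f"D{i + 1}" for i in range(n_off)]
    rows = [(s, UNKNOWN, UNKNOWN) for s in sires]
    rows += [(d, UNKNOWN, UNKNOWN) for d in dams]
    k = 0
    for s, sz in zip(sires, sizes):
        for _ in range(sz):
            rows.append((f"O{k + 1}", s, dams[k]))
            k += 1
    return pd.DataFrame(rows, columns=["id", "sire", "dam"])


def simulate_marker_map(cfg: SimConfig) -> pd.DataFrame:
    """Evenly spaced markers, 1 cM/Mb, per autosome."""
    rows = []
    m = cfg.snps_per_chrom
    for c in range(1, cfg.n_chrom + 1):
        cm = np.linspace(0.0, cfg.chrom_length_cM, m) if m > 1 else np.array([0.0])
        for j in range(m):
            rows.append((f"snp{c}_{j + 1}", c, int(round(cm[j] * 1e6)) + 1, cm[j]))
    return pd.DataFrame(rows, columns=MAP_COLUMNS)


# ------------------------------------------------------------- haplotypes


def simulate_founder_haplotypes(
    cfg: SimConfig, marker_map: pd.DataFrame, founder_ids, rng: np.random.Generator
) -> HaplotypeSet:
    """Founder haplotypes sampled from a finite template pool.

    A pool of ``founder_pool_size`` template haplotypes is built per
    chromosome as mosaics of ancestral block variants: the chromosome is
    cut into blocks of ``founder_block_cM``; each block has
    ``founder_block_variants`` variant sequences (per-site allele
    frequency uniform in [0.2, 0.8]) and every template copies one
    variant per block. Templates therefore share long local stretches —
    linkage disequilibrium that decays with map distance — while sites
    monomorphic across the pool are repaired by flipping one template so
    allele frequencies stay bounded away from 0/1 where possible. Each
    founder haplotype copies a random template with per-site mutation;
    a smaller pool gives stronger LD.
    """
    if cfg.founder_pool_size < 2:
        raise ValueError("founder_pool_size must be >= 2")
    if cfg.founder_block_variants < 2:
        raise ValueError("founder_block_variants must be >= 2")
    founder_ids = [str(i) for i in founder_ids]
    n = len(founder_ids)
    m = len(marker_map)
    chroms = marker_map["chrom"].to_numpy()
    cm_all = marker_map["cM"].to_numpy()
    alleles = np.zeros((n, 2, m), dtype=np.int8)
    for c in np.unique(chroms):
        cols = np.where(chroms == c)[0]
        mc = len(cols)
        cm = cm_all[cols] - cm_all[cols].min()
        block = np.floor(cm / max(cfg.founder_block_cM, 1e-9)).astype(int)
        freq = rng.uniform(0.2, 0.8, mc)
        variants = (
            rng.random((cfg.founder_block_variants, mc)) < freq
        ).astype(np.int8)
        n_blocks = int(block.max()) + 1
        choice = rng.integers(
            0, cfg.founder_block_variants, (cfg.founder_pool_size, n_blocks)
        )
        pool = variants[choice[:, block], np.arange(mc)]
        mono = np.nonzero(pool.min(axis=0) == pool.max(axis=0))[0]
        if len(mono):
            flip_rows = rng.integers(0, cfg.founder_pool_size, len(mono))
            pool[flip_rows, mono] ^= 1
        picks = rng.integers(0, cfg.founder_pool_size, (n, 2))
        hap = pool[picks]  # (n, 2, mc)
        if cfg.founder_mutation_rate > 0:
            flips = rng.random((n, 2, mc)) < cfg.founder_mutation_rate
            hap = hap ^ flips.astype(np.int8)
        alleles[:, :, cols] = hap
    return HaplotypeSet(founder_ids, marker_map, alleles)


def _gamete(hap_pair: np.ndarray, cm: np.ndarray, length: float, rng) -> np.ndarray:
    """Recombinant gamete from a phased pair over one chromosome.

    Crossovers follow a no-interference Poisson process on the cM scale
    (Haldane model): count ~ Poisson(length/100), positions uniform.
    """
    n_x = rng.poisson(length / 100.0)
    start = rng.integers(0, 2)
    if n_x == 0:
        return hap_pair[start]
    cuts = np.sort(rng.uniform(0.0, length, n_x))
    phase = (start + np.searchsorted(cuts, cm, side="right")) % 2
    return hap_pair[phase, np.arange(hap_pair.shape[1])]


def gene_drop(
    ped: pd.DataFrame,
    founders: HaplotypeSet,
    marker_map: pd.DataFrame,
    rng: np.random.Generator,
) -> HaplotypeSet:
    """Drop founder haplotypes through the pedigree.

    Every non-founder inherits one recombinant gamete from each parent;
    phase is recorded (haplotype 0 = paternal). Individuals with exactly
    one known parent are rejected.
    """
    ped = ped.astype(str)
    chroms = marker_map["chrom"].to_numpy()
    cm_all = marker_map["cM"].to_numpy()
    chrom_cols = {c: np.where(chroms == c)[0] for c in np.unique(chroms)}
    chrom_len = {c: float(cm_all[cols].max() - cm_all[cols].min()) for c, cols in chrom_cols.items()}

    ids = list(ped["id"])
    idx = {i: k for k, i in enumerate(ids)}
    founder_idx = {s: k for k, s in enumerate(founders.samples)}
    alleles = np.zeros((len(ids), 2, len(marker_map)), dtype=np.int8)

    for r in ped.itertuples():
        i = idx[r.id]
        if (r.sire == UNKNOWN) != (r.dam == UNKNOWN):
            raise ValueError(
                f"individual {r.id} has exactly one known parent; unsupported"
            )
        if r.sire == UNKNOWN:
            if r.id not in founder_idx:
                raise ValueError(f"founder {r.id} has no haplotypes")
            alleles[i] = founders.alleles[founder_idx[r.id]]
            continue
        for h, parent in enumerate((r.sire, r.dam)):
            p = idx.get(parent)
            if p is None:
                raise ValueError(f"parent {parent} precedes no record")
            for c, cols in chrom_cols.items():
                cm = cm_all[cols] - cm_all[cols].min()
                alleles[i, h, cols] = _gamete(
                    alleles[p][:, cols], cm, chrom_len[c], rng
                )
    return HaplotypeSet(ids, marker_map, alleles)


# ------------------------------------------------------------- phenotypes


def simulate_phenotypes(
    ped: pd.DataFrame,
    haps: HaplotypeSet,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, SimTruth]:
    """Censored log-normal trait for the offspring generation.

    log value = mu + station + beta.(age, days, litter) + sum_k a_k dosage_k
    + u + e, with founder u ~ N(0, sigma2_poly) and offspring
    u = (u_sire + u_dam)/2 + N(0, sigma2_poly/2). Each QTL's allele
    substitution effect a_k is back-solved so the QTL explains its
    configured fraction of the genetic (QTL + polygenic) variance given
    the realized dosage variance. ppm = exp(log value), recorded as 0
    below the detection limit.
    """
    ped = ped.astype(str)
    ids = list(ped["id"])
    hap_idx = {s: k for k, s in enumerate(haps.samples)}
    idx = {i: k for k, i in enumerate(ids)}

    u = np.zeros(len(ids))
    for r in ped.itertuples():
        i = idx[r.id]
        if r.sire == UNKNOWN and r.dam == UNKNOWN:
            u[i] = rng.normal(0.0, np.sqrt(cfg.sigma2_poly)) if cfg.sigma2_poly else 0.0
        else:
            mend = rng.normal(0.0, np.sqrt(cfg.sigma2_poly / 2)) if cfg.sigma2_poly else 0.0
            u[i] = 0.5 * (u[idx[r.sire]] + u[idx[r.dam]]) + mend

    offspring = [r.id for r in ped.itertuples() if r.sire != UNKNOWN]
    off_rows = np.array([hap_idx[i] for i in offspring])

    # locate each QTL at the nearest marker and back-solve its effect
    mm = haps.marker_map
    total_frac = sum(q.frac_genetic for q in cfg.qtl_specs)
    qtl_markers, qtl_effects, qtl_dos = [], [], []
    for q in cfg.qtl_specs:
        on_chrom = mm.index[mm["chrom"] == q.chrom]
        if len(on_chrom) == 0:
            raise ValueError(f"QTL chromosome {q.chrom} absent from map")
        j = on_chrom[np.argmin(np.abs(mm.loc[on_chrom, "cM"].to_numpy() - q.pos_cM))]
        dos = haps.alleles[off_rows, :, j].sum(axis=1).astype(float)
        v_d = dos.var()
        if v_d == 0:
            raise ValueError(
                f"QTL locus {mm.at[j, 'snp_id']} is monomorphic in this simulation"
            )
        # v_k = f_k * G with G = sigma2_poly / (1 - sum f)
        v_k = q.frac_genetic * cfg.sigma2_poly / (1.0 - total_frac)
        a = np.sqrt(v_k / v_d)
        qtl_markers.append(str(mm.at[j, "snp_id"]))
        qtl_effects.append(float(a))
        qtl_dos.append(dos)

    n_off = len(offspring)
    fam_of = {r.id: r.sire for r in ped.itertuples() if r.sire != UNKNOWN}
    sires = list(dict.fromkeys(fam_of.values()))
    sire_station = dict(zip(sires, rng.integers(0, cfg.n_stations, len(sires))))
    stations = np.array([sire_station[fam_of[i]] for i in offspring])
    age = np.round(rng.normal(70.0, 5.0, n_off)).astype(int)
    days = np.round(rng.normal(90.0, 10.0, n_off)).astype(int)
    litter = rng.poisson(11.0, n_off)

    y = (
        cfg.mu
        + np.array([cfg.station_effects[s] for s in stations])
        + cfg.beta_age * age
        + cfg.beta_days * days
        + cfg.beta_litter * litter
        + u[[idx[i] for i in offspring]]
        + (rng.normal(0.0, np.sqrt(cfg.sigma2_e), n_off) if cfg.sigma2_e else 0.0)
    )
    for a, dos in zip(qtl_effects, qtl_dos):
        y = y + a * dos

    ppm = np.exp(y)
    ppm = np.where(ppm < cfg.detection_limit, 0.0, ppm)

    phen = pd.DataFrame(
        {
            "id": offspring,
            "trait_ppm": ppm,
            "station": [f"st{s + 1}" for s in stations],
            "age_entry": age,
            "days_test": days,
            "litter_alive": litter,
        }
    )
    truth = SimTruth(
        polygenic=pd.Series(u, index=ids),
        qtl_markers=qtl_markers,
        qtl_positions=[(q.chrom, q.pos_cM) for q in cfg.qtl_specs],
        qtl_effects=qtl_effects,
        qtl_dosages=pd.DataFrame(
            {f"qtl{k + 1}": d for k, d in enumerate(qtl_dos)}, index=offspring
        ),
        log_values=pd.Series(y, index=offspring),
    )
    return phen, truth


# ------------------------------------------------------------- degradation


def degrade_genotypes(
    haps: HaplotypeSet,
    missing_rate: float,
    genotype_error_rate: float,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Unphased 0/1/2 matrix with missingness and random genotype errors.

    Errors replace the true genotype by one of the two other genotype
    classes uniformly; truth-phased haplotypes are kept separately.
    """
    if not 0 <= missing_rate < 1 or not 0 <= genotype_error_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    g = haps.dosages()
    vals = g.values.astype(np.int8).copy()
    shape = vals.shape
    if genotype_error_rate > 0:
        err = rng.random(shape) < genotype_error_rate
        shift = rng.integers(1, 3, shape)  # +1 or +2 mod 3 => a different class
        vals = np.where(err, (vals + shift) % 3, vals).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random(shape) < missing_rate
        vals = np.where(miss, MISSING, vals).astype(np.int8)
    return GenotypeMatrix(g.samples, g.snp_ids, vals, g.counted_allele)


# ------------------------------------------------------------- orchestration


def simulate_study(cfg: SimConfig) -> SimResult:
    """Run the full generator with the config's seed (deterministic)."""
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    marker_map = simulate_marker_map(cfg)
    founder_ids = list(ped.loc[ped["sire"] == UNKNOWN, "id"])
    founders = simulate_founder_haplotypes(cfg, marker_map, founder_ids, rng)
    haps = gene_drop(ped, founders, marker_map, rng)
    phen, truth = simulate_phenotypes(ped, haps, cfg, rng)
    geno = degrade_genotypes(haps, cfg.missing_rate, cfg.genotype_error_rate, rng)
    return SimResult(cfg, ped, marker_map, haps, geno, phen, truth)


def write_study(res: SimResult, outdir) -> Path:
    """Write a simulated study to disk (PLINK + TSV tables + truth)."""
    out = ensure_dir(outdir)
    write_pedigree(res.pedigree, out / "pedigree.tsv")
    write_marker_map(res.marker_map, out / "markers.tsv")
    write_plink(res.genotypes, res.marker_map, out / "study.ped", out / "study.map")
    write_phased_haplotypes(res.haplotypes, out / "haplotypes.tsv")
    write_phenotypes(res.phenotypes, out / "phenotypes.tsv")
    truth = pd.DataFrame(
        {
            "id": res.truth.polygenic.index,
            "polygenic": res.truth.polygenic.to_numpy(),
        }
    )
    truth.to_csv(out / "truth_polygenic.tsv", sep="\t", index=False)
    qt = res.truth.qtl_dosages.copy()
    qt.insert(0, "id", qt.index)
    qt.to_csv(out / "truth_qtl_dosages.tsv", sep="\t", index=False)
    meta = pd.DataFrame(
        {
            "qtl_marker": res.truth.qtl_markers,
            "chrom": [c for c, _ in res.truth.qtl_positions],
            "pos_cM": [p for _, p in res.truth.qtl_positions],
            "effect": res.truth.qtl_effects,
        }
    )
    meta.to_csv(out / "truth_qtl.tsv", sep="\t", index=False)
    return out
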
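"""Sample- and SNP-level genotype quality control.

Thresholds are strict as printed in the study protocol this pipeline
reproduces: samples kept if call rate > 0.75; SNPs kept if MAF > 0.01,
call frequency > 0.10 and parent-child Mendelian error rate < 0.025;
finally SNPs that are non-informative (monomorphic among the retained
samples) are removed. Samples are filtered first so that the SNP
statistics reflect the analyzed cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix
from .relationship import UNKNOWN


@dataclass(frozen=True)
class QCThresholds:
    maf_min: float = 0.01  # keep if MAF strictly greater
    call_freq_min: float = 0.10  # keep if call frequency strictly greater
    mendel_max: float = 0.025  # keep if Mendelian error rate strictly lower
    sample_call_min: float = 0.75  # keep if sample call rate strictly greater

    def __post_init__(self):
        for v in (self.maf_min, self.call_freq_min, self.mendel_max, self.sample_call_min):
            if not 0 <= v <= 1:
                raise ValueError("QC thresholds must lie in [0, 1]")


@dataclass
class QCReport:
    sample_table: pd.DataFrame  # id, call_rate, kept
    snp_table: pd.DataFrame  # snp_id, maf, call_freq, mendel_rate, kept, reason
    removed_counts: dict = field(default_factory=dict)


def sample_call_rate(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per sample."""
    if g.n_snps == 0:
        raise ValueError("no SNPs")
    return (g.values != MISSING).mean(axis=1)


def snp_call_freq(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per SNP."""
    return (g.values != MISSING).mean(axis=0)


def snp_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per SNP over non-missing calls.

    Invariant to which allele is counted; monomorphic or fully missing
    columns get MAF 0.
    """
    called = g.values != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq1 = np.where(
            n_called > 0,
            np.where(called, g.values, 0).sum(axis=0) / (2.0 * n_called),
            0.0,
        )
    return np.minimum(freq1, 1.0 - freq1)


def _parent_child_pairs(g: GenotypeMatrix, ped: pd.DataFrame) -> np.ndarray:
    idx = {s: k for k, s in enumerate(g.samples)}
    pairs = []
    for r in ped.astype(str).itertuples():
        child = idx.get(r.id)
        if child is None:
            continue
        for parent in (r.sire, r.dam):
            if parent != UNKNOWN and parent in idx:
                pairs.append((idx[parent], child))
    return np.array(pairs, dtype=int).reshape(-1, 2)


def mendel_rate(g: GenotypeMatrix, ped: pd.DataFrame) -> np.ndarray:
    """Per-SNP rate of opposite-homozygote parent-child conflicts.

    Denominator: genotyped pairs at that SNP (missing calls excluded).
    A SNP with no genotyped pair has an undefined rate, reported as 0 so
    it passes the Mendelian rule.
    """
    pairs = _parent_child_pairs(g, ped)
    if len(pairs) == 0:
        return np.zeros(g.n_snps)
    gp = g.values[pairs[:, 0], :]
    gc = g.values[pairs[:, 1], :]
    ok = (gp != MISSING) & (gc != MISSING)
    conflict = ((gp == 0) & (gc == 2)) | ((gp == 2) & (gc == 0))
    denom = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(denom > 0, (conflict & ok).sum(axis=0) / denom, 0.0)
    return rate


def noninformative_mask(g: GenotypeMatrix) -> np.ndarray:
    """SNPs with only one allele observed among the retained samples.

    'Non-informative' is not precisely defined in the source protocol;
    monomorphic-within-cohort is implemented here (see docs/methods.md).
    A column of heterozygotes carries both alleles and is informative;
    a column that is entirely one homozygote (or entirely missing) is not.
    """
    called = g.values != MISSING
    any_called = called.any(axis=0)
    has_allele1 = (called & (g.values > 0)).any(axis=0)
    has_allele0 = (called & (g.values < 2)).any(axis=0)
    return ~(has_allele0 & has_allele1 & any_called)


def run_qc(
    g: GenotypeMatrix,
    ped: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the full filter pipeline; returns filtered matrix + report.

    Order: sample call rate, then SNP MAF / call frequency / Mendelian
    rate (each removal attributed to its first failing rule in that
    order), then non-informative removal. Idempotent on its own output.
    """
    t = thresholds
    cr = sample_call_rate(g)
    keep_sample = cr > t.sample_call_min
    sample_table = pd.DataFrame(
        {"id": g.samples, "call_rate": cr, "kept": keep_sample}
    )
    g1 = g.subset(sample_mask=keep_sample)

    maf = snp_maf(g1)
    cf = snp_call_freq(g1)
    mr = mendel_rate(g1, ped)
    keep_snp = (maf > t.maf_min) & (cf > t.call_freq_min) & (mr < t.mendel_max)
    reason = np.full(g1.n_snps, "", dtype=object)
    reason[mr >= t.mendel_max] = "mendel"
    reason[cf <= t.call_freq_min] = "call_freq"
    reason[maf <= t.maf_min] = "maf"

    g2 = g1.subset(snp_mask=keep_snp)
    noninf = noninformative_mask(g2)
    # map non-informative verdicts back onto the full SNP table
    kept_idx = np.where(keep_snp)[0]
    reason[kept_idx[noninf]] = "noninformative"
    keep_final = keep_snp.copy()
    keep_final[kept_idx[noninf]] = False

    snp_table = pd.DataFrame(
        {
            "snp_id": g1.snp_ids,
            "maf": maf,
            "call_freq": cf,
            "mendel_rate": mr,
            "kept": keep_final,
            "reason": reason,
        }
    )
    g3 = g2.subset(snp_mask=~noninf)
    report = QCReport(
        sample_table=sample_table,
        snp_table=snp_table,
        removed_counts={
            "samples_call_rate": int((~keep_sample).sum()),
            "snps_maf": int((reason == "maf").sum()),
            "snps_call_freq": int((reason == "call_freq").sum()),
            "snps_mendel": int((reason == "mendel").sum()),
            "snps_noninformative": int((reason == "noninformative").sum()),
        },
    )
    return g3, report
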
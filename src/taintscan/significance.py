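"""Chromosome-wise and genome-wide significance, QTL region calling and
cross-breed confirmation.

Chromosome-wise p-values (CWS) use the quick upper bound for the tail of
the supremum of a 1-df chi-square scan process (Davies' bound, as
popularised for QTL scans by Piepho):

    cws_p = Pr(chi2_1 > c) + V * exp(-c/2) / sqrt(2*pi),

with c = 2 * LnLikratio at the evaluated position and V the total
variation of sqrt(2 * LnLikratio) along the chromosome. Genome-wide
p-values multiply CWS by 18, the number of porcine autosomes analyzed.
A position (SNP/QTL) is significant if p < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

N_AUTOSOMES_MULTIPLIER = 18
CWS_ALPHA = 0.05
#: LnLikratio drop defining region extent: 2*drop = chi2_1 95% cutoff.
PEAK_DROP = 1.92
MERGE_BP = 1_000_000

REGION_COLUMNS = [
    "chrom",
    "start_bp",
    "end_bp",
    "peak_bp",
    "peak_snp",
    "peak_lnlikratio",
    "cws_p",
    "gws_p",
    "sig_class",
    "var_explained_pct",
]


def sqrt_total_variation(lnlikratios: np.ndarray) -> float:
    """V = sum |sqrt(2 LR_i) - sqrt(2 LR_{i-1})| along the chromosome."""
    s = np.sqrt(2.0 * np.clip(np.asarray(lnlikratios, float), 0.0, None))
    return float(np.abs(np.diff(s)).sum())


def piepho_cws(lnlikratios) -> float:
    """Chromosome-wise p-value of the chromosome's peak statistic."""
    lr = np.asarray(lnlikratios, dtype=float)
    lr = lr[np.isfinite(lr)]
    if len(lr) < 2:
        raise ValueError("need >= 2 finite statistics on the chromosome")
    c = 2.0 * lr.max()
    V = sqrt_total_variation(lr)
    p = chi2.sf(c, df=1) + V * np.exp(-c / 2.0) / np.sqrt(2.0 * np.pi)
    return float(min(p, 1.0))


def gws_from_cws(cws_p: float) -> float:
    """Genome-wide p: CWS multiplied by the 18 autosomes, capped at 1."""
    return float(min(1.0, N_AUTOSOMES_MULTIPLIER * cws_p))


def adjust_profile(profile: pd.DataFrame) -> pd.DataFrame:
    """Fill per-position cws_p and gws_p columns of a scan profile.

    Each position's statistic is referred to the same scan-maximum bound
    (sharing the chromosome's total variation V), so the chromosome peak
    gets exactly :func:`piepho_cws` and every cws_p is >= the pointwise
    p-value. Non-converged positions are excluded from V and left NaN.
    """
    prof = profile.copy()
    prof["cws_p"] = np.nan
    prof["gws_p"] = np.nan
    for chrom, grp in prof.groupby("chrom"):
        ok = grp["converged"] & np.isfinite(grp["lnlikratio"])
        lr = grp.loc[ok, "lnlikratio"].to_numpy(float)
        if len(lr) < 2:
            continue
        V = sqrt_total_variation(lr)
        c = 2.0 * lr
        p = np.minimum(chi2.sf(c, df=1) + V * np.exp(-c / 2.0) / np.sqrt(2 * np.pi), 1.0)
        prof.loc[grp.index[ok], "cws_p"] = p
        prof.loc[grp.index[ok], "gws_p"] = np.minimum(1.0, N_AUTOSOMES_MULTIPLIER * p)
    return prof


def _local_peaks(lr: np.ndarray) -> list[int]:
    """Indices of strict-or-plateau local maxima (first index of ties)."""
    n = len(lr)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and lr[j + 1] == lr[i]:
            j += 1
        left_ok = i == 0 or lr[i - 1] < lr[i]
        right_ok = j == n - 1 or lr[j + 1] < lr[i]
        if left_ok and right_ok:
            peaks.append(i)
        i = j + 1
    return peaks


def call_regions(
    adjusted_profile: pd.DataFrame,
    cws_alpha: float = CWS_ALPHA,
    peak_drop: float = PEAK_DROP,
    merge_bp: int = MERGE_BP,
) -> pd.DataFrame:
    """Call QTL regions from an adjusted scan profile.

    A region is seeded at each local peak with cws_p < ``cws_alpha``;
    its extent is the contiguous run of positions with
    LnLikratio >= peak - ``peak_drop`` (a 2*drop <= chi2_1(0.95)
    support interval); regions closer than ``merge_bp`` on the same
    chromosome are merged, keeping the higher peak. Class is GWS when
    the peak's gws_p < 0.05, else CWS.
    """
    regions = []
    for chrom, grp in adjusted_profile.groupby("chrom"):
        grp = grp.sort_values("bp").reset_index(drop=True)
        usable = grp["converged"].to_numpy() & np.isfinite(
            grp["lnlikratio"].to_numpy(float)
        )
        lr = np.where(usable, grp["lnlikratio"].to_numpy(float), -np.inf)
        cws = grp["cws_p"].to_numpy(float)
        found = []
        for pk in _local_peaks(lr):
            if not usable[pk] or not (cws[pk] < cws_alpha):
                continue
            lo = pk
            while lo > 0 and lr[lo - 1] >= lr[pk] - peak_drop:
                lo -= 1
            hi = pk
            while hi + 1 < len(lr) and lr[hi + 1] >= lr[pk] - peak_drop:
                hi += 1
            found.append([lo, hi, pk])
        found.sort(key=lambda t: grp.at[t[0], "bp"])
        merged: list[list[int]] = []
        for lo, hi, pk in found:
            if merged and grp.at[lo, "bp"] - grp.at[merged[-1][1], "bp"] < merge_bp:
                prev = merged[-1]
                prev[1] = max(prev[1], hi)
                if lr[pk] > lr[prev[2]]:
                    prev[2] = pk
            else:
                merged.append([lo, hi, pk])
        for lo, hi, pk in merged:
            s2t = grp.at[pk, "sigma2_term"] if "sigma2_term" in grp else 0.0
            s2a = grp.at[pk, "sigma2_poly"] if "sigma2_poly" in grp else 0.0
            denom = s2t + s2a
            regions.append(
                (
                    int(chrom),
                    int(grp.at[lo, "bp"]),
                    int(grp.at[hi, "bp"]),
                    int(grp.at[pk, "bp"]),
                    grp.at[pk, "snp_id"],
                    float(lr[pk]),
                    float(cws[pk]),
                    float(grp.at[pk, "gws_p"]),
                    "GWS" if grp.at[pk, "gws_p"] < 0.05 else "CWS",
                    0.0 if denom == 0 else 100.0 * s2t / denom,
                )
            )
    return pd.DataFrame(regions, columns=REGION_COLUMNS)


def compare_breeds(regions_a: pd.DataFrame, regions_b: pd.DataFrame) -> pd.DataFrame:
    """Cross-breed QTL concordance.

    Regions are paired when their bp intervals overlap on the same
    chromosome. A pair is 'confirmed' iff one member is GWS and the
    other at least CWS (both lists already contain only p < 0.05
    regions, so any overlap with a GWS member confirms). Unpaired or
    never-confirmed regions are breed-specific.
    """
    rows = []
    confirmed_a, confirmed_b = set(), set()
    for ia, ra in regions_a.iterrows():
        for ib, rb in regions_b.iterrows():
            if ra["chrom"] != rb["chrom"]:
                continue
            if ra["start_bp"] > rb["end_bp"] or rb["start_bp"] > ra["end_bp"]:
                continue
            conf = "GWS" in (ra["sig_class"], rb["sig_class"])
            rows.append(
                (
                    int(ra["chrom"]),
                    int(ra["start_bp"]),
                    int(ra["end_bp"]),
                    int(rb["start_bp"]),
                    int(rb["end_bp"]),
                    ra["sig_class"],
                    rb["sig_class"],
                    "confirmed" if conf else "overlap_cws_only",
                )
            )
            if conf:
                confirmed_a.add(ia)
                confirmed_b.add(ib)
    for label, regions, confirmed in (
        ("A", regions_a, confirmed_a),
        ("B", regions_b, confirmed_b),
    ):
        for i, r in regions.iterrows():
            if i not in confirmed:
                rows.append(
                    (
                        int(r["chrom"]),
                        int(r["start_bp"]) if label == "A" else -1,
                        int(r["end_bp"]) if label == "A" else -1,
                        int(r["start_bp"]) if label == "B" else -1,
                        int(r["end_bp"]) if label == "B" else -1,
                        r["sig_class"] if label == "A" else "",
                        r["sig_class"] if label == "B" else "",
                        f"specific_{label}",
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start_bp_a",
            "end_bp_a",
            "start_bp_b",
            "end_bp_b",
            "class_a",
            "class_b",
            "status",
        ],
    )
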
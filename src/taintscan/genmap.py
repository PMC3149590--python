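"""Haldane map-function conversions and marker-map validation.

The Haldane mapping function assumes crossovers occur as a no-interference
Poisson process along the chromosome, so a recombination fraction ``r``
between two loci corresponds to a map distance ``d = -50 ln(1 - 2r)`` cM.
The inverse converts map distance back to recombination fraction; both are
used by the gene-drop simulator and by map sanity checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Number of porcine autosomes handled by the pipeline (SSC1-SSC18).
N_AUTOSOMES = 18

MAP_COLUMNS = ["snp_id", "chrom", "bp", "cM"]


def haldane_cM(r):
    """Convert recombination fraction ``r`` to Haldane map distance in cM.

    ``d = -50 ln(1 - 2r)``. Accepts scalars or arrays; ``r`` must lie in
    ``[0, 0.5)`` — loci with r >= 0.5 are unlinked and have no finite
    map distance.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    out = -50.0 * np.log1p(-2.0 * r)
    return float(out) if out.ndim == 0 else out


def inverse_haldane(d):
    """Convert map distance ``d`` (cM) to recombination fraction.

    ``r = (1 - exp(-2 d / 100)) / 2``; approaches 0.5 as ``d`` grows.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    out = 0.5 * -np.expm1(-2.0 * d / 100.0)
    return float(out) if out.ndim == 0 else out


def validate_map(marker_map: pd.DataFrame) -> pd.DataFrame:
    """Validate a marker map and summarise it per chromosome.

    Checks the schema (snp_id, chrom, bp, cM), uniqueness of snp_ids,
    chromosome numbers in 1..18, sortedness by (chrom, bp) and
    non-decreasing cM within chromosome. Returns a per-chromosome summary
    DataFrame (n_snps, bp span, cM length).
    """
    missing = [c for c in MAP_COLUMNS if c not in marker_map.columns]
    if missing:
        raise ValueError(f"marker map missing columns: {missing}")
    if marker_map["snp_id"].duplicated().any():
        dup = marker_map.loc[marker_map["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id: {dup}")
    chroms = marker_map["chrom"].to_numpy()
    if np.any(chroms < 1) or np.any(chroms > N_AUTOSOMES):
        bad = chroms[(chroms < 1) | (chroms > N_AUTOSOMES)][0]
        raise ValueError(f"chromosome {bad} outside autosomes 1..{N_AUTOSOMES}")
    key = marker_map[["chrom", "bp"]].to_numpy()
    if not (np.lexsort((key[:, 1], key[:, 0])) == np.arange(len(key))).all():
        raise ValueError("marker map not sorted by (chrom, bp)")
    for chrom, grp in marker_map.groupby("chrom", sort=True):
        cm = grp["cM"].to_numpy()
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"cM positions decrease on chromosome {chrom}")
        if grp["bp"].duplicated().any():
            raise ValueError(f"duplicate bp position on chromosome {chrom}")
    summary = (
        marker_map.groupby("chrom")
        .agg(
            n_snps=("snp_id", "size"),
            bp_start=("bp", "min"),
            bp_end=("bp", "max"),
            cM_length=("cM", lambda x: float(x.max() - x.min())),
        )
        .reset_index()
    )
    return summary
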
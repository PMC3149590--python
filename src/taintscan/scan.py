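"""Genome scans: per-SNP mixed-model GWAS and per-position LDLA.

Both scans fit the same mixed model (see :mod:`taintscan.varcomp`) and
report, per tested position, the REML log-likelihood ratio against the
shared polygenic null (fitted once per trait and reused).

* GWAS: the marker term is the 0/1/2 dosage of the '1' allele, a single
  random regression column; missing dosages are imputed to the SNP mean.
* LDLA: phased haplotypes are grouped at each focal position by a binary
  identity rule — two haplotypes are "completely correlated" iff the run
  of matching alleles scanning left from the focal marker plus the run
  scanning right from the next marker, each stopped at the first
  mismatch (or chromosome end), totals >= 10 markers; otherwise they are
  uncorrelated. A greedy reference-haplotype closure turns the pairwise
  relation into a partition (see :func:`cluster_haplotypes_at`), and the
  marker term is the per-individual cluster incidence (each row sums
  to 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, HaplotypeSet, log_transform
from .relationship import RelationshipMatrix
from .varcomp import FitResult, MixedModel, build_design, lnlik_ratio, pointwise_p

IDENTITY_THRESHOLD = 10

PROFILE_COLUMNS = [
    "chrom",
    "snp_id",
    "bp",
    "cM",
    "lnlikratio",
    "sigma2_term",
    "sigma2_poly",
    "p_pointwise",
    "converged",
]


@dataclass
class HaplotypeClusters:
    """Cluster assignment of the haplotypes at one focal marker."""

    focal_index: int
    labels: np.ndarray  # cluster id per haplotype row
    n_clusters: int
    threshold: int = IDENTITY_THRESHOLD


# ------------------------------------------------------------ clustering


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_haplotypes_at(
    haps: np.ndarray,
    focal: int,
    threshold: int = IDENTITY_THRESHOLD,
    closure: str = "reference",
) -> HaplotypeClusters:
    """Cluster haplotype rows at a focal marker by the identity rule.

    ``haps`` is an (n_haplotypes, n_markers) 0/1 array for one
    chromosome. Two rows are "completely correlated" iff left-run
    (including the focal marker) + right-run (from the next marker) of
    agreeing alleles >= ``threshold``; runs stop at the first mismatch
    or chromosome end.

    The pairwise relation is not transitive, so a closure turns it into
    a partition:

    * ``"reference"`` (default): greedy reference-haplotype assignment —
      the first unassigned row founds a cluster and collects every
      remaining row identical to it. Every member is then identical to
      its reference, honouring the completely-correlated semantics, and
      a rare spurious 10-marker agreement misplaces one haplotype at
      worst.
    * ``"single"``: connected components of the identity graph. The most
      permissive closure, but with hundreds of haplotypes the ~1e-3
      per-pair rate of chance 10-marker agreements chains unrelated
      clusters together and collapses the partition.

    A pair satisfies the rule iff the two rows agree on some window of
    ``threshold`` consecutive markers starting in
    [focal - threshold + 1, focal + 1]; hashing rows by each such window
    evaluates the relation in O(threshold * n) instead of all-pairs
    scanning.
    """
    haps = np.asarray(haps, dtype=np.int8)
    if haps.ndim != 2:
        raise ValueError("expected a 2-D haplotype array (phased input required)")
    n, m = haps.shape
    if not 0 <= focal < m:
        raise ValueError("focal marker outside chromosome")
    lo = max(0, focal - threshold + 1)
    hi = min(focal + 1, m - threshold)  # inclusive last window start
    starts = list(range(lo, hi + 1))
    if not starts or n == 0:
        labels = np.arange(n)
        return HaplotypeClusters(focal, labels, n, threshold)
    # integer code per (row, window): rows share a window code iff their
    # alleles agree on that whole window
    codes = np.empty((n, len(starts)), dtype=np.int64)
    void = np.dtype((np.void, threshold))
    for k, a in enumerate(starts):
        block = np.ascontiguousarray(haps[:, a : a + threshold]).view(void).ravel()
        _, codes[:, k] = np.unique(block, return_inverse=True)
    if closure == "single":
        uf = _UnionFind(n)
        for k in range(codes.shape[1]):
            order = np.argsort(codes[:, k], kind="stable")
            col = codes[order, k]
            same = np.nonzero(col[1:] == col[:-1])[0]
            for j in same:
                uf.union(int(order[j]), int(order[j + 1]))
        roots = np.array([uf.find(i) for i in range(n)])
        _, labels = np.unique(roots, return_inverse=True)
    elif closure == "reference":
        labels = np.full(n, -1)
        lab = 0
        unassigned = np.ones(n, dtype=bool)
        while True:
            rest = np.nonzero(unassigned)[0]
            if len(rest) == 0:
                break
            r = rest[0]
            members = (codes[rest] == codes[r]).any(axis=1)
            labels[rest[members]] = lab
            unassigned[rest[members]] = False
            lab += 1
    else:
        raise ValueError(f"unknown closure '{closure}'")
    return HaplotypeClusters(focal, labels, int(labels.max()) + 1, threshold)


def cluster_incidence(clusters: HaplotypeClusters, n_individuals: int) -> np.ndarray:
    """Individuals x clusters incidence; haplotype rows are assumed to be
    ordered (ind0 hap0, ind0 hap1, ind1 hap0, ...). Rows sum to 2."""
    labels = clusters.labels.reshape(n_individuals, 2)
    W = np.zeros((n_individuals, clusters.n_clusters))
    rows = np.repeat(np.arange(n_individuals), 2)
    np.add.at(W, (rows, labels.ravel()), 1.0)
    return W


# ------------------------------------------------------------ scans


def prepare_model(
    phen: pd.DataFrame, A: RelationshipMatrix, detection_limit: float
) -> MixedModel:
    """Build the trait's mixed model (transform, design, A submatrix).

    The eigendecomposition of A happens here once; pass the result to
    both scans via their ``model=`` argument to avoid repeating it.
    """
    ids = [str(i) for i in phen["id"]]
    y = log_transform(phen["trait_ppm"].to_numpy(float), detection_limit)
    X = build_design(phen)
    return MixedModel(y, X, A.submatrix(ids).values)


def _prepare(phen, A, detection_limit, model=None):
    ids = [str(i) for i in phen["id"]]
    if model is None:
        model = prepare_model(phen, A, detection_limit)
    return ids, model


def gwas_scan(
    g: GenotypeMatrix,
    phen: pd.DataFrame,
    A: RelationshipMatrix,
    marker_map: pd.DataFrame,
    detection_limit: float,
    model: MixedModel | None = None,
) -> pd.DataFrame:
    """Per-SNP random-dosage-effect scan.

    Returns a profile DataFrame (one row per SNP, sorted as the map)
    with LnLikratio, the SNP variance component, the null's polygenic
    variance and the pointwise chi-square(1) p-value.
    """
    ids, model = _prepare(phen, A, detection_limit, model)
    sample_idx = {s: k for k, s in enumerate(g.samples)}
    rows = [sample_idx[i] for i in ids]
    null = model.fit()
    if not null.converged:
        raise RuntimeError("polygenic null model did not converge")
    ga0 = null.sigma2_poly / null.sigma2_e if null.sigma2_e > 0 else 1.0

    snp_pos = marker_map.set_index("snp_id")
    out = []
    ga_start, gm_start = max(ga0, 1e-6), 0.05
    for j, snp in enumerate(g.snp_ids):
        dos = g.values[rows, j].astype(float)
        miss = dos == MISSING
        if miss.all():
            raise ValueError(f"SNP {snp} has no called genotypes")
        if miss.any():
            dos[miss] = dos[~miss].mean()
        if dos.var() == 0:
            raise ValueError(f"SNP {snp} has zero dosage variance (QC should remove)")
        fit = model.fit(W=dos[:, None], ga_start=ga_start, gm_start=gm_start)
        if fit.converged and fit.sigma2_e > 0:
            ga_start = max(fit.sigma2_poly / fit.sigma2_e, 1e-6)
            gm_start = max(fit.sigma2_term / fit.sigma2_e, 1e-3)
        lr = lnlik_ratio(fit, null) if fit.converged else np.nan
        out.append(
            (
                int(snp_pos.at[snp, "chrom"]),
                snp,
                int(snp_pos.at[snp, "bp"]),
                float(snp_pos.at[snp, "cM"]),
                lr,
                fit.sigma2_term,
                null.sigma2_poly,
                pointwise_p(lr) if fit.converged else np.nan,
                fit.converged,
            )
        )
    prof = pd.DataFrame(out, columns=PROFILE_COLUMNS)
    return prof.sort_values(["chrom", "bp"], ignore_index=True)


def ldla_scan(
    haps: HaplotypeSet,
    phen: pd.DataFrame,
    A: RelationshipMatrix,
    detection_limit: float,
    threshold: int = IDENTITY_THRESHOLD,
    positions: pd.DataFrame | None = None,
    model: MixedModel | None = None,
) -> pd.DataFrame:
    """Per-position haplotype-cluster scan (LDLA).

    Tested positions default to every marker. At a position where all
    haplotypes fall in one cluster there is no contrast: LnLikratio is
    fixed at 0 and the position flagged non-converged/uninformative.
    """
    ids = [str(i) for i in phen["id"]]
    sub = haps.subset_samples(ids)
    _, model = _prepare(phen, A, detection_limit, model)
    null = model.fit()
    if not null.converged:
        raise RuntimeError("polygenic null model did not converge")
    ga0 = null.sigma2_poly / null.sigma2_e if null.sigma2_e > 0 else 1.0

    mm = haps.marker_map
    if positions is None:
        positions = mm
    chroms = mm["chrom"].to_numpy()
    out = []
    ga_start, gm_start = max(ga0, 1e-6), 0.05
    for chrom in np.unique(positions["chrom"]):
        cols = np.where(chroms == chrom)[0]
        H = sub.alleles[:, :, cols].reshape(len(ids) * 2, len(cols))
        col_of = {int(c): k for k, c in enumerate(cols)}
        for r in positions[positions["chrom"] == chrom].itertuples():
            gj = mm.index[mm["snp_id"] == r.snp_id][0]
            focal = col_of[int(gj)]
            clusters = cluster_haplotypes_at(H, focal, threshold)
            if clusters.n_clusters < 2:
                out.append(
                    (int(r.chrom), r.snp_id, int(r.bp), float(r.cM),
                     0.0, 0.0, null.sigma2_poly, 1.0, False)
                )
                continue
            W = cluster_incidence(clusters, len(ids))
            fit = model.fit(W=W, ga_start=ga_start, gm_start=gm_start)
            if fit.converged and fit.sigma2_e > 0:
                ga_start = max(fit.sigma2_poly / fit.sigma2_e, 1e-6)
                gm_start = max(fit.sigma2_term / fit.sigma2_e, 1e-3)
            lr = lnlik_ratio(fit, null) if fit.converged else np.nan
            out.append(
                (
                    int(r.chrom),
                    r.snp_id,
                    int(r.bp),
                    float(r.cM),
                    lr,
                    fit.sigma2_term,
                    null.sigma2_poly,
                    pointwise_p(lr) if fit.converged else np.nan,
                    fit.converged,
                )
            )
    prof = pd.DataFrame(out, columns=PROFILE_COLUMNS)
    return prof.sort_values(["chrom", "bp"], ignore_index=True)


def variance_explained(fit: FitResult) -> float:
    """Marker share of the genetic variance at a fitted position, in %.

    100 * s2_term / (s2_term + s2_poly); 0 when both are zero.
    """
    denom = fit.sigma2_term + fit.sigma2_poly
    return 0.0 if denom == 0 else 100.0 * fit.sigma2_term / denom


def variance_explained_pct(sigma2_term: float, sigma2_poly: float) -> float:
    denom = sigma2_term + sigma2_poly
    return 0.0 if denom == 0 else 100.0 * sigma2_term / denom
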
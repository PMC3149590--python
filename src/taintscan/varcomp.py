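"""REML variance-component estimation and likelihood-ratio machinery.

The mixed model shared by the GWAS and LDLA scans is

    y = X b + u + m + e,    u ~ N(0, A s2_poly),  m ~ N(0, Z Z' s2_term),
                            e ~ N(0, I s2_e),

with y the detection-limit log-transformed trait, X the fixed design
(intercept, test-station, age at entering test, days in test, litter
mates born alive), A the pedigree additive relationship matrix and Z
either the SNP dosage column (GWAS) or the haplotype-cluster incidence
matrix (LDLA). The marker term is a *random* effect; the scan statistic
is the REML log-likelihood difference between the models with and
without it, with 2*LnLikratio referred to a chi-square(1).

REML criterion (constants dropped consistently so they cancel in
ratios):  -1/2 [ log|V| + log|X' V^-1 X| + y' P y ].

Numerics: the relationship matrix is eigendecomposed once; rotating the
model by its eigenvectors makes V diagonal-plus-low-rank, so each
likelihood evaluation is O(n (p + k)^2) via Woodbury. The residual
variance is profiled out analytically and the remaining variance
*ratios* (s2_poly/s2_e, s2_term/s2_e) are maximised on the log scale by
bounded quasi-Newton (L-BFGS-B). The fit is deterministic: fixed starts,
no random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import eigh
from scipy.stats import chi2

LOG_GAMMA_LO = np.log(1e-8)  # ratio this small is an effective zero
LOG_GAMMA_HI = np.log(1e8)
_ZERO_RATIO = 1e-7


@dataclass
class FitResult:
    """REML estimates on the variance scale plus fit diagnostics."""

    sigma2_poly: float
    sigma2_term: float  # 0.0 when the model has no marker term
    sigma2_e: float
    loglik: float
    converged: bool
    n_iter: int
    has_marker_term: bool = False


def drop_aliased_columns(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Greedy left-to-right removal of linearly dependent columns.

    First-come columns are kept, so reparameterising (e.g. keeping vs
    dropping a reference station level) changes only which copy of the
    aliased information survives, not the fitted model.
    """
    X = np.asarray(X, dtype=float)
    keep: list[int] = []
    basis = np.zeros((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        if basis.shape[1]:
            resid = col - basis @ (basis.T @ col)
        else:
            resid = col.copy()
        norm = np.linalg.norm(resid)
        if norm > tol * max(1.0, np.linalg.norm(col)):
            keep.append(j)
            basis = np.hstack([basis, (resid / norm)[:, None]])
    return X[:, keep]


def build_design(phen: pd.DataFrame) -> np.ndarray:
    """Fixed-effect design: intercept, station indicators, covariates."""
    parts = [np.ones((len(phen), 1))]
    stations = pd.get_dummies(phen["station"].astype(str), dtype=float)
    parts.append(stations.to_numpy())
    parts.append(phen[["age_entry", "days_test", "litter_alive"]].to_numpy(float))
    return drop_aliased_columns(np.hstack(parts))


class MixedModel:
    """One response/design/relationship triple, ready for repeated fits.

    The eigendecomposition of A is done once at construction; the genome
    scans then call :meth:`fit` per marker with only the marker design
    changing.
    """

    def __init__(self, y, X, A: np.ndarray | None = None):
        y = np.asarray(y, dtype=float)
        X = drop_aliased_columns(np.asarray(X, dtype=float))
        n, p = X.shape
        if len(y) != n:
            raise ValueError("response/design length mismatch")
        if n <= p + 1:
            raise ValueError("need n > rank(X) + 1 observations")
        if np.var(y) == 0:
            raise ValueError("response is constant; REML criterion degenerate")
        self.n, self.p = n, p
        self.has_A = A is not None
        if A is not None:
            A = np.asarray(A, dtype=float)
            if A.shape != (n, n):
                raise ValueError("relationship matrix shape mismatch")
            d, U = eigh(A)
            self.d = np.clip(d, 0.0, None)
            self.U = U
            self.ytil = U.T @ y
            self.Xtil = U.T @ X
        else:
            self.d = np.zeros(n)
            self.U = None
            self.ytil = y.copy()
            self.Xtil = X
        self._yX = np.column_stack([self.ytil, self.Xtil])

    def rotate(self, W: np.ndarray) -> np.ndarray:
        return W if self.U is None else self.U.T @ W

    # ---------------------------------------------------------- criterion

    def _neg2_profiled(self, ga: float, gm: float, Wtil: np.ndarray | None):
        """(criterion, sigma2_e_hat) for variance ratios (ga, gm)."""
        n, p = self.n, self.p
        dvec = 1.0 + ga * self.d
        dinv = 1.0 / dvec
        yX = self._yX
        Z = yX * dinv[:, None]
        G = yX.T @ Z
        lndetV = float(np.log(dvec).sum())
        if Wtil is not None and gm > 0:
            if Wtil.shape[1] == 1:  # rank-1 (SNP dosage): scalar Woodbury
                w = Wtil[:, 0]
                S = (w * dinv) @ yX  # (p+1,)
                kscal = 1.0 + gm * float((w * w) @ dinv)
                lndetV += np.log(kscal)
                G = G - (gm / kscal) * np.outer(S, S)
            else:
                S = Wtil.T @ Z  # k x (p+1)
                K = gm * (Wtil.T @ (Wtil * dinv[:, None]))
                K[np.diag_indices_from(K)] += 1.0
                cK = np.linalg.cholesky(K)
                lndetV += 2.0 * float(np.log(np.diag(cK)).sum())
                half = np.linalg.solve(cK, S)
                G = G - gm * half.T @ half
        yy, Xy, M = G[0, 0], G[1:, 0], G[1:, 1:]
        cM = np.linalg.cholesky(M)
        lndetM = 2.0 * float(np.log(np.diag(cM)).sum())
        hx = np.linalg.solve(cM, Xy)
        ss = float(yy - hx @ hx)
        if ss <= 0:
            return np.inf, 0.0
        s2e = ss / (n - p)
        crit = (n - p) * np.log(s2e) + lndetV + lndetM + (n - p)
        return crit, s2e

    def loglik_at(self, sigma2_poly, sigma2_term, sigma2_e, W=None) -> float:
        """REML log-likelihood at fixed variance components (dense path
        kept simple; used for diagnostics and cross-checks)."""
        n = self.n
        V = sigma2_e * np.eye(n) + sigma2_poly * np.diag(self.d)
        Wtil = None if W is None else self.rotate(np.atleast_2d(np.asarray(W, float).reshape(n, -1)))
        if Wtil is not None:
            V = V + sigma2_term * (Wtil @ Wtil.T)
        Vi = np.linalg.inv(V)
        ViX = Vi @ self.Xtil
        Viy = Vi @ self.ytil
        M = self.Xtil.T @ ViX
        Xy = ViX.T @ self.ytil
        quad = float(self.ytil @ Viy - Xy @ np.linalg.solve(M, Xy))
        _, lndetV = np.linalg.slogdet(V)
        _, lndetM = np.linalg.slogdet(M)
        return -0.5 * (lndetV + lndetM + quad)

    # ---------------------------------------------------------- fitting

    def fit(
        self,
        W: np.ndarray | None = None,
        ga_start: float = 1.0,
        gm_start: float = 0.1,
        tol: float = 1e-9,
    ) -> FitResult:
        """Maximise the profiled REML criterion.

        ``W`` is the (unrotated) marker design, one column per random
        level (a single dosage column for GWAS, cluster incidence for
        LDLA); ``None`` fits the polygenic null.
        """
        Wtil = None
        if W is not None:
            W = np.asarray(W, dtype=float).reshape(self.n, -1)
            Wtil = self.rotate(W)

        free: list[str] = []
        if self.has_A:
            free.append("a")
        if Wtil is not None:
            free.append("m")

        if not free:
            crit, s2e = self._neg2_profiled(0.0, 0.0, None)
            return FitResult(0.0, 0.0, s2e, -0.5 * crit, True, 0, False)

        def unpack(theta):
            ga = gm = 0.0
            k = 0
            if "a" in free:
                ga = np.exp(theta[k])
                k += 1
            if "m" in free:
                gm = np.exp(theta[k])
            return ga, gm

        def objective(theta):
            ga, gm = unpack(theta)
            crit, _ = self._neg2_profiled(ga, gm, Wtil)
            return crit

        x0 = []
        if "a" in free:
            x0.append(np.log(max(ga_start, 1e-6)))
        if "m" in free:
            x0.append(np.log(max(gm_start, 1e-6)))
        res = optimize.minimize(
            objective,
            np.array(x0),
            method="L-BFGS-B",
            bounds=[(LOG_GAMMA_LO, LOG_GAMMA_HI)] * len(free),
            options={"ftol": tol, "gtol": 1e-7, "maxiter": 200},
        )
        if not res.success:
            # the quasi-Newton line search can stall on finite-difference
            # noise near the optimum; a simplex polish settles it
            polish = optimize.minimize(
                objective,
                res.x,
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 400},
            )
            if polish.fun <= res.fun:
                res = polish
        ga, gm = unpack(res.x)
        ga = min(max(ga, 0.0), np.exp(LOG_GAMMA_HI))
        gm = min(max(gm, 0.0), np.exp(LOG_GAMMA_HI))
        crit, s2e = self._neg2_profiled(ga, gm, Wtil)
        if ga < _ZERO_RATIO:
            ga = 0.0
        if gm < _ZERO_RATIO:
            gm = 0.0
        loglik = -0.5 * crit
        converged = bool(res.success) and np.isfinite(loglik)
        return FitResult(
            sigma2_poly=ga * s2e,
            sigma2_term=gm * s2e,
            sigma2_e=s2e,
            loglik=loglik,
            converged=converged,
            n_iter=int(res.nit),
            has_marker_term=Wtil is not None,
        )


def reml_fit(y, X, A=None, W=None, **kw) -> FitResult:
    """Convenience one-shot REML fit (see :class:`MixedModel`)."""
    return MixedModel(y, X, A).fit(W=W, **kw)


def lnlik_ratio(full: FitResult, null: FitResult) -> float:
    """LnLikratio = loglik(model incl. marker) - loglik(model excl.).

    Clamped at zero: the nested null can only undershoot numerically.
    """
    if not (full.converged and null.converged):
        raise ValueError("both fits must have converged")
    return max(full.loglik - null.loglik, 0.0)


def pointwise_p(lnlikratio: float) -> float:
    """Pr(chi-square_1 >= 2 * LnLikratio) — the pointwise reference.

    Testing a variance component on its boundary makes chi-square(1)
    conservative (the null is a 50:50 mixture with a point mass at 0);
    the plain chi-square(1) reference is used deliberately.
    """
    return float(chi2.sf(2.0 * max(lnlikratio, 0.0), df=1))
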
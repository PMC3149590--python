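"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: dense
linear algebra instead of the rotated/Woodbury REML evaluation,
recursive coancestry instead of the tabular relationship recursion,
all-pairs run scanning instead of the windowed haplotype clustering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


# ---------------------------------------------------------------- REML


def dense_reml_loglik(y, X, A, W, s2a, s2m, s2e):
    """REML criterion -0.5[log|V| + log|X'V^-1 X| + y'Py], dense V."""
    n = len(y)
    V = s2e * np.eye(n) + s2a * A
    if W is not None:
        V = V + s2m * (W @ W.T)
    Vi = np.linalg.inv(V)
    M = X.T @ Vi @ X
    Xy = X.T @ Vi @ y
    quad = y @ Vi @ y - Xy @ np.linalg.solve(M, Xy)
    return -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(M)[1] + quad)


def grid_reml_oracle(y, X, A, W, rounds=10, pts=13):
    """Nested grid search over variance ratios (profiled residual var).

    For ratios (ga, gm) the residual variance maximising the criterion
    is s2e = y'P0 y/(n-p) with V0 = I + ga A + gm WW' (closed form);
    the grid refines around the incumbent until the ratio resolution
    supports ~1e-5 accuracy on the log-likelihood.
    """
    n, p = X.shape

    def profiled(ga, gm):
        V0 = np.eye(n) + ga * A
        if W is not None:
            V0 = V0 + gm * (W @ W.T)
        Vi = np.linalg.inv(V0)
        M = X.T @ Vi @ X
        Xy = X.T @ Vi @ y
        ss = y @ Vi @ y - Xy @ np.linalg.solve(M, Xy)
        if ss <= 0:
            return -np.inf
        s2e = ss / (n - p)
        return dense_reml_loglik(y, X, A, W, ga * s2e, gm * s2e, s2e)

    lo_a, hi_a = 1e-8, 1e6
    lo_m, hi_m = 1e-8, 1e6
    best = (-np.inf, 1.0, 1.0)
    width = None  # multiplicative half-width, shrinks each round
    for _ in range(rounds):
        gas = np.geomspace(lo_a, hi_a, pts)
        gms = np.geomspace(lo_m, hi_m, pts) if W is not None else np.array([0.0])
        for ga in gas:
            for gm in gms:
                ll = profiled(ga, gm)
                if ll > best[0]:
                    best = (ll, ga, gm)
        _, ga, gm = best
        # multiplicative half-width shrinks geometrically toward 1
        k = 0 if width is None else width + 1
        width = k
        w = 1.0 + 3.0 * 0.4**k
        lo_a, hi_a = max(ga, 1e-9) / w, max(ga, 1e-9) * w
        if W is not None:
            lo_m, hi_m = max(gm, 1e-9) / w, max(gm, 1e-9) * w
    return best[0]


# ---------------------------------------------------------------- kinship


def kinship(a: str, b: str, parents: dict) -> float:
    """Recursive coancestry; ``parents[id] = (sire|None, dam|None)``."""
    order = {}

    def depth(x):
        if x is None:
            return -1
        if x not in order:
            s, d = parents.get(x, (None, None))
            order[x] = 1 + max(depth(s), depth(d))
        return order[x]

    def f(x, z):
        if x is None or z is None:
            return 0.0
        if x == z:
            s, d = parents.get(x, (None, None))
            return 0.5 * (1.0 + f(s, d))
        # recurse on the later-generation member
        if depth(x) < depth(z):
            x, z = z, x
        s, d = parents.get(x, (None, None))
        return 0.5 * (f(s, z) + f(d, z))

    return f(a, b)


def kinship_matrix(ped: pd.DataFrame) -> tuple[list, np.ndarray]:
    ped = ped.astype(str)
    parents = {
        r.id: (r.sire if r.sire != "0" else None, r.dam if r.dam != "0" else None)
        for r in ped.itertuples()
    }
    ids = list(ped["id"])
    K = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids[: i + 1]):
            K[i, j] = K[j, i] = kinship(a, b, parents)
    return ids, K


# ---------------------------------------------------------------- clustering


def brute_force_clusters(
    haps: np.ndarray, focal: int, threshold: int, closure: str = "reference"
) -> np.ndarray:
    """All-pairs identity scan + closure, by direct rule application.

    Left run includes the focal marker; right run starts at the next
    marker; both stop at the first mismatch or chromosome end. The pair
    relation is closed either by connected components ("single") or by
    greedy first-unassigned reference assignment ("reference").
    """
    n, m = haps.shape

    def score(i, j):
        left = 0
        k = focal
        while k >= 0 and haps[i, k] == haps[j, k]:
            left += 1
            k -= 1
        right = 0
        k = focal + 1
        while k < m and haps[i, k] == haps[j, k]:
            right += 1
            k += 1
        return left + right

    identical = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            identical[i, j] = identical[j, i] = score(i, j) >= threshold

    labels = np.full(n, -1)
    lab = 0
    if closure == "reference":
        for r in range(n):
            if labels[r] >= 0:
                continue
            labels[r] = lab
            for i in range(n):
                if labels[i] < 0 and identical[r, i]:
                    labels[i] = lab
            lab += 1
        return labels
    for s in range(n):
        if labels[s] >= 0:
            continue
        stack = [s]
        labels[s] = lab
        while stack:
            u = stack.pop()
            for v in range(n):
                if identical[u, v] and labels[v] < 0:
                    labels[v] = lab
                    stack.append(v)
        lab += 1
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    seen = {}
    for x, y in zip(a, b):
        if x in seen:
            if seen[x] != y:
                return False
        else:
            seen[x] = y
    return len(set(seen.values())) == len(seen)


def random_pedigree(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random multi-generation pedigree of ~n individuals."""
    rows = []
    ids = []
    for i in range(n):
        me = f"I{i}"
        if i < 6 or rng.random() < 0.3:
            rows.append((me, "0", "0"))
        else:
            s, d = rng.choice(len(ids), 2, replace=False)
            rows.append((me, ids[s], ids[d]))
        ids.append(me)
    return pd.DataFrame(rows, columns=["id", "sire", "dam"])
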
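"""Constrained, regularized NMF for methylome dissection.

A complete loci x samples methylation matrix N is factorized as
``N ~ W H`` with latent methylation component (LMC) profiles
``W in [0,1]^(loci x k)`` and mixing proportions ``H`` whose columns live
on the probability simplex. The objective

    ||N - W H||_F^2 + lambda * sum_ij W_ij (1 - W_ij)

adds a concave penalty minimized exactly at {0,1}, nudging LMC profiles
toward biologically plausible binary methylation states. Alternating
minimization: the H-step solves an exact simplex-constrained least
squares per sample column (active-set QP); the W-step runs exact
per-coordinate updates of a box-constrained quadratic, falling back to
the better of the {0,1} endpoints when the penalty makes a coordinate
concave. Both steps decrease the objective, so its trace is
non-increasing.

Model order k and penalty weight lambda are selected by cross-validation
over held-out loci, and fitted LMCs are matched to reference profiles by
mutual-best Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .comethy import MethMatrix

__all__ = [
    "LmcResult",
    "CvGrid",
    "LmcAssignment",
    "factorize",
    "cross_validate",
    "match_lmcs",
    "solve_simplex_ls",
    "box_ls_rows",
]


@dataclass
class LmcResult:
    W: np.ndarray                  # loci x k, in [0,1]
    H: np.ndarray                  # k x samples, simplex columns
    objective_trace: np.ndarray    # non-increasing
    k: int
    lam: float
    n_restarts: int
    best_seed: int
    loci: list[str] | None = None
    samples: list[str] | None = None

    def w_frame(self) -> pd.DataFrame:
        cols = [f"LMC{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.W, index=self.loci, columns=cols)

    def h_frame(self) -> pd.DataFrame:
        rows = [f"LMC{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.H, index=rows, columns=self.samples)


@dataclass
class CvGrid:
    errors: pd.DataFrame           # long format: k, lam, fold, error
    selected: tuple[int, float]    # 1-SE choice
    minimizer: tuple[int, float]

    def mean_errors(self) -> pd.DataFrame:
        return (self.errors.groupby(["k", "lam"])["error"]
                .mean().reset_index())

    def elbow_k(self, drop_frac: float = 0.05) -> int:
        """Largest k still preceded by a substantial error drop.

        A drop from k-1 to k counts as substantial when it exceeds
        ``drop_frac`` of the total error range over the k grid (at each k the
        best lambda is used). This locates the 'knee' of the curve, which the
        minimizer and the 1-SE rule overshoot when the tail is flat but
        noiseless.
        """
        m = self.mean_errors().groupby("k")["error"].min()
        ks = sorted(m.index)
        total = m[ks[0]] - m.min()
        if total <= 0:
            return ks[0]
        elbow = ks[0]
        for prev, k in zip(ks, ks[1:]):
            if m[prev] - m[k] > drop_frac * total:
                elbow = k
        return int(elbow)


@dataclass
class LmcAssignment:
    pairs: list[tuple[int, str]]           # (LMC column index, reference id)
    unmatched_references: list[str]
    correlations: pd.DataFrame = field(default=None, repr=False)


def solve_simplex_ls(W: np.ndarray, y: np.ndarray, ridge: float = 1e-12,
                     max_iter: int = 200) -> np.ndarray:
    """Exact least squares of y on the columns of W over the simplex.

    minimize ||y - W h||^2  s.t.  h >= 0, sum h = 1, via a primal
    active-set QP (k is small, <= a few dozen).
    """
    k = W.shape[1]
    if k == 1:
        return np.array([1.0])
    Q = W.T @ W + ridge * np.eye(k)
    c = W.T @ y
    h = np.full(k, 1.0 / k)
    clamped = np.zeros(k, dtype=bool)
    for _ in range(max_iter):
        free = ~clamped
        nf = int(free.sum())
        # equality-constrained QP on the free coordinates
        K = np.zeros((nf + 1, nf + 1))
        K[:nf, :nf] = Q[np.ix_(free, free)]
        K[:nf, nf] = 1.0
        K[nf, :nf] = 1.0
        rhs = np.concatenate([c[free], [1.0]])
        try:
            sol = np.linalg.solve(K, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
        h_free, nu = sol[:nf], sol[nf]
        if (h_free >= -1e-12).all():
            h = np.zeros(k)
            h[free] = np.clip(h_free, 0.0, None)
            h /= h.sum()
            if not clamped.any():
                return h
            # multipliers of the clamped coordinates
            mu = Q[np.ix_(clamped, free)] @ h[free] - c[clamped] + nu
            if (mu >= -1e-10).all():
                return h
            release = np.flatnonzero(clamped)[int(np.argmin(mu))]
            clamped[release] = False
            continue
        # step from current h toward the equality solution until blocked
        target = np.zeros(k)
        target[free] = h_free
        d = target - h
        neg = (d < -1e-15) & free
        alpha = min(1.0, np.min(-h[neg] / d[neg])) if neg.any() else 1.0
        h = h + alpha * d
        h[h < 1e-15] = 0.0
        block = free & (h <= 0.0)
        if block.any() and int(clamped.sum()) < k - 1:
            clamped[np.flatnonzero(block)[0]] = True
    return h / h.sum()


def _h_step(N: np.ndarray, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    Hn = np.empty_like(H)
    for j in range(N.shape[1]):
        Hn[:, j] = solve_simplex_ls(W, N[:, j])
    return Hn


def box_ls_rows(N: np.ndarray, H: np.ndarray, W0: np.ndarray, lam: float = 0.0,
                n_passes: int = 50, tol: float = 1e-12) -> np.ndarray:
    """Minimize ||N - W H||^2 + lam * sum W(1-W) over W in [0,1], rows
    independent, by exact cyclic coordinate descent started at W0.

    Per coordinate the objective is quadratic with curvature G_jj - lam; when
    the penalty makes it non-convex, the better {0,1} endpoint is taken.
    """
    G = H @ H.T
    C = N @ H.T
    W = W0.copy()
    k = W.shape[1]
    for _ in range(n_passes):
        delta = 0.0
        for j in range(k):
            r = C[:, j] - W @ G[:, j] + W[:, j] * G[j, j]
            q = G[j, j] - lam
            if q > 1e-15:
                new = np.clip((r - lam / 2.0) / q, 0.0, 1.0)
            else:
                # concave coordinate: f(w) = q w^2 + (lam - 2 r) w + const
                f1 = q + lam - 2.0 * r
                new = (f1 < 0.0).astype(np.float64)
            delta = max(delta, float(np.max(np.abs(new - W[:, j]), initial=0.0)))
            W[:, j] = new
        if delta < tol:
            break
    return W


def _objective(N, W, H, lam) -> float:
    r = N - W @ H
    return float((r * r).sum() + lam * (W * (1.0 - W)).sum())


def factorize(matrix, k: int, lam: float = 0.0, n_restarts: int = 10,
              max_iter: int = 300, tol: float = 1e-7, seed: int = 0,
              callback=None) -> LmcResult:
    """Best-of-restarts alternating minimization.

    ``matrix`` may be a MethMatrix or a plain loci x samples array/DataFrame.
    ``callback(iteration, W, H)``, if given, sees every accepted iterate of
    the winning restart's optimization path (it is invoked during each
    restart; use it for invariant monitoring).
    """
    if isinstance(matrix, MethMatrix):
        N = matrix.values.to_numpy(dtype=float)
        loci, samples = matrix.loci, matrix.samples
    elif isinstance(matrix, pd.DataFrame):
        N = matrix.to_numpy(dtype=float)
        loci, samples = list(matrix.index), list(matrix.columns)
    else:
        N = np.asarray(matrix, dtype=float)
        loci = samples = None
    n_loci, n_samples = N.shape
    if k < 1 or k > min(n_loci, n_samples):
        raise ValueError(f"k={k} infeasible for a {n_loci}x{n_samples} matrix")
    if np.isnan(N).any():
        raise ValueError("matrix must be complete; impute upstream")

    best = None
    for r in range(n_restarts):
        rseed = seed + 104729 * r
        rng = np.random.default_rng(rseed)
        cols = rng.choice(n_samples, size=k, replace=k > n_samples)
        W = np.clip(N[:, cols] + rng.normal(0.0, 0.02, size=(n_loci, k)), 0.0, 1.0)
        H = np.full((k, n_samples), 1.0 / k)
        trace = [_objective(N, W, H, lam)]
        if callback:
            callback(0, W, H)
        for it in range(1, max_iter + 1):
            H = _h_step(N, W, H)
            W = box_ls_rows(N, H, W, lam=lam, n_passes=10)
            obj = _objective(N, W, H, lam)
            # exact blockwise minimization cannot increase the objective;
            # clip fp jitter so the recorded trace is non-increasing
            obj = min(obj, trace[-1])
            trace.append(obj)
            if callback:
                callback(it, W, H)
            if trace[-2] - trace[-1] < tol * max(1.0, trace[-2]):
                break
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], W, H, np.array(trace), rseed)
    _, W, H, trace, rseed = best
    return LmcResult(W=W, H=H, objective_trace=trace, k=k, lam=lam,
                     n_restarts=n_restarts, best_seed=rseed,
                     loci=loci, samples=samples)


def cross_validate(matrix, k_grid, lambda_grid, folds: int = 10, seed: int = 0,
                   n_restarts: int = 3, max_iter: int = 150) -> CvGrid:
    """Hold-out-loci cross-validation of (k, lambda).

    Each fold drops a subset of loci; the model is fitted on the remaining
    rows and held-out rows are regressed onto the fitted H under the [0,1]
    box, scoring mean squared reconstruction error. ``selected`` applies the
    one-standard-error rule (smallest k, then smallest lambda, within one SE
    of the minimum); ``minimizer`` is the plain argmin.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if isinstance(matrix, MethMatrix):
        N = matrix.values.to_numpy(dtype=float)
    elif isinstance(matrix, pd.DataFrame):
        N = matrix.to_numpy(dtype=float)
    else:
        N = np.asarray(matrix, dtype=float)
    rows = []
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for fold, (train, test) in enumerate(kf.split(N)):
        for k in k_grid:
            for lam in lambda_grid:
                res = factorize(N[train], k=k, lam=lam, n_restarts=n_restarts,
                                max_iter=max_iter, seed=seed + fold)
                W_test = box_ls_rows(N[test], res.H,
                                     np.full((len(test), k), 0.5), lam=0.0)
                err = float(((N[test] - W_test @ res.H) ** 2).mean())
                rows.append({"k": k, "lam": lam, "fold": fold, "error": err})
    errors = pd.DataFrame(rows)
    stats = errors.groupby(["k", "lam"])["error"].agg(["mean", "sem"]).reset_index()
    i_min = stats["mean"].idxmin()
    minimizer = (int(stats.loc[i_min, "k"]), float(stats.loc[i_min, "lam"]))
    thresh = stats.loc[i_min, "mean"] + np.nan_to_num(stats.loc[i_min, "sem"])
    ok = stats[stats["mean"] <= thresh].sort_values(["k", "lam"])
    selected = (int(ok.iloc[0]["k"]), float(ok.iloc[0]["lam"]))
    return CvGrid(errors=errors, selected=selected, minimizer=minimizer)


def match_lmcs(W, references) -> LmcAssignment:
    """Mutual-best-correlation assignment of LMCs to reference profiles.

    ``W``: loci x k array or DataFrame; ``references``: loci x types frame
    over the same loci. Ties in a best match (within 1e-12) make the LMC
    ambiguous, hence unmatched; constant columns are unmatched with a warning.
    """
    W = pd.DataFrame(W) if not isinstance(W, pd.DataFrame) else W
    refs = references.values if isinstance(references, MethMatrix) else references
    if list(W.index) != list(refs.index) and len(W) != len(refs):
        raise ValueError("W and references must cover the same loci")
    k = W.shape[1]
    ref_ids = list(refs.columns)
    cor = np.full((k, len(ref_ids)), np.nan)
    for i in range(k):
        w = W.iloc[:, i].to_numpy(dtype=float)
        if np.std(w) == 0:
            warnings.warn(f"LMC {i} is constant; correlation undefined")
            continue
        for j, rid in enumerate(ref_ids):
            r = refs[rid].to_numpy(dtype=float)
            if np.std(r) == 0:
                continue
            cor[i, j] = np.corrcoef(w, r)[0, 1]
    pairs = []
    for i in range(k):
        row = cor[i]
        if np.all(np.isnan(row)):
            continue
        j = int(np.nanargmax(row))
        ties = np.flatnonzero(np.abs(row - row[j]) < 1e-12)
        if len(ties) > 1:
            continue
        col = cor[:, j]
        i_best = int(np.nanargmax(col))
        col_ties = np.flatnonzero(np.abs(col - col[i_best]) < 1e-12)
        if i_best == i and len(col_ties) == 1:
            pairs.append((i, ref_ids[j]))
    matched = {rid for _, rid in pairs}
    cor_df = pd.DataFrame(cor, index=[f"LMC{i + 1}" for i in range(k)],
                          columns=ref_ids)
    return LmcAssignment(pairs=pairs,
                         unmatched_references=[r for r in ref_ids if r not in matched],
                         correlations=cor_df)
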
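"""One- and two-component beta mixtures for read/cell methylation levels.

A segment's per-unit methylation levels are modelled as draws from
either a single beta distribution (homogeneous population) or a
two-component beta mixture (bipolar population split into hypo- and
hypermethylated subsets). Bipolarity is scored by the likelihood-ratio
statistic of the two fits; because mixture-order LRTs are non-regular,
the default p-value comes from a parametric bootstrap under the fitted
one-component null, with a fast chi-square(df=2) approximation
available.

Two observation models share one EM engine. Continuous levels use the
beta density on levels shrunk into the open interval. Levels that are
counts out of m sites (4-CpG segments: m = 4, levels on the grid
{0, 1/4, ..., 1}) use the beta-binomial likelihood instead — the beta
describes the latent per-unit level and the binomial the m-site
sampling. On grid data a continuous density would let a component
collapse onto a single atom and blow up the likelihood; the bounded
beta-binomial pmf removes that degeneracy, and the bootstrap then draws
levels from the fitted beta and resamples m sites binomially, matching
the data-generating process.

Component shapes are constrained to a, b >= 1 (no U-shaped densities):
a homogeneous population is unimodal or J-shaped, so mass concentrated
at both boundaries must be carried by the mixture rather than absorbed
into a single U-shaped null. EM uses weighted method-of-moments updates
(fast and stable on small per-segment samples); reported log-likelihoods
are exact, and the fitted two-component likelihood never falls below the
one-component one (the degenerate equal-components solution is always a
candidate).

All fitting routines are vectorised over a batch axis so the hundreds of
bootstrap replicate datasets of one test are fitted in a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln
from scipy.stats import chi2

#: boundary shrink for exact 0/1 levels: 1/(2 * 4 CpG sites)
EPS_LEVEL = 0.125

_NU_MAX = 1e4   # cap on total concentration a+b
_VAR_MIN = 1e-6

__all__ = [
    "BetaMixtureFit",
    "shrink_levels",
    "fit_beta_mixture",
    "test_bipolarity",
    "bipolarity_pvalue",
    "assign_subsets",
    "EPS_LEVEL",
]


@dataclass
class BetaMixtureFit:
    """Two-component fit next to its one-component null."""

    weights: np.ndarray           # (2,), sums to 1
    params: np.ndarray            # (2, 2): [(a_lo, b_lo), (a_hi, b_hi)] by mean
    responsibilities: np.ndarray  # (n, 2), rows sum to 1
    ll1: float
    ll2: float
    converged: bool = True
    counts_m: int | None = None   # sites per unit when beta-binomial

    @property
    def component_means(self) -> np.ndarray:
        a, b = self.params[:, 0], self.params[:, 1]
        return a / (a + b)

    @property
    def lrt(self) -> float:
        return max(0.0, 2.0 * (self.ll2 - self.ll1))


def shrink_levels(levels, eps: float = EPS_LEVEL) -> np.ndarray:
    """Move exact 0/1 levels eps into the open interval (beta support)."""
    x = np.asarray(levels, dtype=np.float64).copy()
    x[x <= 0.0] = eps
    x[x >= 1.0] = 1.0 - eps
    return x


def _mom_ab(mean, var):
    """Method-of-moments beta shapes from a latent-level (mean, variance).

    Both shapes are kept >= 1 (no U-shapes) and the total concentration is
    capped; the mean is preserved under both constraints, so concentrated
    subsets keep their location.
    """
    mean = np.clip(mean, 1e-4, 1.0 - 1e-4)
    cap = mean * (1.0 - mean)
    var = np.clip(var, _VAR_MIN, 0.999 * cap)
    nu = cap / var - 1.0
    nu_floor = 1.0 / np.minimum(mean, 1.0 - mean)  # smaller shape = 1 exactly
    nu = np.clip(np.maximum(nu, nu_floor), None, _NU_MAX)
    a = np.maximum(mean * nu, 1.0)
    b = np.maximum((1.0 - mean) * nu, 1.0)
    return a, b


def _latent_moments(mean, var, m):
    """Moments of the latent beta level from observed level moments.

    For counts-of-m data the observed variance contains a binomial sampling
    share mean(1-mean)/m on top of the latent variance; subtract it (floored)
    before moment matching. m=None passes moments through (continuous data).
    """
    if m is None:
        return mean, var
    cap = np.clip(mean, 1e-4, 1 - 1e-4) * (1 - np.clip(mean, 1e-4, 1 - 1e-4))
    lat = (var - cap / m) / (1.0 - 1.0 / m)
    return mean, np.maximum(lat, _VAR_MIN)


def _bb_logpmf_table(a, b, m):
    """Beta-binomial log pmf over k = 0..m for shape arrays of any shape.

    Returns an array with a trailing axis of length m+1; counts index into it,
    so the expensive gammaln evaluations scale with m, not with sample size.
    """
    k = np.arange(m + 1.0)
    const = gammaln(m + 1.0) - gammaln(k + 1.0) - gammaln(m - k + 1.0)
    ae = a[..., None]
    be = b[..., None]
    return const + betaln(k + ae, (m - k) + be) - betaln(ae, be)


def _fit_one_batch(X, m=None):
    """One-component fit per row of (B, n) levels; returns (a, b, ll)."""
    mean, var = _latent_moments(X.mean(axis=1), X.var(axis=1), m)
    a, b = _mom_ab(mean, var)
    if m is None:
        ll = ((a[:, None] - 1.0) * np.log(X) + (b[:, None] - 1.0) * np.log1p(-X)
              - betaln(a, b)[:, None]).sum(axis=1)
    else:
        K = np.round(X * m).astype(np.intp)
        tab = _bb_logpmf_table(a, b, m)                  # (B, m+1)
        ll = np.take_along_axis(tab, K, axis=1).sum(axis=1)
    return a, b, ll


def _em_two_batch(X, resp0, max_iter, tol, m=None):
    """Batched two-component EM from initial responsibilities.

    X: (B, n) levels; resp0: (B, n, 2). Returns weights (B,2), params
    (B,2,2), ll (B,), resp (B,n,2), converged (B,).
    """
    B, n = X.shape
    Xc = X[:, :, None]
    if m is None:
        logx = np.log(X)[:, :, None]
        log1px = np.log1p(-X)[:, :, None]
        K = None
    else:
        logx = log1px = None
        K = np.round(X * m).astype(np.intp)                  # (B, n)
        rows = np.arange(B)[:, None]
    resp = resp0
    ll_prev = np.full(B, -np.inf)
    converged = np.zeros(B, dtype=bool)
    weights = np.full((B, 2), 0.5)
    ab = np.empty((B, 2, 2))
    for _ in range(max_iter):
        # M-step: weighted latent moments per component
        wsum = resp.sum(axis=1) + 1e-12                      # (B, 2)
        mean = (resp * Xc).sum(axis=1) / wsum
        var = (resp * (Xc - mean[:, None, :]) ** 2).sum(axis=1) / wsum
        a, b = _mom_ab(*_latent_moments(mean, var, m))
        ab = np.stack([a, b], axis=2)                        # (B, 2, 2)
        weights = np.clip(wsum / n, 1e-8, 1.0)
        weights /= weights.sum(axis=1, keepdims=True)
        # E-step
        if m is None:
            logp = ((a[:, None, :] - 1.0) * logx
                    + (b[:, None, :] - 1.0) * log1px
                    - betaln(a, b)[:, None, :])
        else:
            tab = _bb_logpmf_table(a.T, b.T, m)              # (2, B, m+1)
            logp = np.stack([tab[0][rows, K], tab[1][rows, K]], axis=2)
        logp = logp + np.log(weights)[:, None, :]
        norm = np.logaddexp(logp[:, :, 0], logp[:, :, 1])
        resp = np.exp(logp - norm[:, :, None])
        ll = norm.sum(axis=1)
        converged = np.abs(ll - ll_prev) < tol
        if converged.all():
            break
        ll_prev = ll
    return weights, ab, ll, resp, converged


def _init_resps(X, rng, n_restarts):
    """Initial hard assignments: mean-split plus random splits."""
    B, n = X.shape
    inits = []
    hard = (X > X.mean(axis=1, keepdims=True)).astype(np.float64)
    inits.append(np.stack([1.0 - hard, hard], axis=2))
    for _ in range(max(0, n_restarts - 1)):
        h = (rng.random((B, n)) < 0.5).astype(np.float64)
        inits.append(np.stack([1.0 - h, h], axis=2))
    return inits


def _fit_two_batch(X, rng, n_restarts, max_iter, tol, m=None):
    """Best-of-restarts batched EM; restarts ride along the batch axis."""
    B = X.shape[0]
    inits = _init_resps(X, rng, n_restarts)
    R = len(inits)
    Xrep = np.tile(X, (R, 1))
    resp0 = np.concatenate(inits, axis=0)
    w, ab, ll, resp, conv = _em_two_batch(Xrep, resp0, max_iter, tol, m=m)
    pick = ll.reshape(R, B).argmax(axis=0) * B + np.arange(B)
    return w[pick], ab[pick], ll[pick], resp[pick], conv[pick]


def fit_beta_mixture(levels, max_iter: int = 200, tol: float = 1e-8,
                     seed: int = 0, n_restarts: int = 5,
                     eps: float = EPS_LEVEL,
                     counts_m: int | None = None) -> BetaMixtureFit:
    """Fit one- and two-component beta mixtures to one segment's unit levels.

    ``counts_m`` switches to the beta-binomial observation model for levels
    that are counts out of m sites. Components are ordered by mean (index 0 =
    hypomethylated). ``seed`` fixes the random restarts; derive it from the
    segment key for reproducibility.
    """
    raw = np.asarray(levels, dtype=np.float64)
    if raw.ndim != 1 or len(raw) < 2:
        raise ValueError("need at least two unit levels")
    x = raw if counts_m else shrink_levels(raw, eps)
    X = x[None, :]
    _, _, ll1 = _fit_one_batch(X, m=counts_m)
    rng = np.random.default_rng(seed)
    w, ab, ll2, resp, conv = _fit_two_batch(X, rng, n_restarts, max_iter, tol,
                                            m=counts_m)
    w, ab, ll2, resp, conv = w[0], ab[0], float(ll2[0]), resp[0], bool(conv[0])
    ll1 = float(ll1[0])
    if ll2 < ll1:  # degenerate equal-components solution dominates
        ll2 = ll1
    order = np.argsort(ab[:, 0] / ab.sum(axis=1))
    return BetaMixtureFit(weights=w[order], params=ab[order],
                          responsibilities=resp[:, order],
                          ll1=ll1, ll2=ll2, converged=conv, counts_m=counts_m)


def assign_subsets(fit: BetaMixtureFit, raw_levels):
    """Hard partition of units into hypo/hyper subsets with their raw means.

    Returns (hypo_idx, hyper_idx, mu_hypo, mu_hyper, diff); a segment whose
    units all land in one component gets diff = 0 and equal subset means.
    """
    raw = np.asarray(raw_levels, dtype=np.float64)
    hyper = fit.responsibilities[:, 1] > fit.responsibilities[:, 0]
    hypo_idx = np.flatnonzero(~hyper)
    hyper_idx = np.flatnonzero(hyper)
    if len(hypo_idx) == 0 or len(hyper_idx) == 0:
        mu = float(raw.mean())
        return hypo_idx, hyper_idx, mu, mu, 0.0
    mu_hypo = float(raw[hypo_idx].mean())
    mu_hyper = float(raw[hyper_idx].mean())
    if mu_hypo > mu_hyper:  # keep the orientation invariant under relabeling
        hypo_idx, hyper_idx = hyper_idx, hypo_idx
        mu_hypo, mu_hyper = mu_hyper, mu_hypo
    return hypo_idx, hyper_idx, mu_hypo, mu_hyper, mu_hyper - mu_hypo


def test_bipolarity(fit: BetaMixtureFit, levels=None, method: str = "chi2",
                    n_boot: int = 200, seed: int = 0) -> float:
    """p-value for the two- vs one-component likelihood ratio.

    ``chi2`` maps the statistic to a chi-square(2) tail (fast approximation);
    ``bootstrap`` requires the raw levels and recalibrates under the fitted
    one-component null.
    """
    if method == "chi2":
        lam = fit.lrt
        return float(chi2.sf(lam, df=2)) if lam > 1e-8 else 1.0
    if method == "bootstrap":
        if levels is None:
            raise ValueError("bootstrap calibration needs the raw levels")
        p, _ = bipolarity_pvalue(levels, n_boot=n_boot, seed=seed,
                                 discretize=fit.counts_m)
        return p
    raise ValueError(f"unknown method {method!r}")


def bipolarity_pvalue(levels, n_boot: int = 200, seed: int = 0,
                      discretize: int | None = None,
                      n_restarts: int = 2, max_iter: int = 30,
                      tol: float = 1e-6, eps: float = EPS_LEVEL):
    """Parametric-bootstrap p-value of the bipolarity LRT; returns (p, fit).

    Null datasets are drawn from the one-component fit: a plain beta for
    continuous levels, or — with ``discretize=m`` for counts-of-m levels —
    a beta level with binomial resampling of the m sites. Observed and
    replicate statistics use the identical fitting procedure (restarts,
    iterations, tolerance), which the calibration requires.
    """
    raw = np.asarray(levels, dtype=np.float64)
    fit = fit_beta_mixture(raw, max_iter=max_iter, tol=tol, seed=seed,
                           n_restarts=n_restarts, eps=eps, counts_m=discretize)
    lam = fit.lrt
    if lam <= 1e-8:  # numerically indistinguishable fits
        return 1.0, fit
    x = raw if discretize else shrink_levels(raw, eps)
    a0, b0, _ = _fit_one_batch(x[None, :], m=discretize)
    rng = np.random.default_rng(seed + 1)
    # sequential bootstrap (Besag-Clifford): stop once the statistic is
    # clearly unexceptional; run the full n_boot otherwise for resolution
    stop_h, chunk = 10, 50
    exceed, drawn = 0, 0
    while drawn < n_boot:
        c = min(chunk, n_boot - drawn)
        P = rng.beta(a0[0], b0[0], size=(c, len(raw)))
        if discretize:
            Xb = rng.binomial(discretize, P) / discretize
        else:
            Xb = shrink_levels(P, eps)
        _, _, ll1b = _fit_one_batch(Xb, m=discretize)
        _, _, ll2b, _, _ = _fit_two_batch(Xb, rng, n_restarts, max_iter, tol,
                                          m=discretize)
        exceed += int(np.sum(np.maximum(0.0, 2.0 * (ll2b - ll1b)) >= lam))
        drawn += c
        if exceed >= stop_h:
            return exceed / drawn, fit
    return (1.0 + exceed) / (n_boot + 1.0), fit
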
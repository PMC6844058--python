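"""Bipolar-segment candidate selection and pCSM calling.

A 4-CpG segment is a *candidate* cell-type-specific methylation (CSM)
locus when at least one unit (cell or read) shows the fully methylated
pattern "1111" and another the fully unmethylated pattern "0000". For
candidates the per-unit methylation levels are tested for bipolarity: in
single-cell mode with a two- vs one-component beta-mixture likelihood
ratio (:mod:`methdissect.betamix`), in bulk mode after a Dirichlet-process
product-Bernoulli clustering of the raw 4-bit patterns. Segments whose
hypo/hyper subset means differ by more than ``min_diff`` at a
Benjamini–Hochberg adjusted p below ``alpha`` are called pCSM.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .betamix import (BetaMixtureFit, assign_subsets, bipolarity_pvalue,
                      fit_beta_mixture)
from .io_segments import SegmentKey, SegmentProfile

FULL_METH = "1111"
FULL_UNMETH = "0000"

__all__ = [
    "PcsmCall",
    "is_candidate",
    "unit_levels",
    "call_pcsm",
    "cluster_patterns_bulk",
    "subset_diff_stats",
    "calls_to_frame",
    "segment_seed",
]


@dataclass
class PcsmCall:
    """Bipolarity test result for one 4-CpG segment."""

    key: SegmentKey
    hypo_units: tuple[str, ...]
    hyper_units: tuple[str, ...]
    mu_hypo: float
    mu_hyper: float
    diff: float
    p_raw: float
    p_adj: float
    is_pcsm: bool
    coverage: int = 0
    fit: BetaMixtureFit | None = field(default=None, repr=False)


def is_candidate(profile: SegmentProfile) -> bool:
    """True iff the profile holds both a fully methylated and a fully
    unmethylated unit."""
    pats = set(profile.observations.values())
    return FULL_METH in pats and FULL_UNMETH in pats


def unit_levels(profile: SegmentProfile) -> np.ndarray:
    """Per-unit methylation level: methylated sites / 4, in unit-id order."""
    units = sorted(profile.observations)
    return np.array([profile.observations[u].count("1") / 4.0 for u in units])


def segment_seed(key: SegmentKey, base_seed: int = 0) -> int:
    """Stable per-segment RNG seed derived from the genomic key."""
    h = zlib.crc32(str(key).encode()) & 0x7FFFFFFF
    return (h ^ (base_seed * 2654435761 & 0x7FFFFFFF)) & 0x7FFFFFFF


def _subset_call(profile, fit, p_raw):
    units = np.array(sorted(profile.observations))
    raw = unit_levels(profile)
    hypo_idx, hyper_idx, mu_hypo, mu_hyper, diff = assign_subsets(fit, raw)
    return dict(hypo_units=tuple(units[hypo_idx]), hyper_units=tuple(units[hyper_idx]),
                mu_hypo=mu_hypo, mu_hyper=mu_hyper, diff=diff, p_raw=p_raw)


def call_pcsm(profiles, alpha: float = 0.05, min_diff: float = 0.30,
              mode: str = "single_cell", seed: int = 0,
              pvalue_method: str = "bootstrap", n_boot: int = 200,
              max_test_units: int = 60,
              gibbs_sweeps: int = 500, gibbs_burn_in: int = 100) -> list[PcsmCall]:
    """Run the full bipolarity test over filtered segment profiles.

    Non-candidates are never tested (p_raw = p_adj = 1) but still receive a
    subset split so their hypo/hyper methylation difference is reported (a
    single-subset segment gets diff 0). BH adjustment runs over the tested
    candidates only. In single-cell mode the bootstrap null is discretised to
    the 4-site level grid; in bulk mode the DP pattern clustering defines the
    subsets and the same LRT yields the p-value.

    ``max_test_units`` caps the number of units entering the bootstrap test
    (deterministic per-segment subsample): the test's power saturates well
    below typical deep coverage, and the cap bounds worst-case cost. Subset
    assignment and the reported means always use all units.
    """
    calls: list[PcsmCall] = []
    tested_idx: list[int] = []
    for profile in profiles:
        sseed = segment_seed(profile.key, seed)
        raw = unit_levels(profile)
        if len(raw) > max_test_units:
            sub_rng = np.random.default_rng(sseed)
            test_levels = raw[sub_rng.choice(len(raw), max_test_units,
                                             replace=False)]
        else:
            test_levels = raw
        if is_candidate(profile):
            if mode == "single_cell":
                p_raw, _ = bipolarity_pvalue(test_levels, n_boot=n_boot,
                                             seed=sseed, discretize=4)
                fit = fit_beta_mixture(raw, seed=sseed, counts_m=4,
                                       n_restarts=2, max_iter=40, tol=1e-6)
                parts = _subset_call(profile, fit, p_raw)
            else:
                labels = cluster_patterns_bulk(profile, seed=sseed,
                                               n_sweeps=gibbs_sweeps,
                                               burn_in=gibbs_burn_in)
                p_raw, fit = bipolarity_pvalue(test_levels, n_boot=n_boot,
                                               seed=sseed, discretize=4)
                parts = _bulk_subset_call(profile, labels, p_raw)
            tested_idx.append(len(calls))
            calls.append(PcsmCall(key=profile.key, coverage=profile.coverage,
                                  p_adj=1.0, is_pcsm=False, fit=fit, **parts))
        else:
            if len(np.unique(raw)) > 1:
                fit = fit_beta_mixture(raw, seed=sseed, counts_m=4,
                                       n_restarts=2, max_iter=40, tol=1e-6)
                parts = _subset_call(profile, fit, 1.0)
            else:
                units = tuple(sorted(profile.observations))
                mu = float(raw.mean())
                fit = None
                parts = dict(hypo_units=units, hyper_units=(), mu_hypo=mu,
                             mu_hyper=mu, diff=0.0, p_raw=1.0)
            calls.append(PcsmCall(key=profile.key, coverage=profile.coverage,
                                  p_adj=1.0, is_pcsm=False, fit=fit, **parts))
    if tested_idx:
        p_raws = [calls[i].p_raw for i in tested_idx]
        _, p_adjs, _, _ = multipletests(p_raws, method="fdr_bh")
        for i, p_adj in zip(tested_idx, p_adjs):
            c = calls[i]
            c.p_adj = float(p_adj)
            c.is_pcsm = bool(c.diff > min_diff and c.p_adj < alpha)
    return calls


def _bulk_subset_call(profile, labels, p_raw):
    """Reduce DP pattern clusters to hypo/hyper subsets at mean level 0.5."""
    units = np.array(sorted(profile.observations))
    raw = unit_levels(profile)
    lab = np.asarray(labels)
    cluster_ids = np.unique(lab)
    cmeans = np.array([raw[lab == c].mean() for c in cluster_ids])
    hyper_clusters = set(cluster_ids[cmeans >= 0.5])
    hyper = np.array([l in hyper_clusters for l in lab])
    if hyper.all() or not hyper.any():
        mu = float(raw.mean())
        return dict(hypo_units=tuple(units), hyper_units=(), mu_hypo=mu,
                    mu_hyper=mu, diff=0.0, p_raw=p_raw)
    mu_hypo = float(raw[~hyper].mean())
    mu_hyper = float(raw[hyper].mean())
    return dict(hypo_units=tuple(units[~hyper]), hyper_units=tuple(units[hyper]),
                mu_hypo=mu_hypo, mu_hyper=mu_hyper, diff=mu_hyper - mu_hypo,
                p_raw=p_raw)


def cluster_patterns_bulk(profile: SegmentProfile, seed: int = 0,
                          n_sweeps: int = 500, burn_in: int = 100,
                          concentration: float = 1.0) -> np.ndarray:
    """Dirichlet-process product-Bernoulli clustering of 4-bit read patterns.

    Collapsed Gibbs sampling with a Beta(1,1) base per CpG site and CRP
    concentration 1.0 by default; the returned labels come from the
    highest-posterior sweep after burn-in. Labels follow unit-id sort order.
    """
    units = sorted(profile.observations)
    X = np.array([[int(ch) for ch in profile.observations[u]] for u in units])
    n, S = X.shape
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=np.int64)
    # sufficient statistics per cluster: member count and per-site meth count
    counts: dict[int, int] = {0: n}
    meth: dict[int, np.ndarray] = {0: X.sum(axis=0)}
    next_id = 1
    best_labels, best_lp = labels.copy(), -np.inf

    def joint_logpost() -> float:
        lp = 0.0
        for c, nc in counts.items():
            lp += np.log(concentration) + gammaln(nc)
            m = meth[c]
            lp += np.sum(gammaln(m + 1.0) + gammaln(nc - m + 1.0) - gammaln(nc + 2.0))
        return lp

    for sweep in range(n_sweeps):
        for i in range(n):
            c_old = labels[i]
            counts[c_old] -= 1
            meth[c_old] = meth[c_old] - X[i]
            if counts[c_old] == 0:
                del counts[c_old], meth[c_old]
            cids = list(counts)
            logw = np.empty(len(cids) + 1)
            for j, c in enumerate(cids):
                nc, m = counts[c], meth[c]
                pr = (m + 1.0) / (nc + 2.0)
                logw[j] = np.log(nc) + np.sum(
                    X[i] * np.log(pr) + (1 - X[i]) * np.log1p(-pr))
            logw[-1] = np.log(concentration) + S * np.log(0.5)
            logw -= logw.max()
            w = np.exp(logw)
            pick = rng.choice(len(w), p=w / w.sum())
            if pick == len(cids):
                c_new = next_id
                next_id += 1
                counts[c_new] = 0
                meth[c_new] = np.zeros(S, dtype=np.int64)
            else:
                c_new = cids[pick]
            labels[i] = c_new
            counts[c_new] += 1
            meth[c_new] = meth[c_new] + X[i]
        if sweep >= burn_in:
            lp = joint_logpost()
            if lp > best_lp:
                best_lp, best_labels = lp, labels.copy()
    return best_labels


def subset_diff_stats(calls) -> pd.DataFrame:
    """Per-segment overall mean level and hypo/hyper subset difference.

    Segments where only one subset exists carry diff 0, so homogeneous
    fully methylated or fully unmethylated segments contribute no spurious
    heterogeneity signal.
    """
    rows = []
    for c in calls:
        n_hypo, n_hyper = len(c.hypo_units), len(c.hyper_units)
        total = n_hypo + n_hyper
        mean = (c.mu_hypo * n_hypo + c.mu_hyper * n_hyper) / total if total else np.nan
        rows.append({"segment": str(c.key), "mean_level": mean,
                     "diff": c.diff, "is_pcsm": c.is_pcsm})
    return pd.DataFrame(rows)


def calls_to_frame(calls) -> pd.DataFrame:
    """Flat table of pCSM calls (the find-pcsm TSV payload)."""
    return pd.DataFrame([
        {"segment": str(c.key), "chrom": c.key.chrom,
         "pos": ",".join(str(p) for p in c.key.pos),
         "coverage": c.coverage, "mu_hypo": c.mu_hypo, "mu_hyper": c.mu_hyper,
         "diff": c.diff, "p_raw": c.p_raw, "p_adj": c.p_adj,
         "is_pcsm": c.is_pcsm}
        for c in calls
    ])
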
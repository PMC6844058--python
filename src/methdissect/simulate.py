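"""Synthetic methylomes: references, mixtures, planted single-cell data,
and recovery scoring.

The generator builds the study conditions end to end: reference
methylomes pooled from labelled single cells, bulk mixtures of those
references at known Dirichlet-drawn proportions (coverage-weighted, with
optional binomial read-resampling noise), and fully synthetic read-level
single-cell datasets in which a chosen fraction of 4-CpG loci carries a
planted cell-type split (hyper types near 1, hypo types near 0, subset
methylation difference > 0.3 by construction) while the rest share a
common beta-distributed level. Recovery of a factorization is scored by
the RMSE between matched component and reference profiles and by the
mean absolute error (MAE) of the mixing proportions over all reference
types, unmatched types counting as estimated zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decompose import LmcAssignment, LmcResult, match_lmcs
from .io_segments import ReadCalls

__all__ = [
    "MixtureTruth",
    "EvaluationReport",
    "merge_reference",
    "synthesize_mixtures",
    "SyntheticCells",
    "generate_synthetic_cells",
    "select_hvar_cpgs",
    "rmse",
    "mae",
    "evaluate_recovery",
]


@dataclass
class MixtureTruth:
    """Ground truth for one synthetic bulk sample."""

    sample_id: str
    proportions: dict[str, float]
    seed: int

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"proportions sum to {total}, not 1")

    @staticmethod
    def to_frame(truths: list["MixtureTruth"]) -> pd.DataFrame:
        rows = [{"sample_id": t.sample_id, "reference": ref, "proportion": p}
                for t in truths for ref, p in sorted(t.proportions.items())]
        return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    assignment: LmcAssignment
    rmse_per_pair: dict[str, float]
    mae: float
    n_correct: int


def merge_reference(meth_counts: pd.DataFrame, total_counts: pd.DataFrame,
                    cell_types: dict[str, str]):
    """Pool per-cell call counts into per-type reference methylomes.

    ``meth_counts`` / ``total_counts``: loci x cells methylated and total call
    counts; ``cell_types`` maps cell id -> type label. Returns
    (levels loci x types, coverage loci x types).
    """
    types = sorted(set(cell_types.values()))
    levels, cover = {}, {}
    for t in types:
        cells = [c for c in meth_counts.columns if cell_types.get(c) == t]
        if not cells:
            raise ValueError(f"cell type {t!r} has zero cells")
        m = meth_counts[cells].sum(axis=1)
        n = total_counts[cells].sum(axis=1)
        with np.errstate(invalid="ignore"):
            levels[t] = (m / n).astype(float)
        cover[t] = n.astype(float)
    return pd.DataFrame(levels), pd.DataFrame(cover)


def synthesize_mixtures(references: pd.DataFrame, coverage: pd.DataFrame | None = None,
                        n_samples: int = 100, seed: int = 0,
                        proportions: np.ndarray | None = None,
                        resample_depth: int | None = None):
    """Mix reference methylomes at random proportions.

    Proportions are Dirichlet(1,...,1) per sample (uniform on the simplex)
    unless a (n_samples x n_types) matrix is supplied. Mixing is
    coverage-weighted in level space:
    ``level = sum_t p_t c_t m_t / sum_t p_t c_t``; with equal coverage this is
    the plain convex combination. ``resample_depth`` adds binomial
    read-sampling noise at that depth. Returns (loci x samples levels frame,
    list of MixtureTruth).
    """
    rng = np.random.default_rng(seed)
    types = list(references.columns)
    M = references.to_numpy(dtype=float)            # loci x T
    C = (coverage.reindex(columns=types).to_numpy(dtype=float)
         if coverage is not None else np.ones_like(M))
    if proportions is None:
        P = rng.dirichlet(np.ones(len(types)), size=n_samples)
    else:
        P = np.asarray(proportions, dtype=float)
        n_samples = P.shape[0]
    samples, truths = {}, []
    for s in range(n_samples):
        p = P[s]
        wt = C * p[None, :]
        level = (wt * M).sum(axis=1) / wt.sum(axis=1)
        if resample_depth:
            level = rng.binomial(resample_depth, np.clip(level, 0, 1)) / resample_depth
        sid = f"mix{s:03d}"
        samples[sid] = level
        truths.append(MixtureTruth(sample_id=sid,
                                   proportions=dict(zip(types, p.tolist())),
                                   seed=seed))
    # renormalize stored proportions exactly to 1 (float repr round trip)
    for t in truths:
        tot = sum(t.proportions.values())
        t.proportions = {k: v / tot for k, v in t.proportions.items()}
    return pd.DataFrame(samples, index=references.index), truths


@dataclass
class SyntheticCells:
    """Planted single-cell dataset: reads plus complete ground truth."""

    reads: list[ReadCalls]
    truth: pd.DataFrame            # per locus: chrom, positions, is_csm, ...
    cell_types: dict[str, str]
    type_levels: pd.DataFrame      # loci x types true methylation levels
    config: dict = field(default_factory=dict)

    def locus_ids(self) -> list[str]:
        return list(self.truth["locus"])


def generate_synthetic_cells(n_types: int = 5, cells_per_type: int = 40,
                             n_loci: int = 5000, frac_csm: float = 0.2,
                             depth: int = 1, seed: int = 0,
                             hyper_beta=(9.0, 1.0), hypo_beta=(1.0, 9.0),
                             shared_beta=(0.3, 0.3),
                             min_planted_diff: float = 0.3) -> SyntheticCells:
    """Generate read-level 4-CpG data with planted cell-type-specific loci.

    Each locus holds 4 CpGs. A CSM locus assigns a random proper subset of
    types a hypermethylated level ~ Beta(hyper) and the rest ~ Beta(hypo),
    redrawn until the group means differ by more than ``min_planted_diff``;
    a non-CSM locus gives every type one shared level ~ Beta(shared) (the
    U-shaped default mimics the hypo/hyper concentration of real bulk
    methylomes). Every cell contributes ``depth`` reads per locus, each with
    4 Bernoulli(level) site calls.
    """
    if not 0.0 <= frac_csm < 1.0:
        raise ValueError("frac_csm must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    types = [f"type{t + 1}" for t in range(n_types)]
    cells = [f"{t}_c{i:03d}" for t in types for i in range(cells_per_type)]
    cell_types = {c: c.split("_c")[0] for c in cells}

    n_csm = int(round(frac_csm * n_loci))
    is_csm = np.zeros(n_loci, dtype=bool)
    is_csm[rng.choice(n_loci, size=n_csm, replace=False)] = True

    loci_rows = []
    levels = np.empty((n_loci, n_types))
    chrom_loci = 2000  # loci per synthetic chromosome
    for i in range(n_loci):
        chrom = f"chr{i // chrom_loci + 1}"
        start = 1000 + (i % chrom_loci) * 200
        positions = (start, start + 12, start + 25, start + 39)
        if is_csm[i]:
            while True:
                n_hyper = int(rng.integers(1, n_types))
                hyper_set = rng.choice(n_types, size=n_hyper, replace=False)
                lv = rng.beta(*hypo_beta, size=n_types)
                lv[hyper_set] = rng.beta(*hyper_beta, size=n_hyper)
                if lv[hyper_set].mean() - np.delete(lv, hyper_set).mean() > min_planted_diff:
                    break
            hyper_types = ",".join(types[t] for t in sorted(hyper_set))
        else:
            lv = np.full(n_types, rng.beta(*shared_beta))
            hyper_types = ""
        levels[i] = lv
        loci_rows.append({"locus": f"{chrom}:{start}-{positions[-1] + 2}",
                          "chrom": chrom, "positions": positions,
                          "is_csm": bool(is_csm[i]), "hyper_types": hyper_types})
    truth = pd.DataFrame(loci_rows)
    type_levels = pd.DataFrame(levels, index=truth["locus"], columns=types)

    reads = []
    for ci, cell in enumerate(cells):
        t_idx = types.index(cell_types[cell])
        for i in range(n_loci):
            lv = levels[i, t_idx]
            for d in range(depth):
                calls = tuple((rng.random(4) < lv).astype(int))
                reads.append(ReadCalls(unit_id=cell,
                                       chrom=truth["chrom"].iloc[i],
                                       cpg_positions=truth["positions"].iloc[i],
                                       calls=calls))
    config = dict(n_types=n_types, cells_per_type=cells_per_type, n_loci=n_loci,
                  frac_csm=frac_csm, depth=depth, seed=seed)
    return SyntheticCells(reads=reads, truth=truth, cell_types=cell_types,
                          type_levels=type_levels, config=config)


def select_hvar_cpgs(site_matrix: pd.DataFrame, n: int) -> pd.DataFrame:
    """Top-n sites by sample-to-sample variance, ties broken by row order."""
    var = site_matrix.var(axis=1, ddof=1)
    if n > len(site_matrix):
        import warnings
        warnings.warn(f"requested {n} sites but only {len(site_matrix)} available")
        n = len(site_matrix)
    order = np.argsort(-var.to_numpy(), kind="stable")[:n]
    return site_matrix.iloc[np.sort(order)]


def rmse(m, m_hat) -> float:
    """Root-mean-square error between true and estimated level vectors."""
    m = np.asarray(m, dtype=float)
    m_hat = np.asarray(m_hat, dtype=float)
    if m.shape != m_hat.shape or m.size == 0:
        raise ValueError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(((m - m_hat) ** 2).sum() / m.size))


def mae(truth: MixtureTruth, estimate: dict[str, float], n_types: int) -> float:
    """Mean absolute proportion error over all reference types.

    ``estimate`` holds proportions for the matched components only; types
    without a matched component count as estimated zero. The denominator is
    the full number of reference types.
    """
    total = 0.0
    for ref, p in truth.proportions.items():
        total += abs(p - estimate.get(ref, 0.0))
    return total / n_types


def evaluate_recovery(result: LmcResult, references: pd.DataFrame,
                      truths: list[MixtureTruth]) -> EvaluationReport:
    """Match LMCs to references, then score profile RMSE and proportion MAE.

    The reported MAE is the mean over samples of the per-sample MAE across
    all reference types.
    """
    W = result.w_frame() if result.loci is not None else pd.DataFrame(result.W)
    refs = references.loc[W.index] if result.loci is not None else references
    assignment = match_lmcs(W, refs)
    rmse_per_pair = {}
    for i, ref in assignment.pairs:
        rmse_per_pair[ref] = rmse(refs[ref].to_numpy(), result.W[:, i])
    n_types = references.shape[1]
    h = result.H
    sample_ids = result.samples or [t.sample_id for t in truths]
    maes = []
    for t in truths:
        s = sample_ids.index(t.sample_id)
        est = {ref: float(h[i, s]) for i, ref in assignment.pairs}
        maes.append(mae(t, est, n_types))
    return EvaluationReport(assignment=assignment, rmse_per_pair=rmse_per_pair,
                            mae=float(np.mean(maes)),
                            n_correct=len(assignment.pairs))
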
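"""Co-methylation network analysis and eigen-locus selection.

pCSM loci are clustered in two steps mirroring weighted co-expression
network practice: a coarse k-means split of loci into hypo/mid/hyper
methylation groups, then — within each group — a signed weighted
network: adjacency ``a_ij = ((1 + cor_ij)/2)^power`` at a soft power
chosen by the scale-free-topology criterion, topological overlap (TOM)
similarity, average-linkage clustering of the TOM dissimilarity, and a
fixed-height tree cut with small-module absorption. Each module is then
summarised by its eigen loci: the members with maximal absolute PC1
loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

__all__ = [
    "MethMatrix",
    "CoMethModule",
    "build_matrix",
    "kmeans_partition",
    "pick_soft_threshold",
    "scale_free_fit",
    "signed_adjacency",
    "tom_similarity",
    "detect_modules",
    "select_eigen_loci",
    "run_comethylation",
]


@dataclass
class MethMatrix:
    """Loci x samples mean-methylation matrix with a missing-value mask.

    ``values`` is complete (missing entries imputed by the locus mean);
    ``missing`` records which entries were imputed.
    """

    values: pd.DataFrame           # loci x samples, float in [0,1]
    missing: pd.DataFrame | None = None

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValueError("MethMatrix values must be complete; impute first")
        if ((v < -1e-9) | (v > 1 + 1e-9)).any():
            raise ValueError("methylation levels must lie in [0,1]")
        if self.missing is None:
            self.missing = pd.DataFrame(False, index=self.values.index,
                                        columns=self.values.columns)

    @property
    def loci(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, loci) -> "MethMatrix":
        return MethMatrix(self.values.loc[loci], self.missing.loc[loci])

    def to_tsv(self, path) -> None:
        out = self.values.mask(self.missing)
        out.to_csv(path, sep="\t", na_rep="NA", index_label="locus")

    @classmethod
    def from_tsv(cls, path, min_samples_covered: int = 1) -> "MethMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
        df.index.name = None
        return build_matrix(df, min_samples_covered=min_samples_covered)


@dataclass
class CoMethModule:
    """A co-methylation module plus its eigen-locus representatives."""

    module_id: int
    members: list[str]
    soft_power: float
    eigen_loci: list[str] = field(default_factory=list)
    pc1_variance_explained: float | None = None


def build_matrix(levels: pd.DataFrame, min_samples_covered: int = 1) -> MethMatrix:
    """Assemble a MethMatrix from per-sample locus levels with NaN gaps.

    Loci observed in fewer than ``min_samples_covered`` samples are dropped;
    remaining gaps are imputed with the locus mean and flagged in the mask.
    """
    covered = levels.notna().sum(axis=1)
    keep = levels.loc[covered >= min_samples_covered]
    if keep.empty:
        raise ValueError("no locus covered in enough samples")
    missing = keep.isna()
    imputed = keep.apply(lambda row: row.fillna(row.mean()), axis=1)
    return MethMatrix(values=imputed.astype(float), missing=missing)


def kmeans_partition(matrix: MethMatrix, k: int = 3, seed: int = 0,
                     max_restarts: int = 10) -> list[MethMatrix]:
    """Split loci into k methylation-level groups, ordered hypo -> hyper."""
    X = matrix.values.to_numpy()
    if k == 1:
        return [matrix]
    for attempt in range(max_restarts):
        km = KMeans(n_clusters=k, random_state=seed + attempt, n_init=10)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) == k:
            break
    else:
        raise RuntimeError("k-means produced an empty cluster in every restart")
    order = np.argsort([X[labels == c].mean() for c in range(k)])
    groups = []
    for c in order:
        loci = matrix.values.index[labels == c]
        groups.append(matrix.subset(loci))
    return groups


def _pairwise_cor(matrix: MethMatrix) -> np.ndarray:
    """Pearson correlation between locus profiles, pairwise-complete on the
    original (pre-imputation) observations."""
    vals = matrix.values.mask(matrix.missing)
    sd = vals.std(axis=1, skipna=True)
    if (sd < 1e-12).any() or sd.isna().any():
        raise ValueError("zero variance loci; drop constant rows first")
    cor = vals.T.corr(min_periods=2).to_numpy()
    # pairs with too few shared samples fall back to zero correlation
    return np.nan_to_num(cor, nan=0.0)


def signed_adjacency(cor: np.ndarray, power: float) -> np.ndarray:
    """Signed network adjacency ((1 + cor)/2)^power; anti-correlated pairs
    get near-zero weight."""
    return ((1.0 + cor) / 2.0) ** power


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free-topology fit of the connectivity distribution.

    Returns (signed R^2, slope) of the regression of log10 p(k) on log10 k
    over connectivity bins; the R^2 is negated when the slope is positive so
    only decreasing degree distributions score high.
    """
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    k = k[k > 0]
    if len(k) < 2 or np.ptp(k) == 0:
        return 0.0, 0.0
    bins = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, bins[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = np.polyval([slope, intercept], xs)
    ss_res = np.sum((np.array(ys) - fitted) ** 2)
    ss_tot = np.sum((np.array(ys) - np.mean(ys)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_threshold(matrix: MethMatrix, powers=range(1, 21),
                        r2_target: float = 0.8) -> int:
    """Smallest power reaching the scale-free R^2 target (else the argmax)."""
    if len(matrix.samples) < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    cor = _pairwise_cor(matrix)
    best_power, best_r2 = None, -np.inf
    for p in powers:
        r2, _ = scale_free_fit(signed_adjacency(cor, p))
        r2 = max(0.0, r2)  # an anti-scale-free fit scores zero, not negative
        if r2 >= r2_target:
            return int(p)
        if r2 > best_r2:
            best_power, best_r2 = int(p), r2
    return best_power


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a (signed) adjacency."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    L = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    tom = (L + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(matrix: MethMatrix, soft_power: float,
                   min_module_size: int = 30,
                   cut_height_frac: float = 0.995,
                   absorb_cor: float = 0.75) -> list[CoMethModule]:
    """Signed-network module detection on TOM dissimilarity.

    Average-linkage tree cut at ``cut_height_frac`` of its height; branches
    below ``min_module_size`` are absorbed into the best-correlated large
    module (module-mean correlation > ``absorb_cor``) or pooled as the
    unassigned module 0.
    """
    cor = _pairwise_cor(matrix)
    adj = signed_adjacency(cor, soft_power)
    diss = 1.0 - tom_similarity(adj)
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    n = diss.shape[0]
    if n == 1:
        return [CoMethModule(1, list(matrix.loci), soft_power)]
    Z = linkage(squareform(diss, checks=False), method="average")
    height = Z[:, 2].max()
    labels = fcluster(Z, t=cut_height_frac * height, criterion="distance")
    loci = np.array(matrix.loci)
    branches = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    big = [b for b in branches if len(b) >= min_module_size]
    small = [b for b in branches if len(b) < min_module_size]
    if not big:  # nothing passes: everything is one unassigned pool
        return [CoMethModule(0, list(loci), soft_power)]
    X = matrix.values.to_numpy()
    big_means = [X[b].mean(axis=0) for b in big]
    assigned = {i: list(b) for i, b in enumerate(big)}
    unassigned: list[int] = []
    for b in small:
        prof = X[b].mean(axis=0)
        cors = [np.corrcoef(prof, m)[0, 1] for m in big_means]
        j = int(np.argmax(cors))
        if cors[j] > absorb_cor:
            assigned[j].extend(b)
        else:
            unassigned.extend(b)
    modules = []
    order = sorted(assigned, key=lambda j: -len(assigned[j]))
    for rank, j in enumerate(order, start=1):
        modules.append(CoMethModule(rank, [loci[i] for i in sorted(assigned[j])],
                                    soft_power))
    if unassigned:
        modules.append(CoMethModule(0, [loci[i] for i in sorted(unassigned)],
                                    soft_power))
    return modules


def select_eigen_loci(module: CoMethModule, matrix: MethMatrix,
                      fraction: float = 0.10) -> list[str]:
    """Pick the module members with maximal |PC1 loading|.

    PCA runs on the centered samples x loci submatrix; PC1's sign is fixed to
    correlate positively with the module mean profile. Modules under 10 loci
    keep all members (flagged by a warning).
    """
    members = module.members
    if len(members) < 10:
        warnings.warn(f"module {module.module_id} has {len(members)} loci; "
                      "all become eigen loci")
        module.eigen_loci = list(members)
        return module.eigen_loci
    sub = matrix.values.loc[members].to_numpy().T  # samples x loci
    centered = sub - sub.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    score = u[:, 0] * s[0]                # PC1 over samples
    loading = vt[0]                       # per-locus loading
    mean_profile = sub.mean(axis=1)
    if np.std(mean_profile) > 0 and np.corrcoef(score, mean_profile)[0, 1] < 0:
        score, loading = -score, -loading
    module.pc1_variance_explained = float(s[0] ** 2 / (s ** 2).sum())
    n_pick = ceil(fraction * len(members))
    order = np.argsort(-np.abs(loading), kind="stable")
    module.eigen_loci = [members[i] for i in sorted(order[:n_pick])]
    return module.eigen_loci


def run_comethylation(matrix: MethMatrix, k: int = 3, fraction: float = 0.10,
                      min_module_size: int = 30, r2_target: float = 0.8,
                      seed: int = 0) -> tuple[list[CoMethModule], list[str]]:
    """k-means split, per-group module detection, eigen-locus selection.

    Returns (modules, union of eigen loci over all assigned modules).
    """
    modules: list[CoMethModule] = []
    eigen: list[str] = []
    next_id = 1
    for group in kmeans_partition(matrix, k=k, seed=seed):
        power = pick_soft_threshold(group, r2_target=r2_target)
        for mod in detect_modules(group, power, min_module_size=min_module_size):
            if mod.module_id == 0:
                mod.module_id = 0
                modules.append(mod)
                continue
            mod.module_id = next_id
            next_id += 1
            select_eigen_loci(mod, group, fraction=fraction)
            eigen.extend(mod.eigen_loci)
            modules.append(mod)
    return modules, eigen
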
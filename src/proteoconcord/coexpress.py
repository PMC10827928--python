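"""Weighted co-expression network analysis of protein abundance matrices.

Implements the standard WGCNA sequence on a proteins x samples log-abundance
matrix: soft-threshold power selection against a scale-free topology target,
(un)signed adjacency, topological overlap (TOM), average-linkage module
detection on TOM dissimilarity, module eigenproteins (first principal
component of each module's standardised profiles), and Pearson module- and
protein-trait correlation with Student-t p-values.

Module detection simplifies the dynamic hybrid tree cut: the dendrogram is
cut at a fixed fraction of its height, undersized clusters fall into module 0
(unassigned/grey), and modules with near-identical eigenproteins are merged
iteratively. Recovery of planted modules, not label-for-label replication of
any published dendrogram, is the supported contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "AbundanceMatrix",
    "SoftThresholdScan",
    "ModuleAssignment",
    "TraitCorrelation",
    "pick_soft_threshold",
    "adjacency",
    "tom",
    "detect_modules",
    "eigenprotein",
    "trait_correlate",
]

MAX_MISSING_FRACTION = 0.3


@dataclass
class AbundanceMatrix:
    """Proteins x samples matrix of log-scale abundances."""

    values: np.ndarray
    protein_keys: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_keys), len(self.sample_ids)):
            raise ValueError("matrix shape does not match key/sample labels")

    def clean(self) -> "AbundanceMatrix":
        """Drop proteins with >30% missing samples or zero variance; mean-impute the rest."""
        vals = self.values
        missing_frac = np.isnan(vals).mean(axis=1)
        keep = missing_frac <= MAX_MISSING_FRACTION
        vals = vals[keep]
        keys = [k for k, m in zip(self.protein_keys, keep) if m]
        if vals.size and np.isnan(vals).any():
            row_means = np.nanmean(vals, axis=1, keepdims=True)
            vals = np.where(np.isnan(vals), row_means, vals)
        var = vals.var(axis=1)
        nonconst = var > 0
        if not nonconst.all():
            warnings.warn(f"dropping {int((~nonconst).sum())} constant protein row(s)")
        vals = vals[nonconst]
        keys = [k for k, m in zip(keys, nonconst) if m]
        dropped = len(self.protein_keys) - len(keys)
        if dropped and dropped != int((~nonconst).sum()):
            warnings.warn(f"dropped {dropped} protein row(s) during cleaning")
        return AbundanceMatrix(vals, keys, list(self.sample_ids))


@dataclass
class SoftThresholdScan:
    powers: list[int]
    r2_signed: list[float]
    mean_connectivity: list[float]
    chosen_power: int
    r2_target: float
    target_reached: bool


@dataclass
class ModuleAssignment:
    """Module label per protein (0 = unassigned), eigenproteins, sizes."""

    labels: np.ndarray
    eigenproteins: np.ndarray  # modules x samples, row m-1 for module m
    module_sizes: dict[int, int] = field(default_factory=dict)

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0


@dataclass
class TraitCorrelation:
    entity: str
    r: float
    p: float

    @property
    def r2(self) -> float:
        return self.r**2


def _pearson_matrix(values: np.ndarray) -> np.ndarray:
    cor = np.corrcoef(values)
    return np.clip(cor, -1.0, 1.0)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index of a connectivity vector.

    Bins k into equal-width bins, regresses log10 bin frequency on log10
    mean bin connectivity, and returns -sign(slope) * R^2 so that a
    decreasing power-law-like degree distribution scores positively.
    """
    k = k[k > 0]
    if k.size < 4 or np.ptp(k) < 1e-12:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-9
    xs, ys = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (k >= lo) & (k < hi)
        cnt = int(sel.sum())
        if cnt == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(cnt / k.size))
    if len(xs) < 3 or np.ptp(xs) < 1e-12:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)


def pick_soft_threshold(
    m: AbundanceMatrix,
    powers: Sequence[int] = tuple(range(1, 21)),
    r2_target: float = 0.8,
) -> SoftThresholdScan:
    """Scan candidate powers for approximate scale-free topology.

    For each power beta, connectivity is k_i = sum_j |cor(i,j)|^beta (j != i);
    the scan reports the signed fit R^2 and mean connectivity, choosing the
    smallest beta whose signed R^2 reaches the target (default 0.8). If no
    power reaches it, the best-fitting power is chosen with a warning.
    """
    n_prot, n_samp = m.values.shape
    if n_prot < 20 or n_samp < 4:
        raise ValueError("need at least 20 proteins and 4 samples")
    cor = np.abs(_pearson_matrix(m.values))
    np.fill_diagonal(cor, 0.0)
    if not np.any(cor > 0):
        raise ValueError("all-constant matrix: correlations undefined")
    r2s, mean_ks = [], []
    for beta in powers:
        k = (cor**beta).sum(axis=1)
        r2s.append(_scale_free_fit(k))
        mean_ks.append(float(k.mean()))
    chosen, reached = None, False
    for beta, r2 in zip(powers, r2s):
        if r2 >= r2_target:
            chosen, reached = beta, True
            break
    if chosen is None:
        chosen = powers[int(np.argmax(r2s))]
        warnings.warn(
            f"no power reached signed R^2 >= {r2_target}; using best fit power {chosen}"
        )
    return SoftThresholdScan(list(powers), r2s, mean_ks, chosen, r2_target, reached)


def adjacency(m: AbundanceMatrix | np.ndarray, beta: int = 4, signed: bool = False) -> np.ndarray:
    """Weighted network adjacency from correlations.

    Unsigned: a_ij = |cor|^beta. Signed: a_ij = ((1 + cor)/2)^beta.
    Diagonal is 1.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    cor = _pearson_matrix(m.values if isinstance(m, AbundanceMatrix) else np.asarray(m, float))
    adj = ((1.0 + cor) / 2.0) ** beta if signed else np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) where
    l_ij = sum_{u not in {i,j}} a_iu * a_uj and k_i = sum_{u != i} a_iu.
    Diagonal is 1; use 1 - TOM as clustering dissimilarity.
    """
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1] or not np.allclose(adj, adj.T, atol=1e-10):
        raise ValueError("adjacency must be a symmetric square matrix")
    a = adj.copy()
    np.fill_diagonal(a, 1.0)
    # (A @ A)_ij includes u=i and u=j terms a_ii*a_ij + a_ij*a_jj = 2*a_ij
    cross = a @ a - 2.0 * a
    k = a.sum(axis=1) - 1.0
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (cross + a) / (kmin + 1.0 - a)
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def eigenprotein(m: AbundanceMatrix, labels: np.ndarray) -> np.ndarray:
    """Module eigenproteins: first right singular vector per module.

    Each module's member rows are z-scored across samples; the unit-norm
    first principal component over samples is sign-anchored so it correlates
    positively with the module's mean standardised profile. Module 0
    (unassigned) gets no eigenprotein; row ``m-1`` holds module ``m``.
    """
    labels = np.asarray(labels)
    modules = sorted(int(x) for x in np.unique(labels) if x > 0)
    out = np.zeros((len(modules), m.values.shape[1]))
    for i, mod in enumerate(modules):
        sub = m.values[labels == mod]
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        v = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(v, mean_profile) < 0:
            v = -v
        out[i] = v
    return out


def _merge_modules(
    m: AbundanceMatrix, labels: np.ndarray, merge_cut_height: float
) -> np.ndarray:
    """Iteratively merge modules whose eigenproteins correlate above 1 - cut."""
    threshold = 1.0 - merge_cut_height
    labels = labels.copy()
    while True:
        modules = sorted(int(x) for x in np.unique(labels) if x > 0)
        if len(modules) < 2:
            break
        eig = eigenprotein(m, labels)
        cor = _pearson_matrix(eig)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] <= threshold:
            break
        labels[labels == modules[j]] = modules[i]
    return labels


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    sizes = {int(x): int((labels == x).sum()) for x in np.unique(labels) if x > 0}
    order = sorted(sizes, key=lambda x: (-sizes[x], x))
    remap = {old: new for new, old in enumerate(order, start=1)}
    out = np.zeros_like(labels)
    for old, new in remap.items():
        out[labels == old] = new
    return out


def detect_modules(
    dissimilarity: np.ndarray,
    m: AbundanceMatrix | None = None,
    min_module_size: int = 20,
    merge_cut_height: float = 0.15,
    cut_fraction: float = 0.995,
) -> ModuleAssignment:
    """Cluster TOM dissimilarity into co-expression modules.

    Average-linkage hierarchical clustering, cut at ``cut_fraction`` of the
    tree height; clusters below ``min_module_size`` become module 0. If the
    abundance matrix is given, modules whose eigenproteins correlate above
    ``1 - merge_cut_height`` are merged iteratively. Labels are renumbered by
    descending size (module 1 is always the largest).
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    n = d.shape[0]
    if n < min_module_size:
        warnings.warn("fewer proteins than min_module_size; all unassigned")
        return ModuleAssignment(np.zeros(n, dtype=int), np.zeros((0, 0)))
    dd = d.copy()
    np.fill_diagonal(dd, 0.0)
    z = linkage(squareform(dd, checks=False), method="average")
    height = z[:, 2].max()
    raw = fcluster(z, t=cut_fraction * height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    nxt = 1
    for c in np.unique(raw):
        sel = raw == c
        if sel.sum() >= min_module_size:
            labels[sel] = nxt
            nxt += 1
    if m is not None and labels.max() > 1:
        labels = _merge_modules(m, labels, merge_cut_height)
    labels = _renumber_by_size(labels)
    if m is not None and labels.max() > 0:
        eig = eigenprotein(m, labels)
    else:
        eig = np.zeros((0, m.values.shape[1] if m is not None else 0))
    sizes = {int(x): int((labels == x).sum()) for x in np.unique(labels) if x > 0}
    return ModuleAssignment(labels, eig, sizes)


def trait_correlate(
    profiles: np.ndarray, trait: np.ndarray, names: Sequence[str] | None = None
) -> list[TraitCorrelation]:
    """Pearson correlation of each profile row with a per-sample trait.

    p-values are two-sided from t = r*sqrt((n-2)/(1-r^2)) on n-2 df.
    Constant profiles have undefined r and are reported as NaN with a warning.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    trait = np.asarray(trait, dtype=float)
    n = trait.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    if np.std(trait) == 0:
        raise ValueError("trait is constant")
    if profiles.shape[1] != n:
        raise ValueError("profiles and trait have different sample counts")
    names = list(names) if names is not None else [f"profile_{i+1}" for i in range(profiles.shape[0])]
    out: list[TraitCorrelation] = []
    for name, row in zip(names, profiles):
        if np.std(row) == 0:
            warnings.warn(f"{name}: constant profile, correlation undefined")
            out.append(TraitCorrelation(name, float("nan"), float("nan")))
            continue
        r = float(np.corrcoef(row, trait)[0, 1])
        r = max(-1.0, min(1.0, r))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
        out.append(TraitCorrelation(name, r, p))
    return out
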
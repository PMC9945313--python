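"""Alpha diversity, beta-diversity distances, PCoA, PERMANOVA, betadisper.

UniFrac is computed by a single postorder pass accumulating, per branch, the
set (or read fraction) of descendant taxa in each sample; the root has no
branch and contributes nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import CountTable, PhyloTree

__all__ = [
    "AlphaDiversityResult",
    "DistanceMatrix",
    "PermanovaResult",
    "DispersionResult",
    "chao1",
    "shannon_ens",
    "inv_simpson",
    "alpha_diversity",
    "bray_curtis",
    "unweighted_unifrac",
    "weighted_unifrac",
    "beta_diversity",
    "pcoa",
    "permanova",
    "betadisper",
]


# ---------------------------------------------------------------------------
# alpha

def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1*(F1-1) / (2*(F2+1))."""
    counts = _check_counts(counts)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon_ens(counts) -> float:
    """Effective number of taxa exp(H) with H the Shannon entropy (nats)."""
    counts = _check_counts(counts, integral=False)
    p = counts[counts > 0] / counts.sum()
    return float(np.exp(-(p * np.log(p)).sum()))


def inv_simpson(counts) -> float:
    """Inverse Simpson concentration 1 / sum(p_i^2)."""
    counts = _check_counts(counts, integral=False)
    p = counts[counts > 0] / counts.sum()
    return float(1.0 / (p ** 2).sum())


def _check_counts(counts, integral: bool = True) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector of per-taxon counts")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if arr.sum() == 0:
        raise ValueError("all-zero sample has no diversity")
    if integral and not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    return arr


@dataclass
class AlphaDiversityResult:
    """Per-sample alpha diversity at a given taxonomic rank."""

    frame: pd.DataFrame  # index sample_id; columns chao1, shannon_ens, inv_simpson
    rank: str | None = None


def alpha_diversity(table: CountTable, rank: str | None = None) -> AlphaDiversityResult:
    """Chao1 / Shannon ENS / Inverse Simpson per sample.

    If ``rank`` is given, counts are agglomerated to that rank first.
    """
    if rank is not None:
        from .io_model import lineage_at_rank
        glom = [lineage_at_rank(lin, rank) for lin in table.lineages]
        counts = (pd.DataFrame(table.counts, index=glom, columns=table.sample_ids)
                  .groupby(level=0, sort=False).sum().to_numpy())
    else:
        counts = table.counts
    rows = {}
    for j, sid in enumerate(table.sample_ids):
        col = counts[:, j]
        rows[sid] = {"chao1": chao1(col), "shannon_ens": shannon_ens(col),
                     "inv_simpson": inv_simpson(col)}
    return AlphaDiversityResult(pd.DataFrame.from_dict(rows, orient="index"), rank)


# ---------------------------------------------------------------------------
# beta

@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must share a taxon index")
    total = (x + y).sum()
    if total == 0:
        raise ValueError("both samples are all-zero")
    return float(np.abs(x - y).sum() / total)


def _branch_arrays(tree: PhyloTree, taxon_ids: list[str]):
    """Branch lengths and per-branch descendant-taxon indicator matrix.

    Returns (lengths, membership) where membership[b, i] is True when taxon i
    descends through branch b. Branches of length None count as 0.
    """
    index = {t: i for i, t in enumerate(taxon_ids)}
    tree.require_leaves(taxon_ids)
    nodes = [n for n in tree.tree.postorder(include_self=False)]
    lengths = np.array([(n.length or 0.0) for n in nodes], dtype=float)
    membership = np.zeros((len(nodes), len(taxon_ids)), dtype=bool)
    masks: dict[int, np.ndarray] = {}
    for b, node in enumerate(nodes):
        if node.is_tip():
            mask = np.zeros(len(taxon_ids), dtype=bool)
            if node.name in index:
                mask[index[node.name]] = True
        else:
            mask = np.zeros(len(taxon_ids), dtype=bool)
            for child in node.children:
                mask |= masks[id(child)]
        masks[id(node)] = mask
        membership[b] = mask
    return lengths, membership


def unweighted_unifrac(x, y, tree: PhyloTree, taxon_ids: list[str]) -> float:
    """Fraction of branch length unique to one of the two communities."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lengths, member = _branch_arrays(tree, taxon_ids)
    in_x = member @ (x > 0)
    in_y = member @ (y > 0)
    has_x = in_x > 0
    has_y = in_y > 0
    union = lengths[has_x | has_y].sum()
    if union == 0:
        return 0.0
    unique = lengths[has_x ^ has_y].sum()
    return float(unique / union)


def weighted_unifrac(x, y, tree: PhyloTree, taxon_ids: list[str],
                     normalized: bool = True) -> float:
    """Abundance-weighted UniFrac; normalized mode scales into [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("weighted UniFrac undefined for a zero-total sample")
    lengths, member = _branch_arrays(tree, taxon_ids)
    px = member @ (x / x.sum())
    py = member @ (y / y.sum())
    raw = float((lengths * np.abs(px - py)).sum())
    if not normalized:
        return raw
    denom = float((lengths * (px + py)).sum())
    if denom == 0:
        return 0.0
    return raw / denom


def beta_diversity(table: CountTable, metric: str, tree: PhyloTree | None = None,
                   normalized: bool = True) -> DistanceMatrix:
    """All-pairs distance matrix for one of bray_curtis / unifrac / weighted_unifrac."""
    n = len(table.sample_ids)
    d = np.zeros((n, n))
    cols = table.counts.T.astype(float)
    if metric == "bray_curtis":
        for j in range(n):
            for k in range(j + 1, n):
                d[j, k] = d[k, j] = bray_curtis(cols[j], cols[k])
    elif metric in ("unifrac", "weighted_unifrac"):
        if tree is None:
            raise ValueError(f"{metric} requires a tree")
        lengths, member = _branch_arrays(tree, table.taxon_ids)
        if metric == "unifrac":
            present = (member @ (cols.T > 0)) > 0  # branches x samples
            for j in range(n):
                for k in range(j + 1, n):
                    has = present[:, j] | present[:, k]
                    union = lengths[has].sum()
                    uniq = lengths[present[:, j] ^ present[:, k]].sum()
                    d[j, k] = d[k, j] = uniq / union if union else 0.0
        else:
            totals = cols.sum(axis=1)
            if (totals == 0).any():
                raise ValueError("weighted UniFrac undefined for a zero-total sample")
            props = member @ (cols / totals[:, None]).T  # branches x samples
            for j in range(n):
                for k in range(j + 1, n):
                    raw = (lengths * np.abs(props[:, j] - props[:, k])).sum()
                    if normalized:
                        denom = (lengths * (props[:, j] + props[:, k])).sum()
                        raw = raw / denom if denom else 0.0
                    d[j, k] = d[k, j] = raw
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(list(table.sample_ids), d, metric)


# ---------------------------------------------------------------------------
# ordination and tests

@dataclass
class PcoaResult:
    coordinates: pd.DataFrame   # samples x kept axes (positive eigenvalues)
    eigenvalues: np.ndarray     # all eigenvalues, descending
    axes_full: np.ndarray       # samples x all axes, scaled by sqrt(|eigenvalue|)


def pcoa(D: DistanceMatrix) -> PcoaResult:
    """Classical metric multidimensional scaling by double centering.

    Axes with negative eigenvalues are reported in ``eigenvalues`` and kept in
    ``axes_full`` (scaled by sqrt(|eigenvalue|)) but dropped from
    ``coordinates``.
    """
    d2 = D.values ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    axes_full = eigvecs * np.sqrt(np.abs(eigvals))[None, :]
    pos = eigvals > 1e-10 * max(abs(eigvals[0]), 1.0)
    coords = pd.DataFrame(axes_full[:, pos], index=D.sample_ids,
                          columns=[f"PCo{i + 1}" for i in range(int(pos.sum()))])
    return PcoaResult(coords, eigvals, axes_full)


@dataclass
class PermanovaResult:
    variable: str
    r2: float
    f: float
    p: float
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "variable": self.variable, "R2": self.r2, "F": self.f, "p": self.p,
            "n_perm": self.n_permutations, "seed": self.seed}])


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size == 0:
            raise ValueError("empty group in PERMANOVA")
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_total, ss_within


def permanova(D: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0,
              variable: str = "group") -> PermanovaResult:
    """One-factor PERMANOVA: distance sums of squares partitioned by group.

    F = (SS_between/(a-1)) / (SS_within/(N-a)); p by free label permutation
    with the (1 + #{F_perm >= F_obs}) / (1 + n_perm) convention.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(D.sample_ids):
        raise ValueError("one label per sample required")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("PERMANOVA needs >=2 groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(D.sample_ids)
    d2 = D.values ** 2

    ss_total, ss_within = _permanova_ss(d2, codes, a)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        sst, ssw = _permanova_ss(d2, perm, a)
        f_perm = ((sst - ssw) / (a - 1)) / (ssw / (n - a))
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(variable, float(r2), float(f_obs), float(p), n_perm, seed)


@dataclass
class DispersionResult:
    distances: pd.Series        # per sample distance to its group centroid
    group_means: pd.Series
    f: float
    p: float
    n_permutations: int
    seed: int


def _centroid_distances(axes: np.ndarray, eig_sign: np.ndarray,
                        codes: np.ndarray) -> np.ndarray:
    """Distance to group centroid in PCoA space, subtracting the squared
    contribution of negative-eigenvalue (imaginary) axes and clipping at 0."""
    dist2 = np.zeros(axes.shape[0])
    for g in np.unique(codes):
        idx = np.flatnonzero(codes == g)
        centroid = axes[idx].mean(axis=0)
        delta2 = (axes[idx] - centroid) ** 2
        dist2[idx] = delta2 @ eig_sign
    return np.sqrt(np.clip(dist2, 0.0, None))


def betadisper(D: DistanceMatrix, labels, n_perm: int = 999,
               seed: int = 0) -> DispersionResult:
    """Homogeneity of multivariate dispersion via distances to group centroids.

    Samples are embedded by PCoA keeping negative-eigenvalue axes (their
    squared contribution is subtracted). A one-way F on the distances is
    evaluated against label permutations. Singleton groups get a distance of
    zero but are excluded from the F statistic (warned).
    """
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("betadisper needs >=2 groups")
    res = pcoa(D)
    eig_sign = np.sign(res.eigenvalues)
    eig_sign[np.abs(res.eigenvalues) < 1e-10 * max(abs(res.eigenvalues[0]), 1.0)] = 0.0

    dists = _centroid_distances(res.axes_full, eig_sign, codes)

    sizes = np.bincount(codes)
    if (sizes == 1).any():
        warnings.warn("singleton group(s) excluded from the dispersion F test")

    def one_way_f(values: np.ndarray, codes: np.ndarray) -> float:
        keep_groups = np.flatnonzero(np.bincount(codes) >= 2)
        mask = np.isin(codes, keep_groups)
        v, c = values[mask], codes[mask]
        groups = np.unique(c)
        grand = v.mean()
        ss_b = sum((v[c == g].mean() - grand) ** 2 * (c == g).sum() for g in groups)
        ss_w = sum(((v[c == g] - v[c == g].mean()) ** 2).sum() for g in groups)
        df_b = len(groups) - 1
        df_w = len(v) - len(groups)
        if df_b == 0 or df_w == 0:
            return 0.0
        if ss_w == 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / df_b) / (ss_w / df_w)

    f_obs = one_way_f(dists, codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        d_perm = _centroid_distances(res.axes_full, eig_sign, perm)
        if one_way_f(d_perm, perm) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)

    dist_series = pd.Series(dists, index=D.sample_ids)
    means = pd.Series({u: dists[codes == g].mean() for g, u in enumerate(uniq)})
    return DispersionResult(dist_series, means, float(f_obs), float(p), n_perm, seed)
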
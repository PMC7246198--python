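"""Signed weighted-correlation network construction and module detection.

Compounds whose abundances covary across plants form "modules".  The
workflow follows the weighted gene co-expression approach adapted to
metabolomic features:

1. Pearson correlation of z-scored abundances across plants.
2. Signed soft-thresholded adjacency ``a_ij = ((1 + r_ij)/2) ** beta`` so
   negatively correlated compounds are maximally dissimilar; the power
   beta (default 5) is where the scale-free topology index plateaus.
3. Topological overlap (TOM) similarity, which rewards shared neighbors
   and denoises the adjacency; ``1 - TOM`` is the clustering dissimilarity.
4. Average-linkage hierarchical clustering with a static tree cut
   (clusters below ``min_module_size`` fall into module 0, "unassigned").
5. Modules whose first eigenvectors correlate above
   ``1 - merge_cut_height`` are fused, eigenvectors recomputed.
6. A second clustering round on the unassigned leftovers can rescue
   blocks orphaned by the first cut.

Each module is summarized by its first eigenvector: the first
principal-component score of the z-scored member columns, scaled to unit
sample sd and sign-aligned so that its mean correlation with member
compounds is nonnegative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data_model import CompoundMatrix, z_transform

__all__ = [
    "NetworkParams",
    "ModuleSolution",
    "signed_adjacency",
    "scale_free_r2",
    "scale_free_fit",
    "tom_dissimilarity",
    "detect_modules",
    "module_eigenvector",
    "merge_modules",
    "second_round",
    "find_modules",
    "export_network",
]


@dataclass
class NetworkParams:
    """Tuning knobs of the network/clustering stage."""

    power: float = 5.0
    merge_cut_height: float = 0.25
    min_module_size: int = 5
    use_topological_overlap: bool = True
    # static cut considers merge heights up to this absolute 1-TOM height;
    # chance clusters of uncorrelated compounds complete above ~0.85 at
    # these sample sizes, so the default leaves structureless data
    # essentially entirely unassigned while real modules form well below
    static_cut_height: float = 0.85
    run_second_round: bool = True

    def __post_init__(self):
        if self.power < 1:
            raise ValueError("soft-threshold power must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must be in (0, 1)")


@dataclass
class ModuleSolution:
    """Compound -> module assignment (0 = unassigned) plus eigenvectors."""

    assignment: pd.Series  # compound id -> module index
    eigenvectors: pd.DataFrame  # plants x modules, columns "m1", "m2", ...
    round_of_assignment: pd.Series  # 1 or 2 per assigned compound, 0 if unassigned

    @property
    def module_sizes(self) -> pd.Series:
        assigned = self.assignment[self.assignment > 0]
        return assigned.value_counts().sort_index()

    @property
    def n_modules(self) -> int:
        return int((self.assignment.max()) if len(self.assignment) else 0)


def _check_cor(cor: np.ndarray) -> np.ndarray:
    cor = np.asarray(cor, dtype=float)
    if cor.ndim != 2 or cor.shape[0] != cor.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(cor, cor.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if np.any(cor < -1 - 1e-8) or np.any(cor > 1 + 1e-8):
        raise ValueError("correlation entries must lie in [-1, 1]")
    return np.clip(cor, -1.0, 1.0)


def signed_adjacency(cor, power: float = 5.0) -> np.ndarray:
    """Signed soft-threshold adjacency ``((1 + r) / 2) ** power``.

    Maps r = 1 to 1, r = 0 to 2**-power, and r = -1 to 0, so anticorrelated
    compounds never share an edge.  Monotone increasing in r.
    """
    cor = _check_cor(np.asarray(cor, dtype=float))
    adj = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def scale_free_r2(connectivity, n_bins: int = 10) -> float:
    """Scale-free topology index of a connectivity vector.

    R-squared of the regression of log10 frequency on log10 mean
    connectivity over equal-width connectivity bins.  Returns NaN when the
    connectivity is degenerate (all values equal, or fewer than two
    occupied bins).
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[np.isfinite(k) & (k > 0)]
    if len(k) < 3 or np.ptp(k) < 1e-12:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    logk, logp = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        km = k[mask].mean()
        if km <= 0:
            continue
        logk.append(np.log10(km))
        logp.append(np.log10(mask.sum() / len(k)))
    if len(logk) < 3:
        return float("nan")
    logk, logp = np.asarray(logk), np.asarray(logp)
    r = np.corrcoef(logk, logp)[0, 1]
    return float(r**2)


def scale_free_fit(cor, powers: Iterable[float], tol: float = 0.05) -> pd.DataFrame:
    """Scan soft-threshold powers and report fit index and mean connectivity.

    Returns a table (power, r_squared, mean_connectivity) with a boolean
    ``plateau`` column marking the smallest power whose R^2 comes within
    ``tol`` of the maximum over the grid — the "plateau" used to pick beta.
    """
    powers = list(powers)
    if len(powers) < 2:
        raise ValueError("need a grid of at least 2 powers")
    cor = _check_cor(np.asarray(cor, dtype=float))
    rows = []
    for b in powers:
        adj = signed_adjacency(cor, b)
        k = adj.sum(axis=1) - 1.0
        rows.append((b, scale_free_r2(k), float(k.mean())))
    out = pd.DataFrame(rows, columns=["power", "r_squared", "mean_connectivity"])
    out["plateau"] = False
    valid = out["r_squared"].dropna()
    if len(valid):
        best = valid.max()
        hit = out.index[(out["r_squared"] >= best - tol).fillna(False)]
        out.loc[hit[0], "plateau"] = True
    return out


def tom_dissimilarity(adjacency) -> np.ndarray:
    """Topological-overlap dissimilarity ``1 - TOM``.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` where
    ``l_ij = sum_u a_iu a_uj`` over u != i, j and ``k_i`` is node i's
    connectivity.  High overlap means i and j share their neighborhoods,
    not merely each other.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    return dissim


def detect_modules(dissimilarity, params: NetworkParams) -> np.ndarray:
    """Average-linkage clustering with a static cut; returns labels, 0 = unassigned.

    The cut height is chosen to maximize the number of clusters of at
    least ``min_module_size`` members, searching merge heights up to the
    absolute ceiling ``static_cut_height`` (ties go to the larger height,
    i.e. the most complete clusters).  Clusters below the minimum size are
    left unassigned.  Deterministic given its inputs.
    """
    d = np.asarray(dissimilarity, dtype=float)
    p = d.shape[0]
    if p < params.min_module_size:
        warnings.warn("fewer compounds than min_module_size; all unassigned")
        return np.zeros(p, dtype=int)
    if p < 2:
        return np.zeros(p, dtype=int)
    Z = linkage(squareform(d, checks=False), method="average")
    heights = np.unique(Z[:, 2])
    candidates = heights[heights <= params.static_cut_height + 1e-12]
    if len(candidates) == 0:
        warnings.warn("no merges below the static cut height; all compounds unassigned")
        return np.zeros(p, dtype=int)
    best_labels, best_count, best_h = np.zeros(p, dtype=int), 0, -np.inf
    for h in candidates:
        raw = fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(raw)
        keep = {c for c in range(len(sizes)) if sizes[c] >= params.min_module_size}
        count = len(keep)
        if count > best_count or (count == best_count and h > best_h and count > 0):
            labels = np.array([c if c in keep else 0 for c in raw])
            # renumber by decreasing size
            kept = sorted(keep, key=lambda c: (-sizes[c], c))
            remap = {c: i + 1 for i, c in enumerate(kept)}
            best_labels = np.array([remap.get(c, 0) for c in labels])
            best_count, best_h = count, h
    if best_count == 0:
        warnings.warn("no cluster reached min_module_size; all compounds unassigned")
    return best_labels


def module_eigenvector(values: pd.DataFrame | np.ndarray) -> np.ndarray:
    """First principal-component score of z-scored member columns.

    Scaled to unit sample sd and sign-aligned so the mean correlation with
    the member compounds is nonnegative.  A single-compound module reduces
    to the compound's z-scored column.
    """
    vals = values.to_numpy(dtype=float) if hasattr(values, "to_numpy") else np.asarray(values, dtype=float)
    if vals.ndim == 1:
        vals = vals[:, None]
    n, m = vals.shape
    if m < 1:
        raise ValueError("module must contain at least one compound")
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0  # constant member carries no signal
    z = (vals - mean) / sd
    if m == 1:
        score = z[:, 0]
    else:
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        score = u[:, 0] * s[0]
    ssd = score.std(ddof=1)
    if ssd > 0:
        score = score / ssd
    mean_cor = np.mean([np.corrcoef(score, z[:, j])[0, 1] for j in range(m)])
    if mean_cor < 0:
        score = -score
    return score


def _eigenvector_table(z: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    cols = {}
    for m in sorted(set(assignment) - {0}):
        members = assignment.index[assignment == m]
        cols[f"m{m}"] = module_eigenvector(z[members])
    return pd.DataFrame(cols, index=z.index)


def merge_modules(
    z: pd.DataFrame, assignment: pd.Series, merge_cut_height: float = 0.25
) -> pd.Series:
    """Iteratively fuse modules whose eigenvectors nearly coincide.

    Two modules merge when their eigenvector dissimilarity ``1 - cor`` is
    below ``merge_cut_height`` (0.25 means fuse when correlation > 0.75).
    Eigenvectors are recomputed after every merge until no pair qualifies.
    Returns the relabeled assignment (modules numbered by decreasing size).
    """
    assignment = assignment.copy()
    while True:
        labels = sorted(set(assignment) - {0})
        if len(labels) < 2:
            break
        eig = _eigenvector_table(z, assignment)
        cor = np.corrcoef(eig.to_numpy(), rowvar=False)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= merge_cut_height:
            break
        keep, drop = labels[min(i, j)], labels[max(i, j)]
        assignment[assignment == drop] = keep
    return _relabel_by_size(assignment)


def _relabel_by_size(assignment: pd.Series) -> pd.Series:
    sizes = assignment[assignment > 0].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    remap = {m: i + 1 for i, m in enumerate(order)}
    remap[0] = 0
    return assignment.map(remap)


def second_round(
    z: pd.DataFrame, assignment: pd.Series, params: NetworkParams
) -> tuple[pd.Series, pd.Series]:
    """Re-cluster the unassigned leftovers; append any new modules.

    Returns ``(assignment, round_of_assignment)``.  With fewer than two
    leftovers this is a no-op.
    """
    round_of = pd.Series(
        np.where(assignment > 0, 1, 0), index=assignment.index, dtype=int
    )
    leftovers = assignment.index[assignment == 0]
    if len(leftovers) < 2:
        return assignment, round_of
    sub = z[leftovers]
    cor = np.corrcoef(sub.to_numpy(), rowvar=False)
    adj = signed_adjacency(cor, params.power)
    dis = tom_dissimilarity(adj) if params.use_topological_overlap else 1.0 - adj
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = detect_modules(dis, params)
    sub_assign = pd.Series(labels, index=leftovers)
    if (sub_assign > 0).any():
        sub_assign = merge_modules(sub, sub_assign, params.merge_cut_height)
    offset = int(assignment.max())
    out = assignment.copy()
    newly = sub_assign.index[sub_assign > 0]
    out.loc[newly] = sub_assign.loc[newly] + offset
    round_of.loc[newly] = 2
    return out, round_of


def find_modules(cm: CompoundMatrix, params: Optional[NetworkParams] = None) -> ModuleSolution:
    """Full module-detection pipeline on a compound matrix.

    z-scores, builds the signed TOM network, clusters, merges near-duplicate
    modules, runs the optional second round on leftovers, and returns the
    final assignment with per-plant module eigenvectors.
    """
    params = params or NetworkParams()
    z = cm.zscores()
    cor = np.corrcoef(z.to_numpy(), rowvar=False)
    adj = signed_adjacency(cor, params.power)
    dis = tom_dissimilarity(adj) if params.use_topological_overlap else 1.0 - adj
    labels = detect_modules(dis, params)
    assignment = pd.Series(labels, index=z.columns, name="module")
    if (assignment > 0).any():
        assignment = merge_modules(z, assignment, params.merge_cut_height)
    if params.run_second_round:
        assignment, round_of = second_round(z, assignment, params)
    else:
        round_of = pd.Series(
            np.where(assignment > 0, 1, 0), index=assignment.index, dtype=int
        )
    eig = _eigenvector_table(z, assignment)
    return ModuleSolution(assignment=assignment, eigenvectors=eig, round_of_assignment=round_of)


def export_network(
    cor,
    solution: ModuleSolution,
    class_of: Optional[pd.Series] = None,
    primary_threshold: float = 0.5,
    weak_threshold: float = 0.1,
    weak_modules: Optional[set] = None,
) -> tuple[pd.DataFrame, nx.Graph]:
    """Edge list + graph of the compound correlation network.

    Edges connect pairs with r >= ``primary_threshold``; pairs whose two
    endpoints both belong to ``weak_modules`` (modules whose internal
    correlations are weaker) are kept down to ``weak_threshold``.  Node
    attributes carry the module index and the compound class code.
    """
    for t in (primary_threshold, weak_threshold):
        if not 0 < t < 1:
            raise ValueError("thresholds must be in (0, 1)")
    cor = _check_cor(np.asarray(cor, dtype=float))
    ids = list(solution.assignment.index)
    weak_modules = weak_modules or set()
    G = nx.Graph()
    for cid in ids:
        G.add_node(
            cid,
            module=int(solution.assignment[cid]),
            compound_class=str(class_of[cid]) if class_of is not None else "",
        )
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = cor[i, j]
            mi, mj = solution.assignment.iloc[i], solution.assignment.iloc[j]
            keep = r >= primary_threshold or (
                r > weak_threshold and mi in weak_modules and mj in weak_modules
            )
            if keep:
                rows.append((ids[i], ids[j], float(r)))
                G.add_edge(ids[i], ids[j], weight=float(r))
    edges = pd.DataFrame(rows, columns=["source", "target", "r"])
    return edges, G
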
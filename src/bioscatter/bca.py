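"""Recursive PCA-based divisive clustering of QVP cells (the BCA).

Every complete (time, height) cell of a QVP series is a point in the
five-dimensional space (Z_H, Z_V, Z_DR, RHO_HV, K_DP).  Starting from
one root cluster, each current leaf is considered for splitting:

* **inner loop** — the leaf's points are locally re-standardized and
  projected onto the principal components that retain a configured
  fraction of local variance; centre-based partitions are fitted for
  k = 1..k_max and a compactness curve C(k) (mean Euclidean distance of
  points to their barycentre) is recorded.  The normalized curve
  rho(k) = C(k)/C(1) determines the proposal: the smallest k >= 2 whose
  marginal compactness gain rho(k) - rho(k+1) falls below an elbow
  threshold.  If even a two-way split buys too little compactness
  (rho(2) above a rejection ceiling) the leaf proposes no split.

* **outer loop** — a proposed split is committed only if the posterior
  probability of the whole clustering remains high: one full-covariance
  Gaussian is fitted per leaf in the global standardized space, with
  mixture weight equal to the leaf fraction, and the mean (over all
  points) maximum posterior membership probability must stay at or
  above ``max(posterior_min, previous score - posterior_drop_tol)``.

Recursion stops at no-split proposals, at leaves smaller than ``n_min``
or at ``max_depth``.  With a fixed seed the procedure is deterministic:
the same input always yields the same tree and labels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.linalg import solve_triangular
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from bioscatter.qvp import QVPSeries
from bioscatter.radar_io import VARIABLES

log = logging.getLogger(__name__)

#: Sentinel label for masked / incomplete cells in a label grid.
UNCLASSIFIED = -1


@dataclass
class FeatureTable:
    """Complete QVP cells as a standardized cells x 5 matrix.

    ``X`` holds z-scores; ``raw`` the native-unit values; ``cell_index``
    the (time index, height index) coordinate of each row; ``scaler``
    the global per-variable (mean, std) used for standardization.
    """

    cell_index: np.ndarray  # (n, 2) int: (time_idx, height_idx)
    X: np.ndarray  # (n, 5) standardized
    raw: np.ndarray  # (n, 5) native units
    scaler: tuple  # (means (5,), stds (5,))
    heights_m: np.ndarray | None = None  # per-row cell height, metres
    times: np.ndarray | None = None

    @property
    def n(self):
        return self.X.shape[0]


@dataclass(frozen=True)
class BCAConfig:
    """Tunable parameters of the classification algorithm."""

    k_max: int = 6
    variance_retained: float = 0.95
    elbow_epsilon: float = 0.05
    split_reject_rho: float = 0.90
    posterior_min: float = 0.80
    posterior_drop_tol: float = 0.01
    n_min: int = 50
    max_depth: int = 6
    n_init: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.variance_retained <= 1.0):
            raise ValueError("variance_retained must lie in (0, 1]")
        if not (0.0 < self.posterior_min <= 1.0):
            raise ValueError("posterior_min must lie in (0, 1]")
        if self.k_max < 2:
            raise ValueError("k_max must be at least 2")
        if self.n_min < 2 * self.k_max:
            raise ValueError("n_min must be at least 2 * k_max")


@dataclass
class ClusterNode:
    """One node of the divisive tree."""

    node_id: int
    parent_id: int | None
    member_cells: np.ndarray  # row indices into the FeatureTable
    depth: int = 0
    children: list = field(default_factory=list)
    pca_loadings: np.ndarray | None = None
    compactness_curve: dict | None = None  # k -> C(k)
    chosen_k: int | None = None
    posterior_score: float | None = None

    @property
    def is_leaf(self):
        return not self.children


@dataclass
class ClusterTree:
    """The full splitting record plus the final leaf set."""

    root: ClusterNode
    nodes: dict  # node_id -> ClusterNode
    config: BCAConfig

    @property
    def leaves(self):
        return [n for n in self.nodes.values() if n.is_leaf]

    def to_json(self, path=None) -> str:
        def node_dict(n):
            return {
                "node_id": n.node_id,
                "parent_id": n.parent_id,
                "depth": n.depth,
                "n_members": int(n.member_cells.size),
                "children": [c.node_id for c in n.children],
                "chosen_k": n.chosen_k,
                "posterior_score": n.posterior_score,
                "compactness_curve": (
                    {str(k): float(v) for k, v in n.compactness_curve.items()}
                    if n.compactness_curve
                    else None
                ),
            }

        payload = {
            "config": asdict(self.config),
            "nodes": [node_dict(n) for n in self.nodes.values()],
            "leaves": [n.node_id for n in self.leaves],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class Labeling:
    """Per-cell leaf assignment."""

    labels: np.ndarray  # (n,) leaf node ids, aligned with the FeatureTable
    leaf_ids: tuple

    def members(self, leaf_id) -> np.ndarray:
        return np.flatnonzero(self.labels == leaf_id)


# -- feature construction --------------------------------------------------

def build_features(series: QVPSeries, n_min: int = 50) -> FeatureTable:
    """Stack the complete cells of a series into a standardized matrix.

    A cell is retained only if all five variables are unmasked there;
    the z-score scaler is computed over the retained cells.
    """
    missing = [v for v in VARIABLES if v not in series.grids]
    if missing:
        raise ValueError(f"series lacks required variable(s): {missing}")
    masks = [np.ma.getmaskarray(series.grids[v]) for v in VARIABLES]
    complete = ~np.logical_or.reduce(masks)
    idx = np.argwhere(complete)
    if idx.shape[0] < n_min:
        raise ValueError(
            f"only {idx.shape[0]} complete cells; at least {n_min} required"
        )
    raw = np.column_stack(
        [np.ma.getdata(series.grids[v])[complete] for v in VARIABLES]
    ).astype(float)
    means = raw.mean(axis=0)
    stds = raw.std(axis=0, ddof=0)
    if np.any(stds == 0):
        flat = [VARIABLES[i] for i in np.flatnonzero(stds == 0)]
        raise ValueError(f"variable(s) constant across all cells: {flat}")
    X = (raw - means) / stds
    heights = series.heights_m[idx[:, 1]]
    times = series.times[idx[:, 0]]
    return FeatureTable(
        cell_index=idx, X=X, raw=raw, scaler=(means, stds),
        heights_m=heights, times=times,
    )


# -- inner loop ------------------------------------------------------------

def _compactness(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean Euclidean distance of points to their cluster barycentre."""
    total = 0.0
    for lab in np.unique(labels):
        sub = points[labels == lab]
        total += np.linalg.norm(sub - sub.mean(axis=0), axis=1).sum()
    return total / points.shape[0]


def propose_split(subset: np.ndarray, config: BCAConfig, seed: int | None = None):
    """Inner loop: propose a k-way partition of one leaf's points.

    ``subset`` is the leaf's (m, d) standardized matrix.  Returns
    ``(chosen_k, partition, compactness_curve, pca_loadings)`` where
    ``partition`` is an (m,) label vector (all zeros when chosen_k = 1).
    """
    m = subset.shape[0]
    if m < config.n_min:
        raise ValueError(f"subset of {m} points is below n_min = {config.n_min}")
    seed = config.seed if seed is None else seed

    # local re-standardization; constant local dimensions carry no signal
    mu = subset.mean(axis=0)
    sd = subset.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (subset - mu) / sd

    n_comp = _n_components(Z, config.variance_retained)
    pca = PCA(n_components=n_comp, svd_solver="full")
    Y = pca.fit_transform(Z)

    curve = {1: _compactness(Y, np.zeros(m, dtype=int))}
    partitions = {1: np.zeros(m, dtype=int)}
    for k in range(2, config.k_max + 1):
        km = KMeans(n_clusters=k, n_init=config.n_init, random_state=seed)
        labels = km.fit_predict(Y)
        curve[k] = _compactness(Y, labels)
        partitions[k] = labels

    rho = {k: curve[k] / curve[1] for k in curve} if curve[1] > 0 else {
        k: 0.0 for k in curve
    }
    if curve[1] == 0 or rho[2] > config.split_reject_rho:
        return 1, partitions[1], curve, pca.components_

    chosen = config.k_max
    for k in range(2, config.k_max + 1):
        rho_next = rho.get(k + 1, rho[config.k_max])
        if rho[k] - rho_next < config.elbow_epsilon:
            chosen = k
            break
    return chosen, partitions[chosen], curve, pca.components_


def _n_components(Z: np.ndarray, variance_retained: float) -> int:
    """Smallest component count retaining the target variance (min 2)."""
    d = Z.shape[1]
    var = np.linalg.svd(Z - Z.mean(axis=0), compute_uv=False) ** 2
    total = var.sum()
    if total == 0:
        return min(2, d)
    frac = np.cumsum(var) / total
    n = int(np.searchsorted(frac, variance_retained - 1e-12) + 1)
    return min(d, max(2, n))


# -- outer loop ------------------------------------------------------------

def evaluate_clustering(X: np.ndarray, leaf_members) -> float:
    """Mean maximum posterior membership over all points.

    One full-covariance Gaussian per leaf is fitted in the global
    standardized space with mixture weight equal to the leaf fraction;
    singular covariances are ridge-regularized (1e-6 * trace/d on the
    diagonal) with a warning.  A single leaf scores exactly 1.
    """
    leaf_members = [np.asarray(mem) for mem in leaf_members]
    n, d = X.shape
    if len(leaf_members) == 1:
        return 1.0
    log_post = np.empty((n, len(leaf_members)))
    for j, mem in enumerate(leaf_members):
        sub = X[mem]
        w = mem.size / n
        mean = sub.mean(axis=0)
        cov = np.cov(sub, rowvar=False, ddof=0) if mem.size > 1 else np.eye(d)
        cov = np.atleast_2d(cov)
        ridge = 1e-6 * np.trace(cov) / d
        if mem.size < d + 1:
            warnings.warn(
                f"leaf with {mem.size} points < dim+1; covariance regularized"
            )
            ridge = max(ridge, 1e-3)
        cov = cov + ridge * np.eye(d)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn("singular leaf covariance; extra regularization applied")
            cov = cov + 1e-3 * np.eye(d)
            chol = np.linalg.cholesky(cov)
        diff = X - mean
        u = solve_triangular(chol, diff.T, lower=True).T
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        log_post[:, j] = (
            np.log(w)
            - 0.5 * (u**2).sum(axis=1)
            - 0.5 * logdet
            - 0.5 * d * np.log(2 * np.pi)
        )
    mx = log_post.max(axis=1, keepdims=True)
    p = np.exp(log_post - mx)
    post = p / p.sum(axis=1, keepdims=True)
    return float(post.max(axis=1).mean())


# -- recursion -------------------------------------------------------------

def fit(features: FeatureTable, config: BCAConfig = BCAConfig()):
    """Run the full divisive clustering; returns ``(ClusterTree, Labeling)``.

    Depth-first: each leaf receives an inner-loop proposal; the split is
    committed only if the global posterior score stays at or above
    ``max(posterior_min, previous - posterior_drop_tol)``.  Deterministic
    for a fixed config seed.
    """
    X = features.X
    next_id = [0]

    def new_node(parent, members, depth):
        node = ClusterNode(
            node_id=next_id[0], parent_id=parent, member_cells=members, depth=depth
        )
        next_id[0] += 1
        return node

    root = new_node(None, np.arange(X.shape[0]), 0)
    nodes = {root.node_id: root}
    score = [1.0]  # single-leaf posterior is exactly 1

    def current_leaves():
        return [n for n in nodes.values() if n.is_leaf]

    def try_split(node):
        if node.depth >= config.max_depth or node.member_cells.size < config.n_min:
            return
        # per-node deterministic seed derived from the config seed
        node_seed = int(
            np.random.SeedSequence([config.seed, node.node_id]).generate_state(1)[0]
            % (2**31)
        )
        chosen_k, part, curve, loadings = propose_split(
            X[node.member_cells], config, seed=node_seed
        )
        node.compactness_curve = curve
        node.pca_loadings = loadings
        node.chosen_k = chosen_k
        if chosen_k == 1:
            return
        children = [
            new_node(node.node_id, node.member_cells[part == j], node.depth + 1)
            for j in range(chosen_k)
        ]
        candidate = [
            n.member_cells for n in current_leaves() if n is not node
        ] + [c.member_cells for c in children]
        new_score = evaluate_clustering(X, candidate)
        threshold = max(config.posterior_min, score[0] - config.posterior_drop_tol)
        if new_score < threshold:
            log.info(
                "split of node %d rejected: posterior %.4f < %.4f",
                node.node_id, new_score, threshold,
            )
            node.chosen_k = 1
            return
        node.children = children
        node.posterior_score = new_score
        score[0] = new_score
        for c in children:
            nodes[c.node_id] = c
        for c in children:
            try_split(c)

    try_split(root)

    tree = ClusterTree(root=root, nodes=nodes, config=config)
    labels = np.empty(X.shape[0], dtype=int)
    for leaf in tree.leaves:
        labels[leaf.member_cells] = leaf.node_id
    labeling = Labeling(labels=labels, leaf_ids=tuple(n.node_id for n in tree.leaves))
    return tree, labeling


def label_map(
    tree: ClusterTree, labeling: Labeling, features: FeatureTable, series: QVPSeries
) -> np.ndarray:
    """Paint leaf labels onto the series' time x height grid.

    Complete cells get their leaf id; masked or incomplete cells get the
    ``UNCLASSIFIED`` sentinel (-1).
    """
    if features.cell_index[:, 0].max(initial=-1) >= series.times.size or (
        features.cell_index[:, 1].max(initial=-1) >= series.heights_m.size
    ):
        raise ValueError("feature table does not match the series dimensions")
    grid = np.full(series.shape, UNCLASSIFIED, dtype=int)
    grid[features.cell_index[:, 0], features.cell_index[:, 1]] = labeling.labels
    return grid
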
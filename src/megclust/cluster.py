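"""Spatio-spectral cluster-permutation statistics.

The statistic: at every (source node, frequency step) cell, the Spearman
correlation between the post/pre power ratio and the CPT commission post/pre
ratio, partialed for age by residualising the ranks of both variables on the
ranks of age. Cells significant at ``alpha_node`` are filtered for spectral
persistence (a node must stay significant with the same sign over at least
``min_consecutive_steps`` consecutive steps), grouped into sign-consistent
connected components on the node x frequency lattice (spatial graph edges
within a step, step +/- 1 within a node), and pruned by a per-step spatial
extent criterion. The cluster mass is the summed rho over members; the
familywise error rate is controlled by comparing each observed mass with the
distribution of the maximum absolute surrogate mass over permutations that
shuffle the behavioural ratio across participants.

Model interface: :class:`SpectralClusterModel` bundles the inputs;
``fit()`` runs the permutation test and returns
:class:`SpectralClusterResults` with the clusters, p-values, per-cluster
summaries, ROI occupancy and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .datatypes import (
    Cluster,
    ClusterInference,
    ClusterParams,
    CohortTable,
    CorrelationMap,
    PowerTensor,
    RatioTensor,
    SourceGraph,
    roi_label_map,
)

__all__ = [
    "compute_ratio_tensor",
    "compute_cpt_ratio",
    "partial_spearman",
    "correlation_maps",
    "form_clusters",
    "permutation_test",
    "cluster_summary",
    "roi_occupancy",
    "SpectralClusterModel",
    "SpectralClusterResults",
]


# ---------------------------------------------------------------------------
# ratios


def compute_ratio_tensor(pre: PowerTensor, post: PowerTensor) -> RatioTensor:
    """Elementwise post/pre power ratio."""
    if pre.participant_order != post.participant_order:
        raise ValueError("participant order mismatch between pre and post tensors")
    if pre.values.shape != post.values.shape:
        raise ValueError("pre/post tensor shape mismatch")
    if not np.allclose(pre.freq_axis, post.freq_axis):
        raise ValueError("pre/post frequency axes differ")
    if np.any(pre.values <= 0):
        raise ValueError("pre power must be strictly positive to form ratios")
    return RatioTensor(
        post.values / pre.values, pre.freq_axis, list(pre.participant_order)
    )


def compute_cpt_ratio(cohort: CohortTable) -> np.ndarray:
    """Per-participant CPT commission post/pre ratio (< 1 means improvement)."""
    pre = np.asarray(cohort.data["cpt_commission_pre"], float)
    post = np.asarray(cohort.data["cpt_commission_post"], float)
    if np.any(pre <= 0):
        bad = [p for p, v in zip(cohort.participant_ids, pre) if v <= 0]
        raise ValueError(f"non-positive pre score for participant(s) {bad}")
    return post / pre


# ---------------------------------------------------------------------------
# age-partialed Spearman


def _rank_residual_projector(covariate: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q of span{1, ranks(covariate)} for residualisation."""
    rz = stats.rankdata(covariate)
    n = rz.size
    Z = np.column_stack([np.ones(n), rz])
    # QR with column pivoting is overkill; drop the rank column if constant
    if np.ptp(rz) == 0:
        Z = Z[:, :1]
    Q, _ = np.linalg.qr(Z)
    return Q


def partial_spearman(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[float, float]:
    """Spearman correlation of x and y partialing out covariate z.

    Ranks (average ranks for ties) of x and y are residualised on
    [1, ranks(z)] by least squares; rho is the Pearson correlation of the
    residuals and the two-sided p comes from a t distribution with n - 3
    degrees of freedom. A constant covariate reduces to the plain Spearman
    correlation (with the same conservative df).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    n = x.size
    if not (y.size == n and z.size == n):
        raise ValueError("x, y, z must have equal length")
    if n < 5:
        raise ValueError("need at least 5 observations")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)) or np.any(~np.isfinite(z)):
        raise ValueError("missing/non-finite values are not supported")
    Q = _rank_residual_projector(z)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    ex = rx - Q @ (Q.T @ rx)
    ey = ry - Q @ (Q.T @ ry)
    nx = np.linalg.norm(ex)
    ny = np.linalg.norm(ey)
    if nx < 1e-10 * np.sqrt(n) or ny < 1e-10 * np.sqrt(n):
        raise ValueError("constant variable after ranking/residualisation")
    rho = float(np.clip(ex @ ey / (nx * ny), -1.0, 1.0))
    return rho, _rho_to_p(np.asarray(rho), n)


def _rho_to_p(rho: np.ndarray, n: int) -> np.ndarray | float:
    df = n - 3
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / (1.0 - rho**2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    return float(p) if p.ndim == 0 else p


class _PartialRankEngine:
    """Vectorised age-partialed Spearman over all (node, step) cells.

    Ranks of the power ratio are fixed across permutations (only the
    behavioural vector is shuffled), so the rank/residual work on the tensor
    happens once; each permutation then costs a single matrix-vector product.
    """

    def __init__(self, ratio: RatioTensor, cpt_ratio: np.ndarray, age: np.ndarray):
        vals = ratio.values
        n, self.n_nodes, self.n_steps = vals.shape
        cpt_ratio = np.asarray(cpt_ratio, float)
        age = np.asarray(age, float)
        if cpt_ratio.size != n or age.size != n:
            raise ValueError("cpt_ratio/age length must match the tensor")
        if n < 5:
            raise ValueError("need at least 5 participants")
        self.n = n
        self.Q = _rank_residual_projector(age)
        X = vals.reshape(n, -1)
        RX = stats.rankdata(X, axis=0)
        RX = RX - self.Q @ (self.Q.T @ RX)
        norms = np.linalg.norm(RX, axis=0)
        self.valid = norms > 1e-10 * np.sqrt(n)
        safe = np.where(self.valid, norms, 1.0)
        self.RXn = RX / safe
        self.RXn[:, ~self.valid] = 0.0
        self.y_ranks = stats.rankdata(cpt_ratio)
        self.age = age

    def rho_for_orders(self, orders: np.ndarray) -> np.ndarray:
        """rho maps, shape (B, nodes, steps), for B participant orderings."""
        RY = self.y_ranks[orders]  # (B, n)
        RY = RY - (RY @ self.Q) @ self.Q.T
        norms = np.linalg.norm(RY, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        rho = (RY / norms) @ self.RXn
        np.clip(rho, -1.0, 1.0, out=rho)
        return rho.reshape(-1, self.n_nodes, self.n_steps)

    def observed_map(self) -> CorrelationMap:
        rho = self.rho_for_orders(np.arange(self.n)[None, :])[0]
        pval = np.asarray(_rho_to_p(rho, self.n))
        valid = self.valid.reshape(self.n_nodes, self.n_steps)
        rho = np.where(valid, rho, 0.0)
        pval = np.where(valid, pval, 1.0)
        return CorrelationMap(rho=rho, pval=pval, valid=valid)


def correlation_maps(
    ratio: RatioTensor, cpt_ratio: np.ndarray, age: np.ndarray
) -> CorrelationMap:
    """Age-partialed Spearman rho/p at every (node, frequency-step) cell."""
    return _PartialRankEngine(ratio, cpt_ratio, age).observed_map()


# ---------------------------------------------------------------------------
# cluster forming


def _persistence_filter(mask: np.ndarray, k: int) -> np.ndarray:
    """Keep True cells lying in runs of >= k consecutive steps (last axis)."""
    if k <= 1:
        return mask
    ns = mask.shape[-1]
    run = np.zeros(mask.shape, dtype=np.int32)
    acc = np.zeros(mask.shape[:-1], dtype=np.int32)
    for s in range(ns):
        acc = (acc + 1) * mask[..., s]
        run[..., s] = acc
    # propagate each run's total length backwards through the run
    for s in range(ns - 2, -1, -1):
        both = mask[..., s] & mask[..., s + 1]
        run[..., s] = np.where(both, run[..., s + 1], run[..., s])
    return mask & (run >= k)


def _components(
    alive: np.ndarray, edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Connected components of alive cells on the node x step lattice.

    Returns (cell_index_array (nodes, steps) with -1 for dead cells,
    labels per alive cell, number of components).
    """
    n_nodes, n_steps = alive.shape
    ids = np.full((n_nodes, n_steps), -1, dtype=np.int64)
    n_alive = int(alive.sum())
    ids[alive] = np.arange(n_alive)
    if n_alive == 0:
        return ids, np.empty(0, int), 0
    rows = []
    cols = []
    # frequency adjacency: same node, neighbouring steps
    a = ids[:, :-1]
    b = ids[:, 1:]
    m = (a >= 0) & (b >= 0)
    rows.append(a[m])
    cols.append(b[m])
    # spatial adjacency within each step
    if edges.size:
        ea = ids[edges[:, 0], :]
        eb = ids[edges[:, 1], :]
        m = (ea >= 0) & (eb >= 0)
        rows.append(ea[m])
        cols.append(eb[m])
    rows = np.concatenate(rows) if rows else np.empty(0, int)
    cols = np.concatenate(cols) if cols else np.empty(0, int)
    g = sparse.coo_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)),
        shape=(n_alive, n_alive),
    )
    n_comp, labels = connected_components(g, directed=False)
    return ids, labels, n_comp


def _clusters_one_sign(
    rho: np.ndarray,
    sig: np.ndarray,
    sign: int,
    edges: np.ndarray,
    params: ClusterParams,
    masses_only: bool = False,
):
    """Clusters (or just masses) of one correlation sign for one rho map."""
    n_nodes, n_steps = rho.shape
    mask = sig & ((rho > 0) if sign > 0 else (rho < 0))
    if params.persistence_mode == "node_runs":
        mask = _persistence_filter(mask, params.min_consecutive_steps)
    if not mask.any():
        return []
    mask = mask.copy()
    min_nodes = params.min_extent_nodes(n_nodes)

    # Iterate component finding against the span/extent criteria: "trim"
    # removes only the sub-threshold frequency steps of a component (the
    # cluster keeps its well-populated core even when a few ragged edge
    # cells stretch its span), "discard" drops the whole component. Cells
    # strictly decrease each round, so the loop terminates.
    while True:
        ids, labels, n_comp = _components(mask, edges)
        if n_comp == 0:
            return []
        cell_nodes, cell_steps = np.nonzero(mask)
        cell_labels = labels[ids[cell_nodes, cell_steps]]
        order = np.argsort(cell_labels, kind="stable")
        cn, cs, cl = cell_nodes[order], cell_steps[order], cell_labels[order]
        bounds = np.searchsorted(cl, np.arange(n_comp + 1))

        changed = False
        out = []
        for c in range(n_comp):
            lo, hi = bounds[c], bounds[c + 1]
            nodes_c, steps_c = cn[lo:hi], cs[lo:hi]
            s0, s1 = int(steps_c.min()), int(steps_c.max())
            span_len = s1 - s0 + 1
            if (
                params.persistence_mode == "cluster_span"
                and span_len < params.min_consecutive_steps
            ):
                mask[nodes_c, steps_c] = False
                changed = True
                continue
            extent = np.bincount(steps_c - s0, minlength=span_len)
            if min_nodes > 0 and np.any(extent < min_nodes):
                changed = True
                if params.extent_mode == "discard":
                    mask[nodes_c, steps_c] = False
                else:
                    bad = extent[steps_c - s0] < min_nodes
                    mask[nodes_c[bad], steps_c[bad]] = False
                continue
            mass = float(rho[nodes_c, steps_c].sum())
            if masses_only:
                out.append(mass)
            else:
                out.append(
                    Cluster(
                        members=frozenset(zip(nodes_c.tolist(), steps_c.tolist())),
                        sign=sign,
                        mass=mass,
                        freq_span=(s0, s1),
                        extent_per_step=tuple(int(e) for e in extent),
                    )
                )
        if not changed:
            return out


def _clusters_from_rho(
    rho: np.ndarray,
    sig: np.ndarray,
    edges: np.ndarray,
    params: ClusterParams,
    masses_only: bool = False,
):
    out = []
    for sign in (1, -1):
        out.extend(_clusters_one_sign(rho, sig, sign, edges, params, masses_only))
    return out


def _rho_critical(alpha: float, n: int) -> float:
    """|rho| threshold equivalent to a two-sided p < alpha at df = n - 3."""
    df = n - 3
    tc = stats.t.isf(alpha / 2.0, df)
    return tc / np.sqrt(df + tc**2)


def form_clusters(
    cmap: CorrelationMap, graph: SourceGraph, params: ClusterParams
) -> list[Cluster]:
    """Sign-consistent spatio-spectral clusters of significant cells.

    Steps: (1) threshold cells at ``alpha_node`` and split by rho sign;
    (2) per-node spectral persistence filter; (3) connected components on the
    node x frequency lattice; (4) per-step spatial extent filter over the
    cluster's frequency span; (5) mass = summed rho. Clusters are returned
    sorted by decreasing |mass|.
    """
    if cmap.rho.shape[0] != graph.n_nodes:
        raise ValueError("map node dimension does not match graph")
    sig = (cmap.pval < params.alpha_node) & cmap.valid
    clusters = _clusters_from_rho(cmap.rho, sig, graph.edges, params)
    return sorted(clusters, key=lambda c: -abs(c.mass))


# ---------------------------------------------------------------------------
# permutation inference

#: cap on the permutation batch memory (number of rho-map floats per chunk)
_CHUNK_BUDGET = 40_000_000


def permutation_test(
    ratio: RatioTensor,
    cpt_ratio: np.ndarray,
    age: np.ndarray,
    graph: SourceGraph,
    params: ClusterParams,
    orders: np.ndarray | None = None,
) -> ClusterInference:
    """Max-statistic permutation inference over the cluster pipeline.

    For each permutation the behavioural ratio is shuffled across
    participants (age stays paired with the power data unless
    ``params.shuffle == "joint"``), the full map -> cluster pipeline is re-run
    and the maximum absolute surrogate mass recorded (0 when no surrogate
    cluster survives). Each observed cluster's p-value is
    ``(#{null >= |mass|} + 1) / (n_permutations + 1)``.

    ``orders`` may supply an explicit (B, n) array of participant orderings
    (e.g. the full permutation group at tiny n), overriding the random draw.
    """
    engine = _PartialRankEngine(ratio, cpt_ratio, age)
    if graph.n_nodes != engine.n_nodes:
        raise ValueError("graph node count does not match tensor")
    n = engine.n
    edges = graph.edges

    cmap = engine.observed_map()
    observed = form_clusters(cmap, graph, params)

    if orders is not None:
        orders = np.asarray(orders, int)
        if orders.ndim != 2 or orders.shape[1] != n:
            raise ValueError("orders must be (B, n)")
        n_perm = orders.shape[0]
        if n_perm < 100:
            raise ValueError("n_permutations must be >= 100")
    else:
        n_perm = params.n_permutations

    rng = np.random.default_rng(params.seed)
    null_max = np.empty(n_perm, float)
    cells = engine.n_nodes * engine.n_steps
    chunk = max(1, min(n_perm, _CHUNK_BUDGET // max(cells, 1)))
    # thresholding |rho| at the critical value is equivalent to p < alpha at
    # fixed df and avoids millions of t-distribution evaluations per batch
    rho_crit = _rho_critical(params.alpha_node, n)
    valid = engine.valid.reshape(engine.n_nodes, engine.n_steps)

    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        if orders is not None:
            batch = orders[done : done + b]
        else:
            batch = np.empty((b, n), dtype=int)
            for i in range(b):
                batch[i] = rng.permutation(n)
        if params.shuffle == "joint":
            # shuffling (behaviour, age) jointly == residualising the permuted
            # behaviour on the permuted age ranks
            rho_batch = _joint_shuffle_rho(engine, batch)
        else:
            rho_batch = engine.rho_for_orders(batch)
        sig = (np.abs(rho_batch) > rho_crit) & valid[None]
        if params.persistence_mode == "node_runs":
            pos = _persistence_filter(sig & (rho_batch > 0),
                                      params.min_consecutive_steps)
            neg = _persistence_filter(sig & (rho_batch < 0),
                                      params.min_consecutive_steps)
            any_alive = (pos | neg).any(axis=(1, 2))
        else:
            any_alive = sig.any(axis=(1, 2))
        for i in range(b):
            if not any_alive[i]:
                null_max[done + i] = 0.0
                continue
            masses = _clusters_from_rho(
                rho_batch[i], sig[i], edges, params, masses_only=True
            )
            null_max[done + i] = max((abs(m) for m in masses), default=0.0)
        done += b

    p_values = np.array(
        [
            (np.count_nonzero(null_max >= abs(c.mass)) + 1.0) / (n_perm + 1.0)
            for c in observed
        ]
    )
    return ClusterInference(
        clusters=observed,
        null_max_mass=null_max,
        p_values=p_values,
        n_permutations=n_perm,
        seed=params.seed,
    )


def _joint_shuffle_rho(engine: _PartialRankEngine, batch: np.ndarray) -> np.ndarray:
    """rho maps when (behaviour, age) are shuffled together.

    Residualising the permuted behaviour ranks on the permuted age ranks is
    equivalent to residualising in the original order, then permuting — so we
    reuse the precomputed projector on unpermuted age and permute the
    residuals of y. The x-side residuals stay partialed on unpermuted age.
    """
    y = engine.y_ranks
    ey = y - engine.Q @ (engine.Q.T @ y)
    RY = ey[batch]
    norms = np.linalg.norm(RY, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    rho = (RY / norms) @ engine.RXn
    np.clip(rho, -1.0, 1.0, out=rho)
    return rho.reshape(-1, engine.n_nodes, engine.n_steps)


# ---------------------------------------------------------------------------
# post hoc summaries


def cluster_summary(
    cluster: Cluster,
    ratio: RatioTensor,
    cohort: CohortTable,
    age: np.ndarray | None = None,
) -> dict:
    """Per-cluster marker: mean in-cluster power ratio vs the CPT ratio.

    The power ratio is averaged over all cluster members per participant and
    correlated (age-partialed Spearman) with the CPT ratio for the whole
    sample and separately per arm. Also reports the extent profile across the
    cluster's frequency span and its peak-extent step.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    if age is None:
        age = cohort.ages
    nodes_idx, steps_idx = map(np.asarray, zip(*sorted(cluster.members)))
    marker = ratio.values[:, nodes_idx, steps_idx].mean(axis=1)
    cpt_ratio = compute_cpt_ratio(cohort)

    def _corr(mask: np.ndarray):
        try:
            rho, p = partial_spearman(marker[mask], cpt_ratio[mask], np.asarray(age)[mask])
            return {"rho": rho, "p": p, "n": int(mask.sum()), "valid": True}
        except ValueError as err:
            return {"rho": float("nan"), "p": float("nan"),
                    "n": int(mask.sum()), "valid": False, "reason": str(err)}

    all_mask = np.ones(cohort.n, bool)
    return {
        "n_members": cluster.n_members,
        "n_nodes": len(cluster.nodes),
        "freq_span": cluster.freq_span,
        "mass": cluster.mass,
        "sign": cluster.sign,
        "extent_per_step": list(cluster.extent_per_step),
        "peak_extent_step": cluster.peak_extent_step,
        "marker": marker,
        "correlation": {
            "all": _corr(all_mask),
            "experimental": _corr(cohort.arm_mask("experimental")),
            "control": _corr(cohort.arm_mask("control")),
        },
    }


def roi_occupancy(cluster: Cluster, graph: SourceGraph) -> pd.DataFrame:
    """Per-ROI occupancy of a cluster's node set.

    For each labeled ROI: N = nodes carrying the label, n = those appearing
    in the cluster at any frequency step, percent = 100 n / N. ROIs disjoint
    from the cluster are omitted; rows sort by n descending, then ROI name.
    """
    labels = roi_label_map(graph)
    cnodes = cluster.nodes
    rows = []
    for name, nodes in labels.items():
        n_in = int(sum(1 for v in nodes if int(v) in cnodes))
        if n_in == 0:
            continue
        N = int(nodes.size)
        rows.append({"roi": name, "n": n_in, "N": N, "percent": 100.0 * n_in / N})
    rows.sort(key=lambda r: (-r["n"], r["roi"]))
    return pd.DataFrame(rows, columns=["roi", "n", "N", "percent"])


# ---------------------------------------------------------------------------
# model / results facade


class SpectralClusterModel:
    """Cluster-permutation analysis bundled as a fittable model.

    Parameters
    ----------
    ratio : RatioTensor
        Post/pre power ratio (participants x nodes x steps).
    cpt_ratio : array
        Behavioural post/pre ratio, one value per participant.
    age : array
        Covariate partialed out of every correlation.
    graph : SourceGraph
        Spatial adjacency (and optional ROI labels) of the source nodes.
    """

    def __init__(
        self,
        ratio: RatioTensor,
        cpt_ratio: np.ndarray,
        age: np.ndarray,
        graph: SourceGraph,
    ):
        self.ratio = ratio
        self.cpt_ratio = np.asarray(cpt_ratio, float)
        self.age = np.asarray(age, float)
        self.graph = graph

    @classmethod
    def from_dataset(cls, cohort: CohortTable, pre: PowerTensor,
                     post: PowerTensor, graph: SourceGraph,
                     relative_power: bool = False) -> "SpectralClusterModel":
        if relative_power:
            pre, post = pre.to_relative(), post.to_relative()
        ratio = compute_ratio_tensor(pre, post)
        if ratio.participant_order != cohort.participant_ids:
            raise ValueError("tensor participant order does not match cohort")
        model = cls(ratio, compute_cpt_ratio(cohort), cohort.ages, graph)
        model.cohort = cohort
        return model

    def correlation_map(self) -> CorrelationMap:
        return correlation_maps(self.ratio, self.cpt_ratio, self.age)

    def fit(self, params: ClusterParams | None = None, **kwargs
            ) -> "SpectralClusterResults":
        """Run the full map -> cluster -> permutation pipeline."""
        if params is None:
            params = ClusterParams(**kwargs)
        inference = permutation_test(
            self.ratio, self.cpt_ratio, self.age, self.graph, params
        )
        return SpectralClusterResults(self, params, inference)


class SpectralClusterResults:
    """Observed clusters with their permutation p-values and post hoc views."""

    def __init__(self, model: SpectralClusterModel, params: ClusterParams,
                 inference: ClusterInference):
        self.model = model
        self.params = params
        self.inference = inference

    @property
    def clusters(self) -> list[Cluster]:
        return self.inference.clusters

    @property
    def p_values(self) -> np.ndarray:
        return self.inference.p_values

    def significant(self, alpha: float = 0.05):
        return self.inference.significant(alpha)

    def cluster_summary(self, index: int, cohort: CohortTable | None = None) -> dict:
        cohort = cohort or getattr(self.model, "cohort", None)
        if cohort is None:
            raise ValueError("no cohort attached; pass one explicitly")
        return cluster_summary(
            self.clusters[index], self.model.ratio, cohort, self.model.age
        )

    def roi_occupancy(self, index: int) -> pd.DataFrame:
        return roi_occupancy(self.clusters[index], self.model.graph)

    def summary(self) -> pd.DataFrame:
        """One row per cluster: size, band, mass and permutation p."""
        freq = self.model.ratio.freq_axis
        rows = []
        for c, p in zip(self.clusters, self.p_values):
            s0, s1 = c.freq_span
            rows.append(
                {
                    "n_members": c.n_members,
                    "n_nodes": len(c.nodes),
                    "sign": c.sign,
                    "f_lo_hz": float(freq[s0]),
                    "f_hi_hz": float(freq[s1]),
                    "mass": c.mass,
                    "p_perm": float(p),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["n_members", "n_nodes", "sign", "f_lo_hz", "f_hi_hz",
                     "mass", "p_perm"],
        )

    def plot_extent_profile(self, index: int = 0, ax=None):
        """Cluster size (node count) per frequency step across the span."""
        import matplotlib.pyplot as plt

        c = self.clusters[index]
        freq = self.model.ratio.freq_axis
        if ax is None:
            _, ax = plt.subplots()
        steps = np.arange(c.freq_span[0], c.freq_span[1] + 1)
        ax.plot(freq[steps], c.extent_per_step, marker="o")
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("nodes in cluster")
        return ax

    def plot_marker_scatter(self, index: int = 0,
                            cohort: CohortTable | None = None, ax=None):
        """Mean in-cluster power ratio vs CPT ratio, coloured by arm."""
        import matplotlib.pyplot as plt

        cohort = cohort or getattr(self.model, "cohort", None)
        if cohort is None:
            raise ValueError("no cohort attached; pass one explicitly")
        info = self.cluster_summary(index, cohort)
        if ax is None:
            _, ax = plt.subplots()
        for arm, color in (("experimental", "tab:blue"), ("control", "tab:orange")):
            m = cohort.arm_mask(arm)
            ax.scatter(self.model.cpt_ratio[m], info["marker"][m],
                       label=arm, color=color)
        ax.set_xlabel("CPT commission ratio (post/pre)")
        ax.set_ylabel("mean in-cluster power ratio (post/pre)")
        ax.legend()
        return ax
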
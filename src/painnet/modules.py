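"""Weighted-signed modular decomposition and hub taxonomy.

Modularity follows the signed convention in which positive and negative
weights carry separate strength-product null terms:

    Q = (1 / (2w+ + 2w-)) * sum_ij [ A_ij
          - ( s_i+ s_j+ / 2w+  -  s_i- s_j- / 2w- ) ] * delta(c_i, c_j)

reducing to the ordinary Newman-Girvan weighted Q when no negative
edges survive thresholding.  The optimizer mirrors a tabu/fast
sequencing strategy: greedy agglomeration from singletons, "fast"
local-reassignment sweeps, a tabu phase (tenure 10) and a closing fast
pass, repeated over independent restarts keeping the best Q.

Node roles: binary degree, Brandes betweenness, Guimera-Amaral
within-module degree z-score (WMD) and participation coefficient (PC).
Hub taxonomy: *static* (degree above the shuffled-weight null,
permutation p < alpha), *dynamical* (betweenness above the null) and
*connector* (WMD > 1.0 and PC above threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score

from .graphs import GraphError, NullEnsemble, ThresholdedGraph

__all__ = [
    "ModularPartition",
    "signed_modularity_value",
    "optimize_partition",
    "compare_partitions",
    "node_profiles",
    "classify_hubs",
    "modular_link_stats",
    "labels_from_mapping",
]

TABU_TENURE = 10
TABU_STAGNATION = 30  # tabu iterations without a new best before stopping
_EPS = 1e-12


@dataclass
class ModularPartition:
    """Community labels with their signed modularity."""

    labels: np.ndarray  # (n,) contiguous module ids from 0
    Q: float
    node_labels: list[str] = field(default_factory=list)

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_modules)

    def as_mapping(self) -> dict[str, int]:
        return {lab: int(c) for lab, c in zip(self.node_labels, self.labels)}

    def members(self, module: int) -> list[str]:
        return [lab for lab, c in zip(self.node_labels, self.labels) if c == module]


def labels_from_mapping(mapping: dict[str, str | int], node_labels: list[str]) -> np.ndarray:
    """Integer label array (contiguous, order of first appearance) from a
    node->module mapping."""
    seen: dict = {}
    out = np.empty(len(node_labels), dtype=int)
    for i, lab in enumerate(node_labels):
        m = mapping[lab]
        if m not in seen:
            seen[m] = len(seen)
        out[i] = seen[m]
    return out


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 0..m-1 by decreasing size, ties by smallest member."""
    labels = np.asarray(labels)
    ids, counts = np.unique(labels, return_counts=True)
    first = np.array([np.argmax(labels == c) for c in ids])
    order = sorted(range(len(ids)), key=lambda k: (-counts[k], first[k]))
    remap = {ids[k]: rank for rank, k in enumerate(order)}
    return np.array([remap[c] for c in labels], dtype=int)


class _QState:
    """Incremental signed-modularity bookkeeping for local moves."""

    def __init__(self, G: ThresholdedGraph, labels: np.ndarray):
        self.A = G.A
        self.n = G.n_nodes
        self.sp = G.pos_strength
        self.sm = G.neg_strength
        self.twp = float(self.sp.sum())  # = 2 w+
        self.twm = float(self.sm.sum())  # = 2 w-
        self.denom = self.twp + self.twm
        if self.denom <= 0:
            raise GraphError("graph has no edges")
        self.set_labels(labels)

    def set_labels(self, labels: np.ndarray) -> None:
        self.labels = np.asarray(labels, dtype=int).copy()
        m = self.labels.max() + 1
        self.Sp = np.bincount(self.labels, weights=self.sp, minlength=m)
        self.Sm = np.bincount(self.labels, weights=self.sm, minlength=m)

    @property
    def n_modules(self) -> int:
        return len(self.Sp)

    def value(self) -> float:
        q = 0.0
        for c in range(self.n_modules):
            idx = self.labels == c
            if not idx.any():
                continue
            q += self.A[np.ix_(idx, idx)].sum()
            if self.twp > 0:
                q -= self.Sp[c] ** 2 / self.twp
            if self.twm > 0:
                q += self.Sm[c] ** 2 / self.twm
        return q / self.denom

    def link_to_modules(self, i: int) -> np.ndarray:
        return np.bincount(self.labels, weights=self.A[i], minlength=self.n_modules)

    def move_deltas(self, i: int, links: np.ndarray | None = None) -> np.ndarray:
        """ΔQ of moving node i into every module (index m = new singleton)."""
        a = self.labels[i]
        links = self.link_to_modules(i) if links is None else links
        m = self.n_modules
        spi, smi = self.sp[i], self.sm[i]
        Sp_b = np.append(self.Sp, 0.0)
        Sm_b = np.append(self.Sm, 0.0)
        lb = np.append(links, 0.0)
        la = links[a]
        d = 2.0 * (lb - la)
        if self.twp > 0:
            d -= 2.0 * spi * (Sp_b - (self.Sp[a] - spi)) / self.twp
        if self.twm > 0:
            d += 2.0 * smi * (Sm_b - (self.Sm[a] - smi)) / self.twm
        d /= self.denom
        d[a] = 0.0
        return d

    def apply_move(self, i: int, b: int) -> None:
        a = self.labels[i]
        if b == self.n_modules:  # new singleton module
            self.Sp = np.append(self.Sp, 0.0)
            self.Sm = np.append(self.Sm, 0.0)
        self.labels[i] = b
        self.Sp[a] -= self.sp[i]
        self.Sp[b] += self.sp[i]
        self.Sm[a] -= self.sm[i]
        self.Sm[b] += self.sm[i]


def signed_modularity_value(G: ThresholdedGraph, labels) -> float:
    """Signed modularity Q of a labeling (see module docstring).

    ``labels`` may be an integer array, a node->module mapping, or a
    :class:`ModularPartition`.
    """
    if isinstance(labels, ModularPartition):
        labels = labels.labels
    elif isinstance(labels, dict):
        labels = labels_from_mapping(labels, G.node_labels)
    labels = np.asarray(labels)
    if labels.shape != (G.n_nodes,):
        raise GraphError("labels must cover every node exactly once")
    _, labels = np.unique(labels, return_inverse=True)
    return _QState(G, labels).value()


def _fast_pass(state: _QState, rng: np.random.Generator) -> None:
    """Local-reassignment sweeps until no single move improves Q."""
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(state.n):
            d = state.move_deltas(i)
            b = int(np.argmax(d))
            if d[b] > _EPS:
                state.apply_move(i, b)
                improved = True


def _greedy_agglomeration(state: _QState) -> None:
    """Merge module pairs with the best positive ΔQ until none remains."""
    while True:
        m = state.n_modules
        alive = [c for c in range(m) if np.any(state.labels == c)]
        if len(alive) < 2:
            return
        # inter-module weight totals
        ind = np.zeros((state.n, m))
        ind[np.arange(state.n), state.labels] = 1.0
        E = ind.T @ state.A @ ind  # E[a, b] = total weight between a and b
        best, pair = _EPS, None
        for ai, a in enumerate(alive):
            for b in alive[ai + 1:]:
                d = 2.0 * E[a, b]
                if state.twp > 0:
                    d -= 2.0 * state.Sp[a] * state.Sp[b] / state.twp
                if state.twm > 0:
                    d += 2.0 * state.Sm[a] * state.Sm[b] / state.twm
                d /= state.denom
                if d > best:
                    best, pair = d, (a, b)
        if pair is None:
            return
        a, b = pair
        state.labels[state.labels == b] = a
        state.Sp[a] += state.Sp[b]
        state.Sm[a] += state.Sm[b]
        state.Sp[b] = state.Sm[b] = 0.0


def _compact(state: _QState) -> None:
    _, labels = np.unique(state.labels, return_inverse=True)
    state.set_labels(labels)


def _tabu_phase(state: _QState, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Tabu search over single-node moves; returns the best labeling seen.

    A moved node may not move again for TABU_TENURE iterations unless
    the move would beat the best Q seen (aspiration).  Worsening moves
    are allowed, which lets the search leave local optima.
    """
    best_labels = state.labels.copy()
    best_q = state.value()
    q = best_q
    tabu_until = np.zeros(state.n, dtype=int)
    stagnation = 0
    it = 0
    while stagnation < TABU_STAGNATION:
        it += 1
        best_d, best_move = -np.inf, None
        for i in range(state.n):
            d = state.move_deltas(i)
            d[state.labels[i]] = -np.inf  # staying put is not a move
            b = int(np.argmax(d))
            allowed = tabu_until[i] <= it or (q + d[b] > best_q + _EPS)
            if allowed and d[b] > best_d:
                best_d, best_move = d[b], (i, b)
        if best_move is None:
            break
        i, b = best_move
        state.apply_move(i, b)
        q += best_d
        tabu_until[i] = it + TABU_TENURE
        if q > best_q + _EPS:
            best_q, best_labels = q, state.labels.copy()
            stagnation = 0
        else:
            stagnation += 1
    return best_labels, best_q


def optimize_partition(
    G: ThresholdedGraph, n_restarts: int = 100, seed: int | None = None
) -> ModularPartition:
    """Multi-restart signed-modularity maximization.

    Each restart runs greedy agglomeration from singletons, fast local
    passes, a tabu phase and a closing fast pass; the best labeling over
    all restarts (first found among ties) is returned with its Q.
    Deterministic given ``seed``.  Degenerate (edgeless) graphs return
    the one-module partition with Q = 0 by convention.
    """
    n = G.n_nodes
    if G.edge_count == 0:
        return ModularPartition(labels=np.zeros(n, dtype=int), Q=0.0,
                                node_labels=list(G.node_labels))
    rng = np.random.default_rng(seed)
    best_labels, best_q = None, -np.inf
    for _ in range(n_restarts):
        state = _QState(G, np.arange(n))
        _greedy_agglomeration(state)
        _compact(state)
        _fast_pass(state, rng)
        _compact(state)
        tabu_labels, _ = _tabu_phase(state, rng)
        state.set_labels(tabu_labels)
        _compact(state)
        _fast_pass(state, rng)
        _compact(state)
        q = state.value()
        if q > best_q + _EPS:
            best_q, best_labels = q, state.labels.copy()
    labels = _canonical(best_labels)
    return ModularPartition(labels=labels, Q=float(best_q),
                            node_labels=list(G.node_labels))


def compare_partitions(p1, p2, node_labels: list[str] | None = None) -> dict:
    """Normalized mutual information and exact-match-after-relabel flag.

    Accepts :class:`ModularPartition`, node->module dicts (keys must
    agree) or aligned label arrays.
    """
    def as_array(p, other):
        if isinstance(p, ModularPartition):
            return np.asarray(p.labels), list(p.node_labels)
        if isinstance(p, dict):
            return None, None
        return np.asarray(p), node_labels

    if isinstance(p1, dict) or isinstance(p2, dict):
        d1 = p1.as_mapping() if isinstance(p1, ModularPartition) else dict(p1)
        d2 = p2.as_mapping() if isinstance(p2, ModularPartition) else dict(p2)
        if set(d1) != set(d2):
            raise ValueError("partitions cover different node sets")
        keys = sorted(d1)
        a = labels_from_mapping(d1, keys)
        b = labels_from_mapping(d2, keys)
    else:
        a, la = as_array(p1, p2)
        b, lb = as_array(p2, p1)
        if la and lb and la != lb:
            raise ValueError("partitions cover different node sets")
        if len(a) != len(b):
            raise ValueError("partitions cover different node sets")
    nmi = float(normalized_mutual_info_score(a, b, average_method="arithmetic"))
    cont = pd.crosstab(a, b).to_numpy()
    exact = bool(
        np.all((cont > 0).sum(axis=0) == 1) and np.all((cont > 0).sum(axis=1) == 1)
    )
    return {"nmi": nmi, "exact_match_after_relabel": exact}


def node_profiles(G: ThresholdedGraph, partition: ModularPartition) -> pd.DataFrame:
    """Per-node role table: degree, betweenness, WMD z-score, PC.

    Betweenness is unnormalized Brandes on the binary view.  WMD z uses
    the population SD of within-module degree inside each module (0 when
    the SD is 0).  PC = 1 - sum_s (kappa_is / k_i)^2, defined as 0 for
    isolated nodes (flagged).
    """
    labels = np.asarray(partition.labels)
    if labels.shape != (G.n_nodes,):
        raise GraphError("partition does not cover the graph's nodes")
    B = G.binary
    k = G.degree
    m = labels.max() + 1
    ind = np.zeros((G.n_nodes, m))
    ind[np.arange(G.n_nodes), labels] = 1.0
    kappa_im = B @ ind  # links from node i into each module
    kappa = kappa_im[np.arange(G.n_nodes), labels]  # within-module degree
    z = np.zeros(G.n_nodes)
    for c in range(m):
        idx = labels == c
        mu, sd = kappa[idx].mean(), kappa[idx].std()
        if sd > 0:
            z[idx] = (kappa[idx] - mu) / sd
    with np.errstate(invalid="ignore", divide="ignore"):
        pc = 1.0 - np.nansum((kappa_im / np.where(k > 0, k, np.nan)[:, None]) ** 2, axis=1)
    pc[k == 0] = 0.0
    gx = G.to_networkx(weighted=False)
    bc = nx.betweenness_centrality(gx, normalized=False)
    return pd.DataFrame(
        {
            "node": G.node_labels,
            "module": labels,
            "k": k,
            "b": [bc[lab] for lab in G.node_labels],
            "z_wmd": z,
            "pc": pc,
            "isolated": k == 0,
        }
    )


def classify_hubs(
    profiles: pd.DataFrame,
    null: NullEnsemble,
    wmd_min: float = 1.0,
    pc_min: float = 0.45,
    alpha: float = 0.01,
    pc_mode: str = "fixed",
) -> pd.DataFrame:
    """Attach the three hub flags to a node-profile table.

    *static*: degree above the per-node shuffled-weight null at
    permutation p < ``alpha``; *dynamical*: likewise for betweenness;
    *connector*: ``z_wmd > wmd_min`` and ``pc`` above the threshold —
    the fixed ``pc_min`` (default 0.45) or, with
    ``pc_mode="mean_plus_sd"``, mean(pc) + 1 SD over nodes.
    """
    if null is None or "degree" not in null or "betweenness" not in null:
        raise ValueError("null ensemble with degree and betweenness distributions required")
    out = profiles.copy()
    R = null.n_realizations
    ndeg = null.metrics["degree"]
    nbet = null.metrics["betweenness"]
    k = out["k"].to_numpy()
    b = out["b"].to_numpy()
    out["p_degree"] = (1.0 + (ndeg >= k[None, :]).sum(axis=0)) / (1.0 + R)
    out["p_betweenness"] = (1.0 + (nbet >= b[None, :]).sum(axis=0)) / (1.0 + R)
    if pc_mode == "mean_plus_sd":
        pc_thr = float(out["pc"].mean() + out["pc"].std(ddof=0))
    elif pc_mode == "fixed":
        pc_thr = pc_min
    else:
        raise ValueError(f"unknown pc_mode {pc_mode!r}")
    out["hub_static"] = out["p_degree"] < alpha
    out["hub_dynamical"] = out["p_betweenness"] < alpha
    out["hub_connector"] = (out["z_wmd"] > wmd_min) & (out["pc"] > pc_thr)
    out.attrs["thresholds"] = {
        "wmd_min": wmd_min, "pc_threshold": pc_thr, "alpha": alpha, "pc_mode": pc_mode,
    }
    return out


def modular_link_stats(G: ThresholdedGraph, partition: ModularPartition) -> dict:
    """Intra/inter-modular link accounting and network average strength.

    Returns per-module intra-edge counts and proportions (a module's
    intramodular links over all links touching it), the pairwise
    inter-module count matrix, overall intra/inter totals, and the
    network average strength (mean over nodes of the summed thresholded
    weights).
    """
    labels = np.asarray(partition.labels)
    B = G.binary
    m = labels.max() + 1
    ind = np.zeros((G.n_nodes, m))
    ind[np.arange(G.n_nodes), labels] = 1.0
    M = ind.T @ B @ ind
    intra = np.diag(M) / 2.0
    inter = M - np.diag(np.diag(M))
    incident = intra + inter.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(incident > 0, intra / incident, np.nan)
    total_edges = B.sum() / 2.0
    total_intra = intra.sum()
    return {
        "intra_counts": intra.astype(int),
        "intra_proportions": prop,
        "inter_counts": (inter / 1.0).astype(int),
        "total_intra": int(total_intra),
        "total_inter": int(total_edges - total_intra),
        "total_edges": int(total_edges),
        "intra_fraction": float(total_intra / total_edges) if total_edges else float("nan"),
        "average_strength": float(G.A.sum(axis=1).mean()),
    }
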
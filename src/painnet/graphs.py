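"""Density thresholding, global topology battery and shuffled-weight nulls.

Edges are retained by proportional density: the strongest d-fraction of
the n(n-1)/2 possible links ranked by |z|, signs kept (so strong
negative correlations may survive into the signed-modularity stage).
Clustering (C), characteristic path length (L) and betweenness operate
on the binary view of the thresholded graph; the small-world coefficient
sigma = (C/C_random)/(L/L_random) compares them to the mean of a
shuffled-weight null ensemble with identical size, edge count and weight
multiset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

__all__ = [
    "ThresholdedGraph",
    "GlobalMetrics",
    "NullEnsemble",
    "proportional_threshold",
    "global_metrics",
    "random_equivalents",
    "binary_clustering",
    "characteristic_path_length",
    "neighbor_degree_assortativity",
]


class GraphError(ValueError):
    pass


@dataclass
class ThresholdedGraph:
    """Signed sparse graph: weights below the density cut are zeroed."""

    A: np.ndarray  # (n, n) symmetric signed weights, zero diagonal
    density: float
    node_labels: list[str]
    condition: str = ""

    def __post_init__(self):
        A = np.asarray(self.A, float)
        if not np.allclose(A, A.T, atol=1e-10):
            raise GraphError("adjacency must be symmetric")
        np.fill_diagonal(A, 0.0)
        self.A = A

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def binary(self) -> np.ndarray:
        return (self.A != 0).astype(float)

    @property
    def edge_count(self) -> int:
        return int(np.count_nonzero(np.triu(self.A, 1)))

    @property
    def pos_strength(self) -> np.ndarray:
        return np.maximum(self.A, 0.0).sum(axis=1)

    @property
    def neg_strength(self) -> np.ndarray:
        return np.maximum(-self.A, 0.0).sum(axis=1)

    @property
    def degree(self) -> np.ndarray:
        return self.binary.sum(axis=1).astype(int)

    def to_networkx(self, weighted: bool = True) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.node_labels)
        iu = np.triu_indices(self.n_nodes, 1)
        for i, j in zip(*iu):
            if self.A[i, j] != 0:
                G.add_edge(
                    self.node_labels[i], self.node_labels[j],
                    weight=float(self.A[i, j]) if weighted else 1.0,
                )
        return G

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def to_edge_list(self) -> pd.DataFrame:
        iu = np.triu_indices(self.n_nodes, 1)
        mask = self.A[iu] != 0
        return pd.DataFrame(
            {
                "node_a": np.asarray(self.node_labels)[iu[0][mask]],
                "node_b": np.asarray(self.node_labels)[iu[1][mask]],
                "weight": self.A[iu][mask],
            }
        )


@dataclass
class GlobalMetrics:
    """Whole-graph topology at one density."""

    C: float
    L: float
    Q: float
    A: float
    sigma: float
    density: float
    coverage: float = 1.0  # fraction of nodes in the giant component
    assortativity_defined: bool = True
    A_newman: float = float("nan")
    C_random: float = float("nan")
    L_random: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "C": self.C, "L": self.L, "Q": self.Q, "A": self.A,
            "sigma": self.sigma, "density": self.density,
            "coverage": self.coverage,
            "assortativity_defined": self.assortativity_defined,
            "A_newman": self.A_newman,
            "C_random": self.C_random, "L_random": self.L_random,
        }


@dataclass
class NullEnsemble:
    """Metric distributions over shuffled-weight surrogate graphs."""

    metrics: dict[str, np.ndarray]  # name -> (R,) or (R, n) array
    n_realizations: int
    seed: int | None
    density: float | None = None
    node_labels: list[str] = field(default_factory=list)

    def mean(self, name: str) -> float:
        return float(np.nanmean(self.metrics[name]))

    def __contains__(self, name: str) -> bool:
        return name in self.metrics


def proportional_threshold(M: ConnectivityMatrix, density: float) -> ThresholdedGraph:
    """Keep the top floor(d * n(n-1)/2) off-diagonal entries by |z|.

    Signs are retained.  Ties in |z| are broken by (i, j) lexicographic
    order so the selection is deterministic.
    """
    if not (0 < density <= 1):
        raise GraphError(f"density must be in (0, 1], got {density}")
    n = M.n_nodes
    iu = np.triu_indices(n, 1)
    vals = M.Z[iu]
    k = int(np.floor(density * len(vals)))
    order = np.lexsort((iu[1], iu[0], -np.abs(vals)))
    keep = order[:k]
    A = np.zeros((n, n))
    A[iu[0][keep], iu[1][keep]] = vals[keep]
    A = A + A.T
    return ThresholdedGraph(A=A, density=density, node_labels=list(M.node_labels),
                            condition=M.condition)


def binary_clustering(G: ThresholdedGraph) -> float:
    """Mean binary clustering coefficient (degree < 2 nodes contribute 0)."""
    return float(nx.average_clustering(G.to_networkx(weighted=False)))


def characteristic_path_length(G: ThresholdedGraph) -> tuple[float, float]:
    """(mean shortest-path hops over giant-component pairs, coverage)."""
    g = G.to_networkx(weighted=False)
    if g.number_of_edges() == 0:
        raise GraphError("edgeless graph has no path length")
    giant = max(nx.connected_components(g), key=len)
    sub = g.subgraph(giant)
    L = nx.average_shortest_path_length(sub)
    return float(L), len(giant) / G.n_nodes


def neighbor_degree_assortativity(G: ThresholdedGraph) -> tuple[float, bool]:
    """Correlation across nodes of degree vs. mean neighbor degree.

    Returns (value, defined); undefined (NaN, False) when either variable
    has zero variance across the participating (degree > 0) nodes.
    """
    k = G.degree.astype(float)
    B = G.binary
    with np.errstate(invalid="ignore", divide="ignore"):
        mnd = (B @ k) / np.where(k > 0, k, np.nan)
    mask = k > 0
    kk, mm = k[mask], mnd[mask]
    if kk.size < 2 or np.std(kk) == 0 or np.std(mm) == 0:
        return float("nan"), False
    return float(np.corrcoef(kk, mm)[0, 1]), True


def global_metrics(
    G: ThresholdedGraph,
    partition=None,
    null: NullEnsemble | None = None,
) -> GlobalMetrics:
    """Compute the C / L / Q / A / sigma battery on one graph.

    ``partition`` (a :class:`~painnet.modules.ModularPartition` or a
    label array) supplies Q; ``null`` supplies the C_random / L_random
    means for sigma.  Either may be omitted (NaN in the result).
    """
    if G.edge_count == 0:
        raise GraphError("edgeless graph")
    C = binary_clustering(G)
    L, coverage = characteristic_path_length(G)
    A, a_def = neighbor_degree_assortativity(G)
    g = G.to_networkx(weighted=False)
    A_newman = float("nan")
    try:
        with np.errstate(invalid="ignore", divide="ignore"):
            A_newman = float(nx.degree_assortativity_coefficient(g))
    except (ValueError, ZeroDivisionError):
        pass
    Q = float("nan")
    if partition is not None:
        from .modules import signed_modularity_value

        labels = getattr(partition, "labels", partition)
        Q = signed_modularity_value(G, labels)
    sigma = float("nan")
    C_r = L_r = float("nan")
    if null is not None:
        if null.density is not None and G.density is not None and null.density != G.density:
            raise GraphError("null ensemble computed at a different density")
        C_r, L_r = null.mean("C"), null.mean("L")
        sigma = (C / C_r) / (L / L_r)
    return GlobalMetrics(
        C=C, L=L, Q=Q, A=A, sigma=sigma, density=G.density,
        coverage=coverage, assortativity_defined=a_def, A_newman=A_newman,
        C_random=C_r, L_random=L_r,
    )


def _shuffled(A: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = A.shape[0]
    iu = np.triu_indices(n, 1)
    vals = A[iu].copy()
    rng.shuffle(vals)
    S = np.zeros_like(A)
    S[iu] = vals
    return S + S.T


def random_equivalents(
    source: ThresholdedGraph | ConnectivityMatrix,
    n_realizations: int = 100,
    seed: int | None = None,
    density: float | None = None,
    include_modularity: bool = False,
    n_restarts: int = 10,
) -> NullEnsemble:
    """Shuffled-weight null ensemble with matched size and edge count.

    Each realization permutes the upper-triangle weights uniformly at
    random (preserving symmetry, node count, edge count and the weight
    multiset) and re-runs the metric battery.  When ``source`` is an
    unthresholded :class:`ConnectivityMatrix` the shuffled matrix is
    re-thresholded at ``density`` first, mirroring the study's
    shuffle-then-same-pipeline procedure (the edge count is identical
    either way, because shuffling preserves the weight multiset).

    Per-realization outputs: C, L, A, Q (optionally, via the signed
    optimizer with ``n_restarts`` restarts), per-node degree and
    betweenness, and total positive/negative strength.
    """
    if n_realizations < 1:
        raise GraphError("n_realizations must be >= 1")
    if isinstance(source, ThresholdedGraph):
        base, d = source.A, source.density
        labels = source.node_labels
        needs_threshold = False
    else:
        if density is None:
            raise GraphError("density required when shuffling a full matrix")
        base, d = source.Z.copy(), density
        np.fill_diagonal(base, 0.0)
        labels = source.node_labels
        needs_threshold = True
    rng = np.random.default_rng(seed)
    n = base.shape[0]
    out = {
        "C": np.empty(n_realizations),
        "L": np.empty(n_realizations),
        "A": np.empty(n_realizations),
        "degree": np.empty((n_realizations, n)),
        "betweenness": np.empty((n_realizations, n)),
        "pos_strength_total": np.empty(n_realizations),
        "neg_strength_total": np.empty(n_realizations),
        "edge_count": np.empty(n_realizations, dtype=int),
    }
    if include_modularity:
        out["Q"] = np.empty(n_realizations)
        from .modules import optimize_partition

    for r in range(n_realizations):
        S = _shuffled(base, rng)
        if needs_threshold:
            sm = ConnectivityMatrix(Z=S, node_labels=list(labels))
            g = proportional_threshold(sm, d)
        else:
            g = ThresholdedGraph(A=S, density=d, node_labels=list(labels))
        out["edge_count"][r] = g.edge_count
        out["C"][r] = binary_clustering(g)
        out["L"][r], _ = characteristic_path_length(g)
        out["A"][r], _ = neighbor_degree_assortativity(g)
        out["degree"][r] = g.degree
        gx = g.to_networkx(weighted=False)
        bc = nx.betweenness_centrality(gx, normalized=False)
        out["betweenness"][r] = [bc[lab] for lab in labels]
        out["pos_strength_total"][r] = g.pos_strength.sum()
        out["neg_strength_total"][r] = g.neg_strength.sum()
        if include_modularity:
            part = optimize_partition(g, n_restarts=n_restarts,
                                      seed=int(rng.integers(2**31)))
            out["Q"][r] = part.Q
    return NullEnsemble(
        metrics=out, n_realizations=n_realizations, seed=seed,
        density=d, node_labels=list(labels),
    )
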
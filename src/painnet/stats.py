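"""Permutation significance machinery and pain-vs-audio contrasts.

Significance of condition differences uses paired sign-flip
permutations: within-subject designs make each subject their own
control, so under the null hypothesis each subject's condition
difference is symmetric around zero and its sign can be flipped
independently.  P-values use the add-one estimator, so the smallest
attainable p is 1/(n_perm + 1); multiple testing is handled by
Benjamini-Hochberg FDR within each family (edges; global metrics;
modular link statistics) separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConditionContrast",
    "permutation_p",
    "fdr_bh",
    "paired_sign_flip_test",
    "compare_conditions",
]


def permutation_p(observed: float, null_values, two_sided: bool = False) -> float:
    """Add-one permutation p-value of an observed statistic.

    One-sided: fraction of null values >= observed.  Two-sided: based on
    absolute deviation from the null mean.
    """
    null = np.asarray(null_values, float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    if two_sided:
        mu = null.mean()
        extreme = np.abs(null - mu) >= np.abs(observed - mu) - 1e-12
    else:
        extreme = null >= observed - 1e-12
    return float((1 + extreme.sum()) / (1 + null.size))


def fdr_bh(p_values, alpha: float = 0.05) -> dict:
    """Benjamini-Hochberg step-up: reject flags and monotone q-values."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return {"reject": np.array([], bool), "q": np.array([])}
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return {"reject": reject, "q": q}


def _sign_null(D: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Null mean-difference distribution by per-subject sign flips.

    D: (n_subjects, n_stats); returns (n_perm, n_stats)."""
    n_sub = D.shape[0]
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    return signs @ D / n_sub


def paired_sign_flip_test(
    a, b, n_perm: int = 5000, seed: int | None = None, two_sided: bool = True
) -> dict:
    """Paired permutation test of mean(a - b) for one scalar statistic."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    D = (a - b)[:, None]
    obs = float(D.mean())
    rng = np.random.default_rng(seed)
    null = _sign_null(D, n_perm, rng)[:, 0]
    return {"delta": obs, "p": permutation_p(obs, null, two_sided=two_sided),
            "null_mean": float(null.mean())}


@dataclass
class ConditionContrast:
    """Edge-wise, global-metric and modular-link condition differences."""

    edges: pd.DataFrame  # node_a, node_b, delta_z, p, q, reject, direction
    global_metrics: pd.DataFrame  # metric, delta, p, q, reject
    link_stats: pd.DataFrame  # statistic, delta, p, q, reject
    n_perm: int = 0
    seed: int | None = None
    node_labels: list[str] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def delta_matrix(self) -> np.ndarray:
        n = len(self.node_labels)
        M = np.zeros((n, n))
        idx = {lab: i for i, lab in enumerate(self.node_labels)}
        for _, row in self.edges.iterrows():
            i, j = idx[row["node_a"]], idx[row["node_b"]]
            M[i, j] = M[j, i] = row["delta_z"]
        return M


def compare_conditions(
    pain_matrices,
    audio_matrices,
    n_perm: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
    global_pain: pd.DataFrame | None = None,
    global_audio: pd.DataFrame | None = None,
    link_pain: pd.DataFrame | None = None,
    link_audio: pd.DataFrame | None = None,
) -> ConditionContrast:
    """Paired pain-vs-audio contrast on edges (plus optional per-subject
    global metrics and modular link proportions).

    ``pain_matrices`` / ``audio_matrices``: subject-aligned lists (or
    subject-keyed dicts with identical keys) of Fisher-z
    :class:`~painnet.connectivity.ConnectivityMatrix` on the same node
    set.  Per edge: observed delta = mean paired z difference; the null
    flips each subject's condition labels independently (random sign of
    the paired difference); FDR across edges.  The optional per-subject
    DataFrames (columns = metric names, rows = subjects in the same
    order) run the same machinery per column, FDR within each family.
    """
    if isinstance(pain_matrices, dict) or isinstance(audio_matrices, dict):
        if set(pain_matrices) != set(audio_matrices):
            raise ValueError("conditions are not paired: subject sets differ")
        keys = sorted(pain_matrices)
        pain_matrices = [pain_matrices[k] for k in keys]
        audio_matrices = [audio_matrices[k] for k in keys]
    pain_matrices = list(pain_matrices)
    audio_matrices = list(audio_matrices)
    if len(pain_matrices) != len(audio_matrices) or not pain_matrices:
        raise ValueError("conditions are not paired: subject counts differ")
    labels = pain_matrices[0].node_labels
    for m in pain_matrices + audio_matrices:
        if m.node_labels != labels:
            raise ValueError("matrices disagree on the node set")
    n = len(labels)
    iu = np.triu_indices(n, 1)
    P = np.asarray([m.Z[iu] for m in pain_matrices])
    A = np.asarray([m.Z[iu] for m in audio_matrices])
    D = P - A  # (n_subjects, n_edges)
    obs = D.mean(axis=0)
    rng = np.random.default_rng(seed)
    null = _sign_null(D, n_perm, rng)  # (n_perm, n_edges)
    dev = np.abs(null - null.mean(axis=0))
    p = (1 + (dev >= np.abs(obs - null.mean(axis=0))[None, :] - 1e-12).sum(axis=0)) / (
        1 + n_perm
    )
    bh = fdr_bh(p, alpha=alpha)
    edges = pd.DataFrame(
        {
            "node_a": np.asarray(labels)[iu[0]],
            "node_b": np.asarray(labels)[iu[1]],
            "delta_z": obs,
            "p": p,
            "q": bh["q"],
            "reject": bh["reject"],
            "direction": np.where(obs > 0, "pain>audio", "pain<audio"),
        }
    )

    def family(df_a, df_b):
        if df_a is None or df_b is None:
            return pd.DataFrame(columns=["statistic", "delta", "p", "q", "reject"])
        rows = []
        for col in df_a.columns:
            res = paired_sign_flip_test(
                df_a[col], df_b[col], n_perm=n_perm,
                seed=int(rng.integers(2**31)), two_sided=True,
            )
            rows.append({"statistic": col, "delta": res["delta"], "p": res["p"]})
        fam = pd.DataFrame(rows)
        bhf = fdr_bh(fam["p"], alpha=alpha)
        fam["q"], fam["reject"] = bhf["q"], bhf["reject"]
        return fam

    return ConditionContrast(
        edges=edges,
        global_metrics=family(global_pain, global_audio),
        link_stats=family(link_pain, link_audio),
        n_perm=n_perm,
        seed=seed,
        node_labels=list(labels),
        alpha=alpha,
    )
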
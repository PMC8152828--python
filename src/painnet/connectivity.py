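"""Stimulation-weighted Pearson connectivity.

The study's bespoke step: instead of correlating whole sessions, each
time point is weighted by the (clamped) HRF-convolved stimulus
regressor, so volumes acquired while the evoked response is high
dominate the correlation and rest/undershoot volumes contribute little
or nothing.  Session correlation matrices are Fisher-z transformed and
averaged into one matrix per subject per condition, then (after density
thresholding) averaged across subjects into a group matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "StimulusWeights",
    "ConnectivityMatrix",
    "canonical_hrf",
    "stimulus_weights",
    "weighted_pearson",
    "weighted_corr_matrix",
    "fisher_z",
    "build_condition_matrix",
    "group_average",
]

_CLIP = 1.0 - 1e-7  # |r| clip before atanh


class ConnectivityError(ValueError):
    pass


@dataclass
class StimulusWeights:
    """Per-volume nonnegative correlation weights for one condition."""

    w: np.ndarray
    condition: str = ""
    session_id: str = ""
    usable: bool = True  # False when the weight vector is all-zero

    def __post_init__(self):
        self.w = np.asarray(self.w, float)
        if np.any(self.w < 0):
            raise ConnectivityError("weights must be nonnegative")
        if self.w.sum() <= 0:
            self.usable = False


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity matrix (diagonal unused, kept 0)."""

    Z: np.ndarray
    node_labels: list[str]
    condition: str = ""
    level: str = "session"  # session | subject | group
    density: float | None = None  # set once thresholded

    def __post_init__(self):
        Z = np.asarray(self.Z, float)
        if Z.ndim != 2 or Z.shape[0] != Z.shape[1]:
            raise ConnectivityError("Z must be square")
        if not np.allclose(Z, Z.T, atol=1e-10):
            raise ConnectivityError("Z must be symmetric")
        off = Z[~np.eye(Z.shape[0], dtype=bool)]
        if not np.isfinite(off).all():
            raise ConnectivityError("off-diagonal entries must be finite")
        self.Z = Z

    @property
    def r(self) -> np.ndarray:
        """Correlation-scale view, tanh(Z)."""
        return np.tanh(self.Z)

    @property
    def n_nodes(self) -> int:
        return self.Z.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Z, index=self.node_labels, columns=self.node_labels)

    def write(self, path) -> None:
        self.to_frame().to_csv(path)

    def to_edge_list(self) -> pd.DataFrame:
        iu = np.triu_indices(self.n_nodes, 1)
        return pd.DataFrame(
            {
                "node_a": [self.node_labels[i] for i in iu[0]],
                "node_b": [self.node_labels[j] for j in iu[1]],
                "z": self.Z[iu],
            }
        )


def canonical_hrf(TR: float, length: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled every TR.

    h(t) = g(t; 6, 1) - g(t; 16, 1) / 6 with g a gamma density (response
    peaking near 5 s plus a slower negative undershoot), sampled at
    t = 0, TR, 2 TR, ... length, peak-normalized to 1.
    """
    if TR <= 0:
        raise ValueError("TR must be positive")
    t = np.arange(0.0, length + TR / 2, TR)
    h = sp_stats.gamma.pdf(t, a=6.0, scale=1.0) - sp_stats.gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    return h / h.max()


def stimulus_weights(design, TR: float | None = None, n_volumes: int | None = None) -> StimulusWeights:
    """Clamped HRF-convolved boxcar of a stimulus design.

    Boxcar is 1 for volumes within [onset, onset + duration) at volume
    resolution, convolved with the canonical HRF; negative values
    (undershoot) are clamped to 0 so only the "positive and null" part
    of the regressor weights the correlation.  An empty design yields
    all-zero weights flagged unusable.
    """
    TR = design.TR if TR is None else TR
    n_volumes = design.n_volumes if n_volumes is None else n_volumes
    t = np.arange(n_volumes) * TR
    box = np.zeros(n_volumes)
    for onset, dur in zip(design.onsets, design.durations):
        if onset + dur > n_volumes * TR + 1e-9:
            raise ConnectivityError("design extends beyond the requested volume count")
        box[(t >= onset) & (t < onset + dur)] = 1.0
    reg = np.convolve(box, canonical_hrf(TR))[:n_volumes]
    w = np.maximum(reg, 0.0)
    return StimulusWeights(w=w, condition=design.condition, session_id=design.session_id)


def _weighted_moments(X: np.ndarray, w: np.ndarray):
    wn = w / w.sum()
    m = X @ wn
    Xc = X - m[:, None]
    cov = (Xc * wn) @ Xc.T
    var = np.diag(cov).copy()
    return cov, var


def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation of two series.

    r = cov_w(x, y) / sqrt(var_w(x) var_w(y)) with weighted means
    m_x = sum w_t x_t / sum w_t.  Invariant to positive rescaling of w;
    reduces to the ordinary Pearson r for uniform weights.
    """
    wv = w.w if isinstance(w, StimulusWeights) else np.asarray(w, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if not (len(x) == len(y) == len(wv)):
        raise ConnectivityError("x, y, w must have equal length")
    if wv.sum() <= 0:
        raise ConnectivityError("sum of weights must be positive")
    cov, var = _weighted_moments(np.vstack([x, y]), wv)
    for k, nm in ((0, "x"), (1, "y")):
        if var[k] <= 0:
            raise ConnectivityError(f"zero weighted variance for series {nm}")
    return float(cov[0, 1] / np.sqrt(var[0] * var[1]))


def weighted_corr_matrix(X: np.ndarray, w, node_labels: list[str] | None = None) -> np.ndarray:
    """All-pairs weighted Pearson correlations of the rows of X."""
    wv = w.w if isinstance(w, StimulusWeights) else np.asarray(w, float)
    if wv.sum() <= 0:
        raise ConnectivityError("sum of weights must be positive")
    cov, var = _weighted_moments(np.asarray(X, float), wv)
    bad = np.where(var <= 0)[0]
    if bad.size:
        names = [node_labels[i] for i in bad] if node_labels else list(bad)
        raise ConnectivityError(f"zero weighted variance for node(s): {names}")
    s = np.sqrt(var)
    R = cov / np.outer(s, s)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clipped to 1 - 1e-7 (warns on clipping)."""
    r = np.asarray(r, float)
    if np.any(np.abs(r) >= _CLIP):
        warnings.warn("|r| = 1 encountered; clipping before Fisher z", stacklevel=2)
    return np.arctanh(np.clip(r, -_CLIP, _CLIP))


def build_condition_matrix(
    sessions,
    weights,
    condition: str,
    combine: str = "mean_z",
) -> ConnectivityMatrix:
    """Subject-level Fisher-z matrix for one condition.

    Parameters
    ----------
    sessions
        Cleaned sessions (objects with ``X`` and ``node_labels``).
    weights
        Matching list of :class:`StimulusWeights`; unusable (all-zero)
        entries are skipped.
    combine
        ``"mean_z"`` (default): per-session weighted r -> Fisher z ->
        arithmetic mean across sessions.  ``"concat"``: weighted
        correlation of the weight-concatenated sessions, then Fisher z.
    """
    usable = [(s, wt) for s, wt in zip(sessions, weights) if wt.usable]
    if not usable:
        raise ConnectivityError(f"no session with usable weights for condition {condition!r}")
    labels = list(usable[0][0].node_labels)
    if combine == "mean_z":
        zs = []
        for s, wt in usable:
            R = weighted_corr_matrix(s.X, wt, labels)
            np.fill_diagonal(R, 0.0)  # diagonal excluded downstream
            zs.append(fisher_z(R))
        Z = np.mean(zs, axis=0)
    elif combine == "concat":
        X = np.hstack([s.X for s, _ in usable])
        wv = np.concatenate([wt.w for _, wt in usable])
        R = weighted_corr_matrix(X, wv, labels)
        np.fill_diagonal(R, 0.0)
        Z = fisher_z(R)
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    Z = (Z + Z.T) / 2.0
    return ConnectivityMatrix(Z=Z, node_labels=labels, condition=condition, level="subject")


def group_average(matrices) -> ConnectivityMatrix:
    """Entry-wise mean of thresholded subject matrices.

    All inputs must share node order and density (edges removed by the
    threshold are zero-filled, so an edge surviving in a subset of
    subjects is down-weighted accordingly).
    """
    mats = list(matrices)
    if not mats:
        raise ConnectivityError("no matrices to average")
    labels = mats[0].node_labels
    dens = mats[0].density
    for m in mats[1:]:
        if m.node_labels != labels:
            raise ConnectivityError("node order differs between matrices")
        if m.density != dens:
            raise ConnectivityError(
                f"mixed densities in group average: {m.density} vs {dens}"
            )
    Z = np.mean([m.Z for m in mats], axis=0)
    return ConnectivityMatrix(
        Z=Z, node_labels=list(labels), condition=mats[0].condition,
        level="group", density=dens,
    )
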
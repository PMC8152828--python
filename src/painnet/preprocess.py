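"""Nuisance regression, high-pass filtering and per-session standardization.

Each node's series is replaced by its least-squares residual against a
joint design of (intercept + confound columns + discrete-cosine drift
regressors up to the cutoff frequency), then z-scored.  Doing the
confound regression and the high-pass filter in one projection makes the
two steps order-invariant and exactly reproducible; the DCT drift basis
matches the SPM convention (one cosine per drift period longer than
1/cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synth import SessionTimeSeries

__all__ = ["CleanTimeSeries", "clean_timeseries", "dct_drift_basis"]


class PreprocessError(ValueError):
    pass


@dataclass
class CleanTimeSeries:
    """Standardized residual series (per node: mean 0, SD 1)."""

    X: np.ndarray  # (n_nodes, n_volumes), unitless
    TR: float
    node_labels: list[str]
    provenance: dict = field(default_factory=dict)
    designs: dict = field(default_factory=dict)
    subject_id: str = ""
    session_id: str = ""

    @property
    def n_volumes(self) -> int:
        return self.X.shape[1]


def dct_drift_basis(n_volumes: int, TR: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine drift regressors spanning periods > 1/cutoff_hz.

    Returns a (n_volumes, K) matrix with columns
    cos(pi * k * (2t + 1) / (2 N)), k = 1..K, K = floor(2 N TR cutoff).
    The constant (k = 0) term is excluded; the intercept covers it.
    """
    total_s = n_volumes * TR
    K = int(np.floor(2.0 * total_s * cutoff_hz))
    K = min(K, n_volumes - 1)
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_volumes)) for k in range(1, K + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


def clean_timeseries(
    ts: SessionTimeSeries, cutoff_hz: float = 0.01
) -> CleanTimeSeries:
    """Regress confounds + drift out of every node series and z-score.

    Raises :class:`PreprocessError` on a rank-deficient regressor matrix
    (naming the collinear columns) or on a zero-variance residual
    (naming the node).
    """
    X = np.asarray(ts.X, float)
    n_nodes, n_vol = X.shape
    conf = np.asarray(ts.confounds, float)
    if conf.size and conf.shape[1] != n_vol:
        raise PreprocessError("confound matrix volume count does not match X")
    drift = dct_drift_basis(n_vol, ts.TR, cutoff_hz)
    names = (
        ["intercept"]
        + [f"confound_{i}" for i in range(conf.shape[0])]
        + [f"dct_{k + 1}" for k in range(drift.shape[1])]
    )
    R = np.column_stack([np.ones(n_vol), conf.T, drift])
    if R.shape[1] >= n_vol:
        raise PreprocessError(
            f"{R.shape[1]} regressors for {n_vol} volumes: underdetermined fit"
        )
    rank = np.linalg.matrix_rank(R)
    if rank < R.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j in range(R.shape[1]):
            keep = [c for c in range(R.shape[1]) if c != j]
            if np.linalg.matrix_rank(R[:, keep]) == rank:
                collinear.append(names[j])
        raise PreprocessError(f"rank-deficient regressor matrix; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(R, X.T, rcond=None)
    resid = X - (R @ beta).T
    sd = resid.std(axis=1)
    dead = np.where(sd < 1e-12 * max(X.std(), 1e-30))[0]
    if dead.size:
        bad = [ts.node_labels[i] for i in dead]
        raise PreprocessError(f"zero-variance residual for node(s): {bad}")
    Z = (resid - resid.mean(axis=1, keepdims=True)) / sd[:, None]
    return CleanTimeSeries(
        X=Z,
        TR=ts.TR,
        node_labels=list(ts.node_labels),
        provenance={
            "steps": ["confound_regression+dct_highpass (joint OLS)", "zscore"],
            "cutoff_hz": cutoff_hz,
            "n_confounds": int(conf.shape[0]),
            "n_dct": int(drift.shape[1]),
        },
        designs=dict(ts.designs),
        subject_id=ts.subject_id,
        session_id=ts.session_id,
    )
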
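"""Synthetic BOLD cohorts with a planted modular correlation structure.

Every downstream stage (cleaning, stimulation-weighted connectivity,
thresholding, modular decomposition, hub detection, condition contrasts)
is exercised on cohorts produced here, since the original scan data are
not public.  The generator emulates the two acquisition designs used in
the study:

* ``group1`` — 5 sessions x 220 volumes at TR 2.2 s, 12 heat-pain
  stimuli of 15 s per session plus 8 auditory stimuli of 10-50 s;
* ``group2`` — 3 sessions x 205 volumes at TR 2.56 s, 12 heat-pain
  stimuli of 25 s, no audio.

Signal model per node i in module m (all latents unit variance):

    x_i(t) = sqrt(b) g(t) + sqrt(w - b) l_m(t) alpha(t)
             + noise_sd * sqrt(1 - w) e_i(t)
             + sum_c gain[c, m] r_c(t) + loadings_i . confounds(t)

with g a global latent, l_m a module latent, e_i node-unique noise,
r_c the HRF-convolved stimulus regressor of condition c, and
(w, b) = (within_r, between_r) the target latent correlations.
alpha(t) = 1 + sum_c coupling_gain[c] * r_c(t)/max(r_c) amplifies
module coupling during stimulation — the stimulus-locked connectivity
that stimulation-weighted correlation is designed to pick up.  With
alpha = 1 and noise_sd = 1 the latent part of two same-module nodes
correlates at within_r and two nodes from different modules at
between_r, exactly in expectation; with noise_sd = 0 same-module nodes
are identical copies.  Latents follow an AR(1) process (rho = 0.3) to
mimic BOLD temporal autocorrelation; a white-noise alternative is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .connectivity import canonical_hrf
from .roi import ROITable

__all__ = [
    "StimulusDesign",
    "GroundTruth",
    "SessionTimeSeries",
    "CohortPreset",
    "PRESETS",
    "generate_design",
    "generate_interleaved_designs",
    "generate_cohort",
    "write_session",
    "read_session",
]

AR_RHO = 0.3  # lag-1 autocorrelation of the latent signals


class DesignError(ValueError):
    """Raised when a stimulus train cannot be packed into a session."""


@dataclass(frozen=True)
class StimulusDesign:
    """Event train of one condition within one session."""

    condition: str
    onsets: tuple[float, ...]  # seconds
    durations: tuple[float, ...]  # seconds
    TR: float
    n_volumes: int
    session_id: str = ""

    def __post_init__(self):
        on = np.asarray(self.onsets, float)
        du = np.asarray(self.durations, float)
        if on.size != du.size:
            raise DesignError("onsets and durations differ in length")
        if on.size and np.any(np.diff(on) <= 0):
            raise DesignError("onsets must be strictly increasing")
        if on.size and np.any(on + du > self.n_volumes * self.TR + 1e-9):
            raise DesignError("a stimulus extends beyond the session end")

    @property
    def session_seconds(self) -> float:
        return self.n_volumes * self.TR


@dataclass(frozen=True)
class GroundTruth:
    """Planted statistical structure of a synthetic cohort."""

    partition: dict[str, str]  # node label -> module name
    within_r: float = 0.6
    between_r: float = 0.1
    stim_gain: dict[str, dict[str, float]] = field(default_factory=dict)
    # per-node overrides of the module gain, keyed by condition
    node_gain: dict[str, dict[str, float]] = field(default_factory=dict)
    # stimulus-dependent coupling: module-latent amplitude is multiplied by
    # (1 + coupling_gain[c] * normalized evoked regressor of condition c),
    # so within-module connectivity strengthens during stimulation; the
    # per-condition entry is a scalar (all modules) or a module -> gain dict
    coupling_gain: dict[str, float | dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    confound_scale: float = 0.1
    ar_latents: bool = True
    seed: int | None = None

    def __post_init__(self):
        if not (self.within_r > self.between_r >= 0):
            raise ValueError(
                f"need within_r > between_r >= 0, got "
                f"({self.within_r}, {self.between_r})"
            )
        if self.within_r > 1:
            raise ValueError("within_r must be <= 1")

    def module_of(self, label: str) -> str:
        return self.partition[label]


@dataclass
class SessionTimeSeries:
    """Node x volume signal matrix with its designs and confounds."""

    X: np.ndarray  # (n_nodes, n_volumes)
    TR: float
    designs: dict[str, StimulusDesign]
    confounds: np.ndarray  # (n_confounds, n_volumes)
    node_labels: list[str]
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self):
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (nodes x volumes)")
        if self.confounds.shape[1] != self.X.shape[1]:
            raise ValueError("confounds and X disagree on volume count")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class CohortPreset:
    """Acquisition + stimulation parameters of one study group."""

    name: str
    TR: float
    n_volumes: int
    n_sessions: int
    n_subjects: int
    pain_n_stimuli: int
    pain_duration: float
    audio_n_stimuli: int = 0
    audio_duration_range: tuple[float, float] = (10.0, 50.0)
    isi_range: tuple[float, float] = (12.0, 20.0)
    # gap between consecutive events when pain and audio streams are
    # interleaved on one timeline (the packed group-1 sessions)
    interleave_gap: tuple[float, float] = (1.0, 4.0)


# The two acquisition designs of the study (main and validation cohorts).
PRESETS: dict[str, CohortPreset] = {
    "group1": CohortPreset(
        name="group1", TR=2.2, n_volumes=220, n_sessions=5, n_subjects=36,
        pain_n_stimuli=12, pain_duration=15.0, audio_n_stimuli=8,
    ),
    "group2": CohortPreset(
        name="group2", TR=2.56, n_volumes=205, n_sessions=3, n_subjects=24,
        pain_n_stimuli=12, pain_duration=25.0, audio_n_stimuli=0,
    ),
}


def default_ground_truth(partition: dict[str, str], seed: int | None = None) -> GroundTruth:
    """Study-condition defaults: strong sensorimotor pain response, weak
    limbic engagement, auditory cortex driven mainly by audio."""
    modules = sorted(set(partition.values()))
    pain = {m: 0.6 for m in modules}
    pain.update({"SM": 1.0, "limbic": 0.2, "auditory": 0.2})
    audio = {m: 0.5 for m in modules}
    audio.update({"SM": 0.3})
    node_gain = {
        "pain": {"A1_left": 0.2, "A1_right": 0.2},
        "audio": {"A1_left": 1.5, "A1_right": 1.5},
    }
    pain_c: dict[str, float] = {m: 2.0 for m in modules}
    audio_c: dict[str, float] = {m: 1.0 for m in modules}
    if "auditory" in pain_c:  # A1 couples with sound, barely with pain
        pain_c["auditory"] = 0.2
        audio_c["auditory"] = 2.5
    return GroundTruth(
        partition=dict(partition),
        stim_gain={"pain": pain, "audio": audio},
        node_gain=node_gain,
        coupling_gain={"pain": pain_c, "audio": audio_c},
        seed=seed,
    )


def _max_feasible_count(duration_max: float, isi_min: float, session_s: float) -> int:
    per = duration_max + isi_min
    return max(int(session_s // per), 0)


def generate_design(
    condition: str,
    n_stimuli: int,
    duration: float | tuple[float, float],
    isi_range: tuple[float, float],
    TR: float,
    n_volumes: int,
    seed: int | np.random.Generator | None = None,
    session_id: str = "",
    max_tries: int = 1000,
) -> StimulusDesign:
    """Draw an event train with inter-stimulus intervals uniform in
    ``isi_range`` (the interval before the first stimulus is drawn from
    the same range).

    ``duration`` may be a scalar or a (low, high) range sampled per
    stimulus (used for the variable-length auditory phrases).
    Deterministic given ``seed``.  Raises :class:`DesignError`, reporting
    the maximal feasible stimulus count, when the train cannot fit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    session_s = n_volumes * TR
    if n_stimuli == 0:
        return StimulusDesign(condition, (), (), TR, n_volumes, session_id)
    lo, hi = isi_range
    dur_min = duration if np.isscalar(duration) else duration[0]
    if n_stimuli * (dur_min + lo) > session_s:
        raise DesignError(
            f"{n_stimuli} stimuli of >= {dur_min} s with ISI >= {lo} s do not "
            f"fit in {session_s:.1f} s; at most "
            f"{_max_feasible_count(dur_min, lo, session_s)} fit"
        )
    for _ in range(max_tries):
        isis = rng.uniform(lo, hi, size=n_stimuli)
        if np.isscalar(duration):
            durs = np.full(n_stimuli, float(duration))
        else:
            durs = rng.uniform(duration[0], duration[1], size=n_stimuli)
        onsets = np.cumsum(isis) + np.concatenate([[0.0], np.cumsum(durs[:-1])])
        if onsets[-1] + durs[-1] <= session_s:
            return StimulusDesign(
                condition, tuple(onsets), tuple(durs), TR, n_volumes, session_id
            )
    raise DesignError(
        f"could not pack {n_stimuli} {condition} stimuli into {session_s:.1f} s "
        f"after {max_tries} draws; at most "
        f"{_max_feasible_count(dur_min, lo, session_s)} are reliably feasible"
    )


def generate_interleaved_designs(
    n_pain: int,
    pain_duration: float,
    n_audio: int,
    audio_duration_range: tuple[float, float],
    gap_range: tuple[float, float],
    TR: float,
    n_volumes: int,
    seed: int | np.random.Generator | None = None,
    session_id: str = "",
    max_tries: int = 1000,
) -> dict[str, StimulusDesign]:
    """Pain and audio event trains interleaved on one non-overlapping
    timeline (events in shuffled order, short gaps between consecutive
    events), emulating the packed sessions where auditory phrases are
    intermingled with the heat stimuli but separated in time from them.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    session_s = n_volumes * TR
    kinds = np.array(["pain"] * n_pain + ["audio"] * n_audio)
    for _ in range(max_tries):
        order = rng.permutation(len(kinds))
        seq = kinds[order]
        durs = np.where(
            seq == "pain",
            pain_duration,
            rng.uniform(*audio_duration_range, size=len(seq)),
        )
        gaps = rng.uniform(*gap_range, size=len(seq))
        onsets = np.cumsum(gaps) + np.concatenate([[0.0], np.cumsum(durs[:-1])])
        if onsets[-1] + durs[-1] > session_s:
            continue
        out = {}
        for cond in ("pain", "audio"):
            mask = seq == cond
            if mask.any():
                out[cond] = StimulusDesign(
                    cond, tuple(onsets[mask]), tuple(durs[mask]),
                    TR, n_volumes, session_id,
                )
        return out
    raise DesignError(
        f"could not interleave {n_pain} pain + {n_audio} audio stimuli into "
        f"{session_s:.1f} s after {max_tries} draws"
    )


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Unit-variance AR(1) series (stationary start via burn-in)."""
    burn = 100
    eps = rng.standard_normal(n + burn) * np.sqrt(1.0 - rho * rho)
    x = sp_signal.lfilter([1.0], [1.0, -rho], eps)
    return x[burn:]


def _latent(rng: np.random.Generator, n: int, ar: bool) -> np.ndarray:
    return _ar1(rng, n, AR_RHO) if ar else rng.standard_normal(n)


def _confounds(rng: np.random.Generator, n_volumes: int, TR: float) -> np.ndarray:
    """8 nuisance series: 6 motion-like drifts + WM-like + CSF-like.

    Motion-like regressors are random walks low-pass filtered below
    0.005 Hz; WM/CSF-like regressors are AR(1).  All standardized.
    """
    fs = 1.0 / TR
    sos = sp_signal.butter(2, min(0.005 / (fs / 2), 0.99), output="sos")
    rows = []
    for _ in range(6):
        walk = np.cumsum(rng.standard_normal(n_volumes))
        rows.append(sp_signal.sosfiltfilt(sos, walk))
    for _ in range(2):
        rows.append(_ar1(rng, n_volumes, 0.5))
    C = np.asarray(rows)
    C = C - C.mean(axis=1, keepdims=True)
    sd = C.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return C / sd


def _evoked_regressor(design: StimulusDesign) -> np.ndarray:
    """HRF-convolved boxcar at volume resolution (not clamped)."""
    n, TR = design.n_volumes, design.TR
    box = np.zeros(n)
    t = np.arange(n) * TR
    for onset, dur in zip(design.onsets, design.durations):
        box[(t >= onset) & (t < onset + dur)] = 1.0
    h = canonical_hrf(TR)
    return np.convolve(box, h)[:n]


def generate_cohort(
    roi_table: ROITable,
    ground_truth: GroundTruth,
    n_subjects: int | None = None,
    n_sessions: int | None = None,
    preset: CohortPreset | str = "group1",
    seed: int | None = None,
) -> tuple[dict[str, list[SessionTimeSeries]], GroundTruth]:
    """Simulate a cohort of session time series.

    Returns ``(cohort, ground_truth)`` where ``cohort`` maps subject ids
    (``"sub-01"`` ...) to their sessions.  Fully determined by ``seed``
    (which overrides ``ground_truth.seed`` when given).
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    labels = roi_table.labels
    missing = [lab for lab in labels if lab not in ground_truth.partition]
    if missing:
        raise ValueError(f"ground truth partition lacks nodes: {missing}")
    n_subjects = preset.n_subjects if n_subjects is None else n_subjects
    n_sessions = preset.n_sessions if n_sessions is None else n_sessions
    if seed is None:
        seed = ground_truth.seed
    gt = replace(ground_truth, seed=seed)

    master = np.random.SeedSequence(seed)
    sub_seeds = master.spawn(n_subjects)
    modules = sorted(set(gt.partition[lab] for lab in labels))
    mod_index = {m: k for k, m in enumerate(modules)}
    node_mod = np.array([mod_index[gt.partition[lab]] for lab in labels])
    n_nodes = len(labels)

    w, b = gt.within_r, gt.between_r
    c_g, c_m = np.sqrt(b), np.sqrt(w - b)
    c_e = gt.noise_sd * np.sqrt(1.0 - w)

    conditions = ["pain"]
    if preset.audio_n_stimuli > 0:
        conditions.append("audio")

    cohort: dict[str, list[SessionTimeSeries]] = {}
    for s in range(n_subjects):
        sub_id = f"sub-{s + 1:02d}"
        rng = np.random.default_rng(sub_seeds[s])
        # per-subject jitter of the evoked amplitudes (module x condition)
        jitter = {
            c: {m: max(rng.normal(1.0, 0.15), 0.0) for m in modules}
            for c in conditions
        }
        loadings = rng.normal(0.0, gt.confound_scale, size=(n_nodes, 8))
        sessions = []
        for k in range(n_sessions):
            ses_id = f"ses-{k + 1:02d}"
            if preset.audio_n_stimuli > 0:
                designs = generate_interleaved_designs(
                    preset.pain_n_stimuli, preset.pain_duration,
                    preset.audio_n_stimuli, preset.audio_duration_range,
                    preset.interleave_gap, preset.TR, preset.n_volumes,
                    seed=rng, session_id=ses_id,
                )
            else:
                designs = {"pain": generate_design(
                    "pain", preset.pain_n_stimuli, preset.pain_duration,
                    preset.isi_range, preset.TR, preset.n_volumes,
                    seed=rng, session_id=ses_id,
                )}
            nv = preset.n_volumes
            g = _latent(rng, nv, gt.ar_latents)
            lat = np.asarray([_latent(rng, nv, gt.ar_latents) for _ in modules])
            eps = rng.standard_normal((n_nodes, nv))
            regs = {c: _evoked_regressor(d) for c, d in designs.items()}
            # stimulus-locked coupling modulation, per module
            alpha = np.ones((len(modules), nv))
            for cond, reg in regs.items():
                cg = gt.coupling_gain.get(cond, 0.0)
                if reg.max() <= 0:
                    continue
                regn = np.maximum(reg, 0.0) / reg.max()
                for mi, mname in enumerate(modules):
                    gamma = cg.get(mname, 0.0) if isinstance(cg, dict) else cg
                    if gamma:
                        alpha[mi] += gamma * regn
            X = c_g * g[None, :] + c_m * lat[node_mod] * alpha[node_mod] + c_e * eps
            for cond, design in designs.items():
                reg = regs[cond]
                gains = np.array([
                    gt.node_gain.get(cond, {}).get(
                        lab,
                        gt.stim_gain.get(cond, {}).get(gt.partition[lab], 0.0),
                    ) * jitter[cond][gt.partition[lab]]
                    for lab in labels
                ])
                X = X + gains[:, None] * reg[None, :]
            conf = _confounds(rng, nv, preset.TR)
            X = X + loadings @ conf
            sessions.append(SessionTimeSeries(
                X=X, TR=preset.TR, designs=designs, confounds=conf,
                node_labels=list(labels), subject_id=sub_id, session_id=ses_id,
            ))
        cohort[sub_id] = sessions
    return cohort, gt


# ---------------------------------------------------------------------------
# On-disk layout (BIDS-events-flavoured TSV trio per session)

def write_session(ts: SessionTimeSeries, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{ts.subject_id}_{ts.session_id}"
    paths = {
        "timeseries": out_dir / f"{stem}_timeseries.tsv",
        "events": out_dir / f"{stem}_events.tsv",
        "confounds": out_dir / f"{stem}_confounds.tsv",
    }
    pd.DataFrame(ts.X, index=ts.node_labels).to_csv(paths["timeseries"], sep="\t")
    rows = []
    for cond, d in ts.designs.items():
        for onset, dur in zip(d.onsets, d.durations):
            rows.append({"onset": onset, "duration": dur, "trial_type": cond})
    events = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
    events.sort_values("onset", inplace=True, kind="stable")
    events.to_csv(paths["events"], sep="\t", index=False)
    conf = pd.DataFrame(
        ts.confounds.T,
        columns=[f"motion_{i}" for i in range(6)] + ["wm", "csf"],
    )
    conf.to_csv(paths["confounds"], sep="\t", index=False)
    return paths


def read_session(
    timeseries_path: str | Path, TR: float,
    events_path: str | Path | None = None,
    confounds_path: str | Path | None = None,
    subject_id: str = "", session_id: str = "",
) -> SessionTimeSeries:
    tdf = pd.read_csv(timeseries_path, sep="\t", index_col=0)
    X = tdf.to_numpy(float)
    n_vol = X.shape[1]
    designs: dict[str, StimulusDesign] = {}
    if events_path is not None:
        ev = pd.read_csv(events_path, sep="\t")
        for cond, grp in ev.groupby("trial_type"):
            grp = grp.sort_values("onset")
            designs[str(cond)] = StimulusDesign(
                str(cond), tuple(grp["onset"]), tuple(grp["duration"]),
                TR, n_vol, session_id,
            )
    if confounds_path is not None:
        conf = pd.read_csv(confounds_path, sep="\t").to_numpy(float).T
    else:
        conf = np.empty((0, n_vol))
    return SessionTimeSeries(
        X=X, TR=TR, designs=designs, confounds=conf,
        node_labels=[str(i) for i in tdf.index],
        subject_id=subject_id, session_id=session_id,
    )
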
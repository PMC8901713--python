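"""Mouse-trajectory preprocessing, metrics and macro-state analysis.

Raw cursor traces are reduced to actual motion, time-normalized to 101
points by linear interpolation, and spatially aligned so every
trajectory runs from (0, 0) to (1, 1) via the per-coordinate affine map

    c' = (c - c_t0) / (c_T - c_t0) * (c_end - c_start) + c_start.

Per-trial metrics: area between the path and the ideal straight line
(AUC, shoelace), permutation entropy of each coordinate series
(Bandt-Pompe ordinal patterns, embedding dimension 5, delay 1,
normalized by log m!), direction changes (D), Euclidean path length (ED)
and mean velocity (V = ED / duration).

Macro-states are estimated by Gaussian mixture models on the pooled
(x, y) points, with the cluster count selected by AIC over k = 2..10
under the constraint that every cluster is present in every
participant's trajectories; the winning clusters are labeled by the mean
time index of their points (Initiation, Prediction, Evaluation,
Termination when k = 4) and summarized by transition matrices and dwell
times.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "RawTrajectory",
    "NormalizedTrajectory",
    "TrajectoryMetrics",
    "StateModel",
    "TrajectoryStateModel",
    "extract_motion",
    "time_normalize",
    "spatial_align",
    "auc",
    "permutation_entropy",
    "count_deviations",
    "kinematics",
    "compute_trajectory_metrics",
    "fit_state_model",
    "state_sequence",
    "transition_matrix",
    "dwell_time",
    "STATE_NAMES",
]

STATE_NAMES = ("Initiation", "Prediction", "Evaluation", "Termination")
N_GRID = 101


@dataclass
class RawTrajectory:
    """Time-stamped cursor samples of one trial."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class NormalizedTrajectory:
    """101-point trajectory aligned from (0, 0) to (1, 1)."""

    x: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != N_GRID or len(self.y) != N_GRID:
            raise ValueError(f"normalized trajectories have {N_GRID} points")

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class TrajectoryMetrics:
    auc: float
    pe_x: float
    pe_y: float
    d_x: int
    d_y: int
    ed: float
    v: float

    def as_dict(self) -> dict:
        return {"auc": self.auc, "pe_x": self.pe_x, "pe_y": self.pe_y,
                "d_x": self.d_x, "d_y": self.d_y, "ed": self.ed, "v": self.v}


# ---------------------------------------------------------------------------
# preprocessing

def extract_motion(raw: RawTrajectory, mode: str = "both") -> RawTrajectory:
    """Keep only samples where the cursor actually moved.

    ``mode='both'`` requires displacement on both coordinates since the
    previous kept-eligible sample position, ``'either'`` on at least
    one.  The first sample is always retained.  A trace with fewer than
    2 moving samples is degenerate and raises.
    """
    dx = np.diff(raw.x) != 0
    dy = np.diff(raw.y) != 0
    if mode == "both":
        moved = dx & dy
    elif mode == "either":
        moved = dx | dy
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = np.concatenate([[True], moved])
    if keep.sum() < 2:
        raise ValueError("trajectory has no usable motion")
    return RawTrajectory(raw.t[keep], raw.x[keep], raw.y[keep], dict(raw.meta))


def time_normalize(raw: RawTrajectory, n: int = N_GRID) -> RawTrajectory:
    """Linear interpolation onto ``n`` equally spaced times."""
    grid = np.linspace(raw.t[0], raw.t[-1], n)
    return RawTrajectory(grid, np.interp(grid, raw.t, raw.x),
                         np.interp(grid, raw.t, raw.y), dict(raw.meta))


def _affine(series: np.ndarray, start: float, end: float) -> np.ndarray:
    c0, cT = series[0], series[-1]
    if cT == c0:
        raise ValueError("degenerate coordinate: first and last samples equal")
    return (series - c0) / (cT - c0) * (end - start) + start


def spatial_align(
    raw: RawTrajectory,
    c_start: tuple[float, float] = (0.0, 0.0),
    c_end: tuple[float, float] = (1.0, 1.0),
) -> NormalizedTrajectory:
    """Affine alignment of both coordinates onto [start, end]."""
    if len(raw.x) != N_GRID:
        raw = time_normalize(raw)
    meta = dict(raw.meta)
    meta.setdefault("duration_ms", raw.duration)
    return NormalizedTrajectory(
        _affine(raw.x, c_start[0], c_end[0]),
        _affine(raw.y, c_start[1], c_end[1]),
        meta,
    )


# ---------------------------------------------------------------------------
# metrics

def auc(traj: NormalizedTrajectory, signed: bool = False) -> float:
    """Area enclosed between the path and the straight (0,0)-(1,1) line.

    Shoelace formula on the polygon closed by the ideal line; unsigned
    by default.
    """
    x = np.concatenate([traj.x, [traj.x[0]]])
    y = np.concatenate([traj.y, [traj.y[0]]])
    area = 0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])
    return float(area) if signed else float(abs(area))


def permutation_entropy(
    series: Sequence[float], m: int = 5, delay: int = 1, normalize: bool = True
) -> float:
    """Bandt-Pompe permutation entropy of a scalar series.

    Ordinal patterns of ``m`` consecutive (delay-spaced) samples, ties
    broken by order of appearance (stable argsort); Shannon entropy in
    nats, normalized by log(m!) when ``normalize``.
    """
    s = np.asarray(series, dtype=float)
    n_windows = len(s) - (m - 1) * delay
    if n_windows < 1:
        raise ValueError(f"series too short for m={m}, delay={delay}")
    idx = np.arange(n_windows)[:, None] + np.arange(m)[None, :] * delay
    windows = s[idx]
    patterns = np.argsort(windows, axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    h = float(-np.sum(p * np.log(p)))
    if normalize:
        h /= math.log(math.factorial(m))
    return h


def count_deviations(series: Sequence[float]) -> int:
    """Direction changes: sign flips of successive first differences.

    Zero differences are skipped (the previous sign carries over).
    """
    s = np.asarray(series, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 samples")
    signs = np.sign(np.diff(s))
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs) != 0))


def kinematics(traj: NormalizedTrajectory,
               duration_ms: Optional[float] = None) -> tuple[float, float]:
    """Path length (ED, normalized units) and mean velocity (V = ED / T)."""
    if duration_ms is None:
        duration_ms = traj.meta.get("duration_ms")
    if duration_ms is None or duration_ms <= 0:
        raise ValueError("a positive trial duration is required for velocity")
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    ed = float(steps.sum())
    return ed, ed / duration_ms


def compute_trajectory_metrics(
    traj: NormalizedTrajectory, m: int = 5, delay: int = 1
) -> TrajectoryMetrics:
    ed, v = kinematics(traj)
    return TrajectoryMetrics(
        auc=auc(traj),
        pe_x=permutation_entropy(traj.x, m, delay),
        pe_y=permutation_entropy(traj.y, m, delay),
        d_x=count_deviations(traj.x),
        d_y=count_deviations(traj.y),
        ed=ed,
        v=v,
    )


# ---------------------------------------------------------------------------
# macro-states

@dataclass
class StateModel:
    k: int
    means: np.ndarray
    covariances: np.ndarray
    weights: np.ndarray
    label_map: dict
    aic: float
    aic_table: dict
    _gmm: GaussianMixture = None

    def state_names(self) -> list[str]:
        return [self.label_map[c] for c in range(self.k)]


class TrajectoryStateModel:
    """AIC-selected Gaussian mixture over pooled trajectory points.

    sklearn-style estimator: ``fit`` pools the (x, y) points of all
    trajectories, fits full-covariance GMMs for each candidate k,
    disqualifies any k for which some participant lacks points hard-
    assigned to some cluster, and keeps the AIC minimizer.  ``predict``
    hard-labels points by maximum posterior responsibility.
    """

    def __init__(self, k_range: Sequence[int] = tuple(range(2, 11)),
                 tol: float = 1e-3, max_iter: int = 1000, seed: int = 0,
                 use_time_feature: bool = False):
        self.k_range = k_range
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed
        self.use_time_feature = use_time_feature

    def get_params(self, deep: bool = True) -> dict:
        return {"k_range": self.k_range, "tol": self.tol,
                "max_iter": self.max_iter, "seed": self.seed,
                "use_time_feature": self.use_time_feature}

    def set_params(self, **kw) -> "TrajectoryStateModel":
        for k, v in kw.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _features(self, trajs: Sequence[NormalizedTrajectory]) -> np.ndarray:
        feats = []
        for tr in trajs:
            f = tr.points
            if self.use_time_feature:
                f = np.column_stack([f, np.linspace(0, 1, N_GRID)])
            feats.append(f)
        return np.vstack(feats)

    def fit(self, trajs: Sequence[NormalizedTrajectory]) -> "TrajectoryStateModel":
        participants = {tr.meta.get("participant_id", 0) for tr in trajs}
        if len(participants) < 2:
            raise ValueError("state estimation needs at least 2 participants")
        X = self._features(trajs)
        part_index = {p: i for i, p in enumerate(sorted(participants, key=str))}
        part_of_point = np.concatenate([
            np.full(N_GRID, part_index[tr.meta.get("participant_id", 0)])
            for tr in trajs
        ])
        aic_table, disqualified, fitted = {}, {}, {}
        for k in self.k_range:
            gmm = GaussianMixture(n_components=k, covariance_type="full",
                                  tol=self.tol, max_iter=self.max_iter,
                                  random_state=self.seed)
            labels = gmm.fit_predict(X)
            aic_table[k] = float(gmm.aic(X))
            missing = []
            for p in np.unique(part_of_point):
                present = np.unique(labels[part_of_point == p])
                if len(present) < k:
                    missing.append(int(p))
            if missing:
                disqualified[k] = len(missing)
            else:
                fitted[k] = gmm
        if not fitted:
            raise ValueError(
                f"no candidate k qualified (participants missing clusters: "
                f"{disqualified})"
            )
        best_k = min(fitted, key=lambda k: aic_table[k])
        gmm = fitted[best_k]

        # label clusters by the mean time index of their assigned points
        labels = gmm.predict(X)
        t_index = np.tile(np.arange(N_GRID), len(trajs))
        mean_t = np.array([
            t_index[labels == c].mean() if (labels == c).any() else np.inf
            for c in range(best_k)
        ])
        order = np.argsort(mean_t)
        label_map = {}
        for rank, c in enumerate(order):
            if best_k == 4:
                label_map[int(c)] = STATE_NAMES[rank]
            else:
                label_map[int(c)] = f"state_{rank}"

        self.model_ = StateModel(
            k=best_k, means=gmm.means_, covariances=gmm.covariances_,
            weights=gmm.weights_, label_map=label_map,
            aic=aic_table[best_k], aic_table=aic_table, _gmm=gmm,
        )
        return self

    def predict(self, traj: NormalizedTrajectory) -> np.ndarray:
        X = self._features([traj])
        resp = self.model_._gmm.predict_proba(X)
        # posterior ties broken toward the larger mixture weight
        resp = resp + 1e-12 * self.model_.weights[None, :]
        return np.argmax(resp, axis=1)


def fit_state_model(
    trajs: Sequence[NormalizedTrajectory],
    k_range: Sequence[int] = tuple(range(2, 11)),
    tol: float = 1e-3,
    max_iter: int = 1000,
    seed: int = 0,
) -> StateModel:
    est = TrajectoryStateModel(k_range=k_range, tol=tol, max_iter=max_iter,
                               seed=seed)
    est.fit(trajs)
    model = est.model_
    model._estimator = est
    return model


def state_sequence(traj: NormalizedTrajectory, model: StateModel) -> np.ndarray:
    """Per-point hard state labels by maximum posterior responsibility."""
    est = getattr(model, "_estimator", None)
    if est is None:
        est = TrajectoryStateModel()
        est.model_ = model
    return est.predict(traj)


def transition_matrix(sequences: Sequence[np.ndarray], k: int) -> np.ndarray:
    """Row-stochastic k x k matrix of pooled consecutive-label transitions.

    Rows of states with no outgoing transitions are left as zeros (the
    caller can detect them by a zero row sum).
    """
    counts = np.zeros((k, k))
    for seq in sequences:
        seq = np.asarray(seq)
        np.add.at(counts, (seq[:-1], seq[1:]), 1)
    rowsums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(rowsums > 0, counts / rowsums, 0.0)
    return probs


def _run_lengths(seq: np.ndarray, state: int) -> list[int]:
    runs, current = [], 0
    for lab in seq:
        if lab == state:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def dwell_time(sequences: Sequence[np.ndarray], k: int) -> np.ndarray:
    """Mean dwell time per state (in grid samples).

    Run lengths are averaged within each trajectory and then across the
    trajectories containing the state; trajectories without the state do
    not contribute zeros.
    """
    per_state = [[] for _ in range(k)]
    for seq in sequences:
        seq = np.asarray(seq)
        for state in range(k):
            runs = _run_lengths(seq, state)
            if runs:
                per_state[state].append(float(np.mean(runs)))
    return np.array([float(np.mean(v)) if v else np.nan for v in per_state])


# ---------------------------------------------------------------------------
# table-level driver

def trajectories_from_table(
    samples: pd.DataFrame,
    meta: Optional[pd.DataFrame] = None,
    trial_col: str = "trial_id",
    t_col: str = "t_ms",
    x_col: str = "x",
    y_col: str = "y",
) -> list[RawTrajectory]:
    """Long (trial, t, x, y) table -> RawTrajectory list (meta joined by trial)."""
    meta_by_trial = {}
    if meta is not None:
        meta_by_trial = {row[trial_col]: row.to_dict()
                         for _, row in meta.iterrows()}
    out = []
    for trial, sub in samples.groupby(trial_col, sort=True):
        sub = sub.sort_values(t_col)
        m = dict(meta_by_trial.get(trial, {}))
        m.setdefault(trial_col, trial)
        out.append(RawTrajectory(sub[t_col].to_numpy(), sub[x_col].to_numpy(),
                                 sub[y_col].to_numpy(), m))
    return out


def preprocess_trajectories(
    raws: Sequence[RawTrajectory], mode: str = "both"
) -> list[NormalizedTrajectory]:
    """Motion extraction -> time normalization -> spatial alignment.

    Degenerate trials (no motion, or a coordinate with equal first and
    last samples) are dropped with a warning.
    """
    out = []
    for raw in raws:
        try:
            moved = extract_motion(raw, mode=mode)
            moved.meta.setdefault("duration_ms", moved.duration)
            out.append(spatial_align(time_normalize(moved)))
        except ValueError as exc:
            warnings.warn(
                f"trajectory {raw.meta.get('trial_id', '?')} dropped: {exc}")
    return out
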
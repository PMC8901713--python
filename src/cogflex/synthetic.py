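"""Synthetic two-condition datasets with the structure the pipeline assumes.

Raw data from experiments of this design are rarely public, so this
module generates stand-in datasets that emulate their statistical shape: free-response tables
whose binary participant x response incidence matrices have Zipf-like
response popularity and block co-occurrence structure with tunable
cross-condition overlap; 64-trial, 50%-congruent Stroop sessions drawn
from the conflict-diffusion generative process with known per-condition
parameters; 4-phase mouse trajectories sampled at 100 Hz; and paired
[0, 1] questionnaire ratings with planted per-item standardized mean
differences.

Condition effects are generative knobs, not copied effect sizes: the
default "DD" arm has denser/more homogeneous response co-occurrence, a
lower automatic-process amplitude and a higher trajectory wobble than
the default "OR" arm, encoding the condition contrasts this design is
built to detect.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dcm import DCMParams, simulate_session

__all__ = [
    "GenerationError",
    "ConditionParams",
    "SyntheticConfig",
    "gen_aut",
    "gen_stroop",
    "gen_trajectories",
    "gen_asc",
    "write_all",
]

# per-item planted standardized mean differences (DD minus OR) matching
# the questionnaire dimensions the pipeline compares
DEFAULT_ASC_EFFECTS = {
    "vivid": 0.45,
    "patterns": 1.79,
    "imagery": 2.63,
    "intensity": 0.46,
    "strange": 2.85,
    "space": 0.81,
    "muddle": 1.03,
    "spirit": 0.50,
}


class GenerationError(RuntimeError):
    """Raised when the requested parameters cannot produce usable data."""


@dataclass(frozen=True)
class ConditionParams:
    """Generative knobs of one condition arm.

    Trajectory scales are in normalized start-to-target units (the
    straight start-to-target path spans (0,0)-(1,1)).
    """

    popularity_exponent: float = 0.9   # Zipf exponent of response popularity
    block_mixing: float = 0.05         # prob. of responding outside own blocks
    core_rate: float = 0.0             # prob. of drawing from the shared
                                       # consensus core (top tokens)
    core_size: int = 12                # size of that consensus core
    dcm: DCMParams = field(default_factory=lambda: DCMParams(alpha=25.0))
    wobble_amplitude: float = 0.05     # evaluation-phase lateral scatter
    tremor_frac: float = 0.15          # white tremor as a fraction of blob
                                       # scatter (drives PE / direction changes)
    incongruent_pull: float = 0.05     # first-guess offset toward the distractor


# default contrasts: the DD arm has more
# homogeneous response co-occurrence (lower ASPL, higher S, larger
# percolation integral), a weaker automatic process and stronger tremor
DEFAULT_CONDITIONS = {
    "OR": ConditionParams(popularity_exponent=0.9, block_mixing=0.05,
                          dcm=DCMParams(alpha=25.0),
                          wobble_amplitude=0.05, tremor_frac=0.15),
    "DD": ConditionParams(popularity_exponent=1.2, block_mixing=0.35,
                          core_rate=0.5, core_size=18,
                          dcm=DCMParams(alpha=12.0),
                          wobble_amplitude=0.06, tremor_frac=0.50),
}


@dataclass
class SyntheticConfig:
    n_participants: int = 52
    vocab_size: int = 120
    n_blocks: int = 8
    responses_per_prompt: int = 6
    prompts_per_condition: int = 2
    overlap_rate: float = 0.85
    conditions: dict = field(default_factory=lambda: dict(DEFAULT_CONDITIONS))
    n_stroop_trials: int = 64
    congruent_share: float = 0.5
    trajectory_trials: int = 64
    sample_rate: float = 100.0
    trajectory_noise_sd: float = 0.004  # normalized start-to-target units
    asc_effects: dict = field(default_factory=lambda: dict(DEFAULT_ASC_EFFECTS))
    asc_baseline_mean: float = 0.25
    asc_sd: float = 0.15
    seed: int = 0
    mirror_conditions: bool = False  # identical response draws in both arms

    def __post_init__(self):
        if self.n_participants <= 0 or self.vocab_size < 10:
            raise ValueError("n_participants > 0 and vocab_size >= 10 required")
        if not (0.0 <= self.overlap_rate <= 1.0):
            raise ValueError("overlap_rate must lie in [0, 1]")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        # deterministic per-stage stream derived from the master seed
        code = int.from_bytes(stage.encode(), "little") % (2**31)
        return np.random.default_rng([self.seed, code])


# ---------------------------------------------------------------------------
# AUT responses

def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def _condition_responses(
    config: SyntheticConfig, cond: ConditionParams, rng: np.random.Generator,
    shared_vocab: np.ndarray, exclusive_vocab: np.ndarray,
) -> list[list[str]]:
    """Response token lists, one per participant, for one condition arm."""
    n_shared = len(shared_vocab)
    blocks = np.array_split(np.arange(n_shared), config.n_blocks)
    zipf_all = _zipf_weights(n_shared, cond.popularity_exponent)
    n_per_participant = config.responses_per_prompt * config.prompts_per_condition

    out = []
    for _ in range(config.n_participants):
        # each participant favors a couple of concept blocks
        chosen = rng.choice(config.n_blocks, size=2, replace=False)
        own = np.concatenate([blocks[b] for b in chosen])
        own_w = zipf_all[own] / zipf_all[own].sum()
        tokens: list[str] = []
        core = np.arange(min(cond.core_size, n_shared))
        core_w = zipf_all[core] / zipf_all[core].sum()
        for _ in range(n_per_participant):
            if exclusive_vocab.size and rng.random() > config.overlap_rate:
                tokens.append(str(rng.choice(exclusive_vocab)))
            elif rng.random() < cond.core_rate:
                # consensus core: widely shared responses that give the
                # network a high-similarity backbone
                tokens.append(str(shared_vocab[rng.choice(core, p=core_w)]))
            elif rng.random() < cond.block_mixing:
                tokens.append(str(shared_vocab[rng.choice(n_shared, p=zipf_all)]))
            else:
                tokens.append(str(shared_vocab[rng.choice(own, p=own_w)]))
        out.append(sorted(set(tokens)))
    return out


def gen_aut(config: SyntheticConfig) -> pd.DataFrame:
    """Free-response table (participant_id, condition, prompt, response).

    Raises :class:`GenerationError` when the matched-response universe
    (tokens given by >= 2 participants in both conditions) ends up too
    small for network construction.
    """
    rng = config.rng("aut")
    conds = list(config.conditions)
    shared_vocab = np.array([f"resp_{i:03d}" for i in range(config.vocab_size)])
    exclusive = {
        c: np.array([f"{c.lower()}_only_{i:03d}"
                     for i in range(config.vocab_size // 2)])
        for c in conds
    }

    rows = []
    sets_by_cond = {}
    for c in conds:
        # mirrored arms replay the same stream with the same parameters,
        # producing identical response sets in both conditions
        cond_rng = rng if not config.mirror_conditions else config.rng("aut-arm")
        cond_params = (config.conditions[c] if not config.mirror_conditions
                       else config.conditions[conds[0]])
        excl = exclusive[c] if config.overlap_rate < 1.0 else np.array([])
        per_participant = _condition_responses(
            config, cond_params, cond_rng, shared_vocab, excl)
        counts: dict[str, int] = {}
        for p, tokens in enumerate(per_participant):
            for k, tok in enumerate(tokens):
                prompt = f"prompt_{k % config.prompts_per_condition}"
                rows.append((f"p{p:03d}", c, prompt, tok))
                counts[tok] = counts.get(tok, 0) + 1
        sets_by_cond[c] = {t for t, n in counts.items() if n >= 2}

    matched = set.intersection(*sets_by_cond.values())
    if len(matched) < 4:
        raise GenerationError(
            f"matched-response set has only {len(matched)} tokens; raise "
            "overlap_rate or vocabulary sharing"
        )
    return pd.DataFrame(rows, columns=["participant_id", "condition",
                                       "prompt", "response"])


# ---------------------------------------------------------------------------
# Stroop trials

def gen_stroop(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """64-trial, 50%-congruent Stroop sessions per participant and condition.

    Returns the trial table and the ground-truth parameter sidecar used
    by recovery tests.
    """
    rng = config.rng("stroop")
    frames = []
    truth: dict = {}
    for c, cond in config.conditions.items():
        truth[c] = cond.dcm.as_dict()
        for p in range(config.n_participants):
            df = simulate_session(
                cond.dcm, n_trials=config.n_stroop_trials,
                congruent_share=config.congruent_share,
                seed=int(rng.integers(2**31)),
            )
            df.insert(0, "condition", c)
            df.insert(0, "participant_id", f"p{p:03d}")
            frames.append(df)
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# mouse trajectories

_TARGET_X = np.array([128.0, 384.0, 640.0, 896.0])
_TARGET_Y = 960.0
_START = np.array([512.0, 64.0])


def _one_trajectory(
    rng: np.random.Generator, cond: ConditionParams, congruent: bool,
    noise_sd: float, dt_ms: float,
    participant_offsets: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """One four-phase path, built in normalized start-to-target coordinates
    and mapped out to screen pixels.

    Phases: hold near the start, hold at the first-guess point (pulled
    laterally toward the distractor box on incongruent trials), a
    lateral evaluation wobble, and the target approach; short linear
    bridges connect them.  Each hold superimposes a slow oscillation
    and white tremor, so entropy/direction-change metrics respond to
    ``tremor_sd`` while cluster geometry stays four-blob.
    """
    target_idx = int(rng.integers(4))
    lateral_sign = rng.choice([-1.0, 1.0])
    pull = 0.0 if congruent else cond.incongruent_pull * lateral_sign
    offsets = participant_offsets if participant_offsets is not None \
        else np.zeros((4, 2))
    centers = [
        np.array([0.0, 0.0]) + offsets[0],
        np.array([0.42 + pull, 0.38]) + offsets[1],
        np.array([0.74 + 0.5 * pull, 0.78]) + offsets[2],
        np.array([1.0, 1.0]) + offsets[3],
    ]
    scatters = [
        (0.020, 0.020),
        (0.050, 0.045),
        (cond.wobble_amplitude, 0.045),
        (0.015, 0.015),
    ]
    # exactly 101 raw samples per trial (1.01 s at 100 Hz), split over the
    # four phases at random
    durations = np.full(4, 18) + rng.multinomial(101 - 4 * 18,
                                                 [0.25] * 4)

    # each blob mixes a smooth component with white tremor; both are
    # Gaussian, so the pooled point cloud remains a 4-Gaussian mixture
    # while the tremor share controls entropy / direction changes
    tremor_frac = min(cond.tremor_frac * (1.3 if not congruent else 1.0), 0.95)
    smooth_frac = math.sqrt(1.0 - tremor_frac ** 2)

    def ar1(n, sd, rho=0.6):
        # stationary AR(1): Gaussian marginal N(0, sd^2), smooth in time
        e = rng.normal(0.0, sd, size=n)
        out = np.empty(n)
        out[0] = e[0]
        c = math.sqrt(1.0 - rho * rho)
        for t in range(1, n):
            out[t] = rho * out[t - 1] + c * e[t]
        return out

    segs = []
    for center, (sx, sy), n_k in zip(centers, scatters, durations):
        x = smooth_frac * ar1(n_k, sx) + rng.normal(0, tremor_frac * sx, n_k)
        y = smooth_frac * ar1(n_k, sy) + rng.normal(0, tremor_frac * sy, n_k)
        segs.append(np.column_stack([center[0] + x, center[1] + y]))
    xy = np.vstack(segs)
    xy = xy + rng.normal(0.0, noise_sd, size=xy.shape)

    # map the normalized frame onto the screen
    target = np.array([_TARGET_X[target_idx], _TARGET_Y])
    screen = _START[None, :] + xy * (target - _START)[None, :]
    t = np.arange(len(screen)) * dt_ms
    return t, screen[:, 0], screen[:, 1], target_idx


def gen_trajectories(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long sample table (trial_id, t_ms, x, y) plus a trial-metadata table.

    Each trajectory has four phases -- hold near the start button, a
    ballistic first guess, a lateral evaluation wobble, and the target
    approach -- sampled at ``config.sample_rate`` Hz with Gaussian
    positional noise; incongruent trials get a biased first guess and a
    larger wobble.
    """
    dt_ms = 1000.0 / config.sample_rate
    if dt_ms <= 0:
        raise ValueError("non-positive sample interval")
    rng = config.rng("traj")
    sample_rows, meta_rows = [], []
    trial_id = 0
    # stable per-participant style: tiny idiosyncratic blob displacements
    part_offsets = {
        p: config.rng(f"traj-style-{p}").normal(0.0, 0.01, size=(4, 2))
        for p in range(config.n_participants)
    }
    for c, cond in config.conditions.items():
        for p in range(config.n_participants):
            for k in range(config.trajectory_trials):
                congruent = k % 2 == 0
                t, x, y, target_idx = _one_trajectory(
                    rng, cond, congruent, config.trajectory_noise_sd, dt_ms,
                    participant_offsets=part_offsets[p])
                sample_rows.append(pd.DataFrame(
                    {"trial_id": trial_id, "t_ms": t, "x": x, "y": y}))
                meta_rows.append({
                    "trial_id": trial_id, "participant_id": f"p{p:03d}",
                    "condition": c, "congruent": congruent, "correct": True,
                    "target": int(target_idx),
                    "start_x": _START[0], "start_y": _START[1],
                })
                trial_id += 1
    return (pd.concat(sample_rows, ignore_index=True),
            pd.DataFrame(meta_rows))


# ---------------------------------------------------------------------------
# questionnaire ratings

def gen_asc(config: SyntheticConfig) -> pd.DataFrame:
    """Paired ratings in [0, 1] with planted per-item effects (clipped)."""
    rng = config.rng("asc")
    conds = list(config.conditions)
    if len(conds) != 2:
        raise ValueError("ASC generation assumes exactly two conditions")
    base, sd = config.asc_baseline_mean, config.asc_sd
    rows = []
    for item, d in config.asc_effects.items():
        if not np.isfinite(d):
            raise ValueError(f"non-finite planted effect for {item!r}")
        for p in range(config.n_participants):
            subject_shift = rng.normal(0.0, sd / 2)
            a = rng.normal(base + subject_shift, sd)
            b = rng.normal(base + subject_shift + d * sd, sd)
            rows.append((f"p{p:03d}", conds[0], item, float(np.clip(a, 0, 1))))
            rows.append((f"p{p:03d}", conds[1], item, float(np.clip(b, 0, 1))))
    return pd.DataFrame(rows, columns=["participant_id", "condition",
                                       "item", "rating"])


# ---------------------------------------------------------------------------
# serialization

def write_all(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate all four tables and a ground-truth sidecar into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    aut = gen_aut(config)
    stroop, truth = gen_stroop(config)
    samples, meta = gen_trajectories(config)
    asc = gen_asc(config)
    for name, df in [("aut", aut), ("stroop", stroop),
                     ("trajectories", samples), ("trajectory_meta", meta),
                     ("asc", asc)]:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p

    sidecar = {
        "seed": config.seed,
        "dcm_ground_truth": truth,
        "conditions": {
            c: {k: v for k, v in asdict(cp).items() if k != "dcm"}
            for c, cp in config.conditions.items()
        },
    }
    p = outdir / "ground_truth.json"
    p.write_text(json.dumps(sidecar, indent=2, default=float))
    paths["ground_truth"] = p
    return paths
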
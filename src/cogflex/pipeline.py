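"""End-to-end orchestration: data -> four analysis stages -> comparisons.

A run takes either a directory of CSV inputs (free responses, Stroop
trials, trajectories, questionnaire ratings) or a synthetic preset,
executes the enabled stages in the order questionnaire -> semantic
networks -> percolation -> conflict-diffusion -> trajectories, pairs the
two conditions by participant (or resampling unit), and serializes all
tables plus a summary JSON.  Every stochastic stage derives its seed
deterministically from the master seed and the stage name, so re-running
with the same config reproduces results bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import dcm as dcm_mod
from . import mousetraj as traj_mod
from . import percolation as perc_mod
from . import semnet as semnet_mod
from . import stats as stats_mod
from . import synthetic as synth_mod

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run", "validate_inputs", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    input_dir: Optional[str] = None      # None -> generate synthetic data
    conditions: tuple[str, str] = ("OR", "DD")
    seed: int = 0
    out_dir: str = "cogflex_out"
    stages: tuple[str, ...] = ("asc", "semnet", "percolation", "dcm", "traj")
    n_permutations: int = 10_000
    min_participants: int = 2
    percolation_convention: str = "weighted_sum"
    ls_iterations: int = 500
    dcm_budget: Optional[dcm_mod.FitBudget] = None
    dcm_max_participants: Optional[int] = None
    gmm_k_range: tuple[int, ...] = tuple(range(2, 11))
    gmm_max_trajectories: int = 600
    synthetic: synth_mod.SyntheticConfig = None

    def __post_init__(self):
        if self.synthetic is None:
            self.synthetic = synth_mod.SyntheticConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", None)
        budget = raw.pop("dcm_budget", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if synth:
            cfg.synthetic = synth_mod.SyntheticConfig(seed=cfg.seed, **synth)
        if budget:
            cfg.dcm_budget = dcm_mod.FitBudget(**budget)
        return cfg

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return float(o)
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=enc)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    tests: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            return str(o)
        return json.dumps({
            "config_hash": self.config_hash, "seed": self.seed,
            "tests": self.tests, "tables": self.tables, "errors": self.errors,
        }, indent=2, default=enc)


REQUIRED_COLUMNS = {
    "aut": ["participant_id", "condition", "prompt", "response"],
    "stroop": ["participant_id", "condition", "congruent", "correct", "rt_ms"],
    "trajectories": ["trial_id", "t_ms", "x", "y"],
    "trajectory_meta": ["trial_id", "participant_id", "condition",
                        "congruent", "correct"],
    "asc": ["participant_id", "condition", "item", "rating"],
}


def validate_inputs(input_dir: str | Path) -> dict[str, list[str]]:
    """Schema check of the four CSV inputs; returns per-file error lists."""
    input_dir = Path(input_dir)
    problems: dict[str, list[str]] = {}
    for name, cols in REQUIRED_COLUMNS.items():
        path = input_dir / f"{name}.csv"
        errs: list[str] = []
        if not path.exists():
            problems[name] = [f"missing file {path}"]
            continue
        df = pd.read_csv(path)
        for c in cols:
            if c not in df.columns:
                errs.append(f"missing column {c!r}")
        if name == "trajectories" and not errs:
            for trial, sub in df.groupby("trial_id"):
                t = sub["t_ms"].to_numpy()
                bad = np.flatnonzero(np.diff(t) <= 0)
                if bad.size:
                    errs.append(
                        f"trial {trial}: non-monotone t_ms at row "
                        f"{sub.index[bad[0] + 1]}")
                    break
        if name == "asc" and not errs:
            out = df[(df["rating"] < 0) | (df["rating"] > 1)]
            if len(out):
                errs.append(f"{len(out)} ratings outside [0, 1], "
                            f"first at row {out.index[0]}")
        if errs:
            problems[name] = errs
    return problems


def _paired_test(df, unit, cond_pair, value, n_iter, seed):
    sample = stats_mod.paired_sample_from_long(
        df, unit_col=unit, condition_col="condition", value_col=value,
        conditions=cond_pair)
    return stats_mod.permutation_paired_ttest(sample, n_iter=n_iter, seed=seed)


def _result_record(res: stats_mod.TestResult) -> dict:
    return {"statistic": res.statistic, "p": res.p_value, "d": res.effect_d,
            "phi": res.effect_phi, "n_iter": res.n_iterations,
            "seed": res.seed}


def run(config: RunConfig) -> RunReport:
    """Execute the enabled stages and write tables + summary to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash(), seed=config.seed)
    ca, cb = config.conditions

    # ---- load or synthesize inputs
    if config.input_dir is None:
        data_dir = out / "synthetic_inputs"
        synth_mod.write_all(config.synthetic, data_dir)
    else:
        data_dir = Path(config.input_dir)
        problems = validate_inputs(data_dir)
        if problems:
            raise ValueError(f"input validation failed: {problems}")
    tables = {name: pd.read_csv(data_dir / f"{name}.csv")
              for name in REQUIRED_COLUMNS}

    def save(name: str, df: pd.DataFrame):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        report.tables[name] = str(path)

    # ---- questionnaire stage
    if "asc" in config.stages:
        seed = stage_seed(config.seed, "asc")
        asc = tables["asc"]
        results = {}
        for i, (item, sub) in enumerate(sorted(asc.groupby("item"))):
            res = _paired_test(sub, "participant_id", (cb, ca), "rating",
                               config.n_permutations, seed + i)
            results[item] = _result_record(res)
        report.tests["asc"] = results

    # ---- semantic-network stage
    nets = None
    if "semnet" in config.stages or "percolation" in config.stages:
        try:
            matrices = semnet_mod.preprocess_aut(tables["aut"])
            nets = semnet_mod.run_semnet_pipeline(
                tables["aut"], config.conditions,
                min_participants=config.min_participants)
        except ValueError as exc:
            report.errors["semnet"] = str(exc)

    if "semnet" in config.stages and nets is not None:
        seed = stage_seed(config.seed, "semnet")
        counts = semnet_mod.overlap_counts(
            matrices[ca].response_set, matrices[cb].response_set)
        mcnemar = stats_mod.mcnemar_test(counts)
        full_metrics = {c: semnet_mod.compute_metrics(
            nets[c], community_seed=seed).as_dict() for c in config.conditions}

        lono = {c: semnet_mod.lono(nets[c], community_seed=seed)
                for c in config.conditions}
        loso = semnet_mod.loso(tables["aut"], config.conditions,
                               min_participants=config.min_participants,
                               community_seed=seed)
        tests = {}
        for method, dists in (("LONO", lono), ("LOSO", loso)):
            for metric in ("aspl", "cc", "q", "s"):
                ids_a = dists[ca].unit_ids
                ids_b = dists[cb].unit_ids
                common = [u for u in ids_a if u in set(ids_b)]
                va = {u: v for u, v in zip(ids_a, dists[ca].values(metric))}
                vb = {u: v for u, v in zip(ids_b, dists[cb].values(metric))}
                sample = stats_mod.PairedSample(
                    np.array([vb[u] for u in common]),
                    np.array([va[u] for u in common]), common)
                res = stats_mod.permutation_paired_ttest(
                    sample, config.n_permutations, seed)
                tests[f"{method}_{metric}"] = _result_record(res)
        report.tests["semnet"] = {
            "mcnemar_unique_responses": _result_record(mcnemar),
            "overlap": {"a_only": counts.discordant_a_only,
                        "b_only": counts.discordant_b_only,
                        "both": counts.concordant_both,
                        "union": counts.n_total},
            "full_metrics": full_metrics,
            "comparisons": tests,
        }
        for c in config.conditions:
            save(f"network_{c}", nets[c].to_edge_dataframe())
            save(f"lono_{c}", lono[c].to_dataframe())
            save(f"loso_{c}", loso[c].to_dataframe())

    # ---- percolation stage
    if "percolation" in config.stages and nets is not None:
        seed = stage_seed(config.seed, "percolation")
        conv = config.percolation_convention
        full_phi, curves = {}, {}
        for c in config.conditions:
            res = perc_mod.percolate(nets[c], conv)
            full_phi[c] = res.integral_phi
            curves[c] = res.curve
            save(f"percolation_curve_{c}", res.curve.to_dataframe())
        tests = {}
        # LONO: paired by removed node label
        lono_phi = {c: dict(zip(*perc_mod.percolation_lono(nets[c], conv)))
                    for c in config.conditions}
        common = [u for u in lono_phi[ca] if u in lono_phi[cb]]
        sample = stats_mod.PairedSample(
            np.array([lono_phi[cb][u] for u in common]),
            np.array([lono_phi[ca][u] for u in common]), common)
        tests["LONO"] = _result_record(
            stats_mod.permutation_paired_ttest(sample, config.n_permutations,
                                               seed))
        # LOSO: paired by removed participant
        loso_phi = perc_mod.percolation_loso(
            tables["aut"], config.conditions, conv,
            min_participants=config.min_participants)
        ids_a = dict(zip(*loso_phi[ca]))
        ids_b = dict(zip(*loso_phi[cb]))
        common = [u for u in ids_a if u in ids_b]
        sample = stats_mod.PairedSample(
            np.array([ids_b[u] for u in common]),
            np.array([ids_a[u] for u in common]), common)
        tests["LOSO"] = _result_record(
            stats_mod.permutation_paired_ttest(sample, config.n_permutations,
                                               seed))
        # LS: paired by iteration index
        ls = {c: perc_mod.ls_null(nets[c], config.ls_iterations,
                                  stage_seed(config.seed, f"ls-{c}"), conv)
              for c in config.conditions}
        sample = stats_mod.PairedSample(ls[cb], ls[ca],
                                        list(range(config.ls_iterations)))
        tests["LS"] = _result_record(
            stats_mod.permutation_paired_ttest(sample, config.n_permutations,
                                               seed))
        report.tests["percolation"] = {"full_phi": full_phi,
                                       "comparisons": tests}

    # ---- conflict-diffusion stage
    if "dcm" in config.stages:
        seed = stage_seed(config.seed, "dcm")
        try:
            clean, prep = dcm_mod.preprocess_stroop(tables["stroop"])
            budget = config.dcm_budget or dcm_mod.FitBudget.desk()
            participants = sorted(clean["participant_id"].unique())
            if config.dcm_max_participants:
                participants = participants[: config.dcm_max_participants]
            fits = []
            for p in participants:
                for c in config.conditions:
                    sub = clean[(clean["participant_id"] == p)
                                & (clean["condition"] == c)]
                    trials = dcm_mod.TrialSet.from_dataframe(sub)
                    try:
                        res = dcm_mod.fit(trials, budget=budget,
                                          seed=stage_seed(seed, f"{p}-{c}"))
                    except ValueError as exc:
                        logger.warning("fit skipped for %s/%s: %s", p, c, exc)
                        continue
                    rec = {"participant_id": p, "condition": c,
                           "rmse": res.rmse}
                    rec.update(res.params.as_dict())
                    fits.append(rec)
            fits_df = pd.DataFrame(fits)
            save("dcm_fits", fits_df)
            tests = {}
            for param in ("alpha", "tau", "delta", "beta"):
                res = _paired_test(fits_df, "participant_id",
                                   (cb, ca), param,
                                   config.n_permutations, seed)
                tests[param] = _result_record(res)
            report.tests["dcm"] = {
                "preprocess": {"median_rt": prep.median_rt,
                               "mad_rt": prep.mad_rt,
                               "fraction_removed": prep.fraction_removed,
                               "excluded": prep.excluded_participants},
                "comparisons": tests,
            }
        except ValueError as exc:
            report.errors["dcm"] = str(exc)

    # ---- trajectory stage
    if "traj" in config.stages:
        seed = stage_seed(config.seed, "traj")
        meta = tables["trajectory_meta"]
        keep_ids = set(meta.loc[meta["correct"].astype(bool), "trial_id"])
        samples = tables["trajectories"]
        raws = traj_mod.trajectories_from_table(
            samples[samples["trial_id"].isin(keep_ids)], meta)
        trajs = traj_mod.preprocess_trajectories(raws)
        rows = []
        for tr in trajs:
            rec = traj_mod.compute_trajectory_metrics(tr).as_dict()
            rec.update({k: tr.meta.get(k) for k in
                        ("trial_id", "participant_id", "condition",
                         "congruent")})
            rows.append(rec)
        metrics_df = pd.DataFrame(rows)
        save("trajectory_metrics", metrics_df)

        tests = {}
        for congruent in (True, False):
            sub = metrics_df[metrics_df["congruent"] == congruent]
            agg = sub.groupby(["participant_id", "condition"]).mean(
                numeric_only=True).reset_index()
            for metric in ("auc", "pe_x", "pe_y", "d_x", "d_y", "ed", "v"):
                res = _paired_test(agg, "participant_id", (cb, ca),
                                   metric, config.n_permutations, seed)
                key = "congruent" if congruent else "incongruent"
                tests[f"{metric}_{key}"] = _result_record(res)

        # macro-states on a (deterministic) subsample of trajectories
        pool = trajs
        if len(pool) > config.gmm_max_trajectories:
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(pool), config.gmm_max_trajectories,
                             replace=False)
            pool = [pool[i] for i in sorted(idx)]
        try:
            model = traj_mod.fit_state_model(pool, k_range=config.gmm_k_range,
                                             seed=seed)
            seqs = {}
            for tr in pool:
                key = (tr.meta.get("condition"),
                       bool(tr.meta.get("congruent")))
                seqs.setdefault(key, []).append(
                    traj_mod.state_sequence(tr, model))
            trans = {f"{c}_{'con' if g else 'inc'}":
                     traj_mod.transition_matrix(s, model.k).tolist()
                     for (c, g), s in seqs.items()}
            dwell = {f"{c}_{'con' if g else 'inc'}":
                     traj_mod.dwell_time(s, model.k).tolist()
                     for (c, g), s in seqs.items()}
            states = {"k": model.k, "aic_table": model.aic_table,
                      "label_map": model.label_map,
                      "transition_matrices": trans, "dwell_times": dwell}
        except ValueError as exc:
            states = {"error": str(exc)}
            report.errors["traj_states"] = str(exc)
        report.tests["traj"] = {"comparisons": tests, "states": states}

    (out / "report.json").write_text(report.to_json())
    return report
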
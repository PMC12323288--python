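"""End-to-end orchestration: simulate -> preprocess -> timecourse ->
cpa / gca / dpa -> associate, under one config and one master seed.

Per-stage seeds are derived deterministically from the master seed through
``numpy.random.SeedSequence(master_seed, spawn_key=(stage_index,))``, so a
stage can be re-run in isolation and still reproduce.  The manifest written
alongside the results records the verbatim config, every derived seed, and
every under-specified default in effect (I-VT threshold, divergence run
length, GCA df method, FDR family definition, aggregation level).
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import write_results
from .preprocessing import (BinnedFixationTensor, FixationParams,
                            preprocess_cohort)
from .synthetic import (CohortSpec, GroupParams, NoiseParams, ScoreLink,
                        simulate_cohort, write_cohort)
from . import associations, cpa, dpa, gca, timecourse

STAGES = ("simulate", "preprocess", "timecourse", "cpa", "gca", "dpa",
          "associate")

DEFAULT_CONFIG: dict = {
    "master_seed": 0,
    "stages": {s: True for s in STAGES},
    "cohort": {
        "n_per_group": {"autistic": 45, "NT": 52},
        "n_trials": 24,
        "group_params": {},          # per-group GroupParams overrides
        "noise": {},                 # NoiseParams overrides
    },
    "preprocess": {
        "velocity_threshold_deg_s": 30.0,
        "velocity_window_ms": 20.0,
        "max_gap_ms": 75.0,
        "merge_max_gap_ms": 75.0,
        "merge_max_angle_deg": 0.5,
        "min_duration_ms": 100.0,
        "bin_width": 50.0,
        "window": [0.0, 2500.0],
        "min_overlap_ms": 0.0,
    },
    "timecourse": {
        "level": "trial",
        "prediction_window": [0.0, 1300.0],
        "dp_run_bins": 4,
    },
    "cpa": {
        "comparisons": ["target", "agent_related", "action_related"],
        "n_perm": 1000,
        "alpha": 0.05,
    },
    "gca": {"k": 4, "k_max": 5, "alpha": 0.05},   # k: int or "auto"
    "dpa": {
        "window": [750.0, 2500.0],
        "n_boot": 1000,
        "run_bins": 4,
        "alpha": 0.05,
    },
    "associate": {"include_trial_intercept": True},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults merged in)."""

    raw: dict

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "RunConfig":
        cfg = _merge(DEFAULT_CONFIG, overrides or {})
        unknown = set(cfg) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        return cls(cfg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.raw[key]

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(self.raw["master_seed"],
                                    spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def cohort_spec(self) -> CohortSpec:
        c = self.raw["cohort"]
        base = CohortSpec()
        group_params = dict(base.group_params)
        for group, over in (c.get("group_params") or {}).items():
            group_params[group] = dataclasses.replace(
                group_params[group], **over)
        noise = dataclasses.replace(base.noise, **(c.get("noise") or {}))
        return CohortSpec(
            n_per_group=dict(c["n_per_group"]), group_params=group_params,
            noise=noise, score_link=ScoreLink(), n_trials=c["n_trials"],
            seed=self.stage_seed("simulate"))

    def fixation_params(self) -> FixationParams:
        p = self.raw["preprocess"]
        return FixationParams(
            max_gap_ms=p["max_gap_ms"],
            velocity_threshold_deg_s=p["velocity_threshold_deg_s"],
            velocity_window_ms=p["velocity_window_ms"],
            merge_max_gap_ms=p["merge_max_gap_ms"],
            merge_max_angle_deg=p["merge_max_angle_deg"],
            min_duration_ms=p["min_duration_ms"])


def run_pipeline(config: RunConfig | dict | None = None,
                 out_dir="results") -> dict:
    """Execute every enabled stage in dependency order; returns the manifest.

    Any stage failure raises :class:`PipelineStageError` with the stage
    name; outputs of completed stages (and the partial manifest) are left
    in place.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = config["stages"]
    manifest: dict = {
        "package": "vwpgaze",
        "version": __version__,
        "config": config.raw,
        "seeds": {s: config.stage_seed(s) for s in STAGES},
        "defaults_in_effect": {
            "ivt_velocity_threshold_deg_s":
                config["preprocess"]["velocity_threshold_deg_s"],
            "divergence_run_bins": config["dpa"]["run_bins"],
            "individual_dp_run_bins": config["timecourse"]["dp_run_bins"],
            "gca_df_method": "between-within",
            "gca_estimation": "REML (ML for order selection)",
            "fdr_family": "5 AQ subscales per (group, index)",
            "log_ratio_level": config["timecourse"]["level"],
            "cluster_forming_test": "two-sided paired t",
            "dpa_onset_test": "one-sided paired t",
        },
        "stages_run": [],
        "outputs": {},
    }

    def _finish_stage(stage: str, outputs: list):
        manifest["stages_run"].append(stage)
        # paths relative to the output dir keep manifests byte-identical
        # across runs into different directories
        manifest["outputs"][stage] = [
            str(Path(p).relative_to(out)) if str(p).startswith(str(out))
            else str(p) for p in outputs]
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    cohort = None
    tensor: BinnedFixationTensor | None = None
    series = None
    indices = None

    try:
        stage = "simulate"
        if enabled[stage]:
            cohort = simulate_cohort(config.cohort_spec())
            info = write_cohort(cohort, out / "simulated")
            manifest["cohort"] = info
            _finish_stage(stage, [out / "simulated"])
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("simulate", exc) from exc

    try:
        stage = "preprocess"
        if enabled[stage]:
            if cohort is None:
                raise RuntimeError("preprocess requires the simulate stage "
                                   "(or load a tensor and disable both)")
            p = config["preprocess"]
            tensor = preprocess_cohort(
                list(cohort.gaze.values()), cohort.designs,
                params=config.fixation_params(),
                window=tuple(p["window"]), bin_width=p["bin_width"],
                min_overlap_ms=p["min_overlap_ms"])
            tensor.to_csv(out / "tensor.csv")
            _finish_stage(stage, [out / "tensor.csv"])
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    try:
        stage = "timecourse"
        if enabled[stage]:
            tc = config["timecourse"]
            curves = timecourse.proportion_curves(tensor)
            series = timecourse.log_ratio_series(tensor, level=tc["level"])
            indices = timecourse.participant_indices(
                tensor, series, window=tuple(tc["prediction_window"]),
                run_bins=tc["dp_run_bins"])
            curves.to_csv(out / "curves.csv", index=False,
                          float_format="%.17g")
            series.to_csv(out / "series.csv")
            files = write_results({"indices": indices}, out)
            _finish_stage(stage, [out / "curves.csv", out / "series.csv",
                                  *files])
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    try:
        stage = "cpa"
        if enabled[stage]:
            cp = config["cpa"]
            seed = config.stage_seed(stage)
            all_clusters = []
            for group in sorted(set(tensor.groups)):
                for comparison in cp["comparisons"]:
                    _, clusters, _ = cpa.permutation_test(
                        tensor, comparison, group, n_perm=cp["n_perm"],
                        seed=seed, alpha=cp["alpha"])
                    all_clusters.extend(clusters)
            files = write_results(
                {"clusters": cpa.clusters_frame(all_clusters)}, out)
            _finish_stage(stage, files)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    try:
        stage = "gca"
        if enabled[stage]:
            gc = config["gca"]
            outputs = []
            k = gc["k"]
            if k == "auto":
                k, sel = gca.select_order(series, k_max=gc["k_max"],
                                          alpha=gc["alpha"])
                sel.to_csv(out / "model_selection.csv", index=False,
                           float_format="%.17g")
                outputs.append(out / "model_selection.csv")
            fit = gca.fit_growth_model(series, k=int(k))
            outputs += write_results({"growth": fit.table}, out)
            manifest["gca"] = {
                "k": int(k), "vc": fit.vc, "loglik": fit.loglik,
                "converged": fit.converged,
                "dropped_components": fit.dropped_components}
            _finish_stage(stage, outputs)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    try:
        stage = "dpa"
        if enabled[stage]:
            dp = config["dpa"]
            groups = tuple(sorted(set(tensor.groups)))
            results, difference = dpa.bootstrap_divergence(
                tensor, groups=groups, n_boot=dp["n_boot"],
                seed=config.stage_seed(stage), window=tuple(dp["window"]),
                run_bins=dp["run_bins"], alpha=dp["alpha"])
            files = write_results(
                {"divergence": dpa.divergence_frame(results)}, out)
            diff_frame = pd.DataFrame([{
                "group_a": difference.order[0], "group_b": difference.order[1],
                "difference_ms": difference.difference_ms,
                "ci_lo_ms": difference.ci95[0],
                "ci_hi_ms": difference.ci95[1],
                "p": difference.p, "n_missing": difference.n_missing}])
            diff_frame.to_csv(out / "divergence_difference.csv", index=False,
                              float_format="%.17g")
            _finish_stage(stage, [*files, out / "divergence_difference.csv"])
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    try:
        stage = "associate"
        if enabled[stage]:
            corr = associations.correlation_suite(indices, cohort.scores)
            files = write_results({"correlations": corr}, out)
            acc = associations.accuracy_model(
                cohort.responses,
                include_trial_intercept=config["associate"]
                ["include_trial_intercept"])
            acc_frame = pd.DataFrame([{
                "term": "group", "estimate": acc.coef, "se": acc.se,
                "z": acc.z, "p": acc.p, "separated": acc.separated}])
            acc_frame.to_csv(out / "accuracy.csv", index=False,
                             float_format="%.17g")
            _finish_stage(stage, [*files, out / "accuracy.csv"])
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    return manifest
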
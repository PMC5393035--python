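"""End-to-end orchestration: simulate → preprocess → clean → metrics → stats → regress.

A single JSON/YAML-able config drives every stage; all randomness derives
from one root seed, so a fixed config yields byte-identical outputs.  Stages
communicate through in-memory objects here and through files in the CLI; a
manifest records the config hash and every derived seed.
"""

from __future__ import annotations

import copy
import difflib
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .artifact_removal import classify_components, decompose, reconstruct_clean
from .clinical_classification import classify_sensory_impairment
from .evoked_metrics import (compute_laterality, compute_metrics,
                             compute_ssr_power, hemisphere_delta_e)
from .group_statistics import anova_with_tukey, wilcoxon_signed_rank
from .lesion_regression import build_feature_tables, permutation_significance
from .preprocessing import (apply_filters, check_min_periods,
                            exclude_bad_channels, rereference_common_average,
                            reject_periods_by_torque, segment_periods)
from .signal_design import build_default_spec
from .synthetic_data import CohortConfig, simulate_cohort

#: Full default configuration: a small demonstration cohort at a reduced
#: sample rate (the 1.25 s period grid stays exact at 256 Hz).
DEFAULT_CONFIG = {
    "seed": 0,
    "cohort": {
        "group_sizes": {"severe": 4, "mild": 4, "none": 4, "control": 4},
        "n_trials": 12,
        "sample_rate_hz": 256.0,
        "violation_fraction": 0.05,
        "artifacts": [],
        "gain_jitter_sd": 0.1,
        "lesion_volume_max_ml": 20.0,
        "lesion_noise_sd_ml": 1.5,
        "severe_gain": None,        # override of the severe-group gain, optional
    },
    "preprocessing": {
        "band_hz": [0.8, 120.0],
        "notches_hz": [50.0, 100.0],
        "notch_halfwidth_hz": 1.0,
        "bad_channels": "none",     # "none" | "auto" | [labels]
        "discard_first": 2,
        "torque_tolerance_fraction": 0.5,
        "min_periods": 80,
    },
    "ica": {
        "enabled": False,
        "backend": "fastica",
        "reject": ["muscle", "eye", "single-electrode"],
    },
    "regression": {
        "enabled": True,
        "tasks": "passive",
        "n_permutations": 100,
        "n_folds": 10,
    },
}


class ConfigError(ValueError):
    pass


def _check_keys(doc, template, path=""):
    errors = []
    for key in doc:
        if key not in template:
            hint = difflib.get_close_matches(str(key), list(template), n=1)
            msg = f"unknown config key {path + str(key)!r}"
            if hint:
                msg += f" (did you mean {path + hint[0]!r}?)"
            errors.append(msg)
        elif isinstance(template[key], dict) and key != "group_sizes":
            if not isinstance(doc[key], dict):
                errors.append(f"{path + key!r} must be a mapping")
            else:
                errors.extend(_check_keys(doc[key], template[key], path + key + "."))
    return errors


def _merge(base, doc):
    out = copy.deepcopy(base)
    for key, val in doc.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict) and key != "group_sizes":
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def validate_config(document: dict | None = None) -> dict:
    """Fill defaults and validate; all schema violations are reported at once."""
    document = document or {}
    errors = _check_keys(document, DEFAULT_CONFIG)
    cfg = _merge(DEFAULT_CONFIG, document)
    pre = cfg["preprocessing"]
    try:
        if pre["torque_tolerance_fraction"] < 0:
            errors.append("preprocessing.torque_tolerance_fraction must be >= 0")
        if pre["discard_first"] < 0:
            errors.append("preprocessing.discard_first must be >= 0")
        if pre["min_periods"] < 1:
            errors.append("preprocessing.min_periods must be >= 1")
        if not 0 <= cfg["cohort"]["violation_fraction"] <= 1:
            errors.append("cohort.violation_fraction must lie in [0, 1]")
        if any(v < 0 for v in cfg["cohort"]["group_sizes"].values()):
            errors.append("cohort.group_sizes must be non-negative")
        if cfg["ica"]["backend"] not in ("fastica", "infomax"):
            errors.append("ica.backend must be 'fastica' or 'infomax'")
        if cfg["regression"]["tasks"] not in ("passive", "active", "both"):
            errors.append("regression.tasks must be 'passive', 'active' or 'both'")
        if cfg["regression"]["enabled"] and cfg["regression"]["n_permutations"] < 100:
            errors.append("regression.n_permutations must be >= 100")
    except TypeError as err:
        errors.append(f"wrongly typed config value: {err}")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def _config_hash(cfg) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _process_participant(part, spec, cfg, ica_seed):
    pre = cfg["preprocessing"]
    sessions = {"passive": part.passive, "active": part.active}
    cleaned = {}
    for task, rec in sessions.items():
        if rec is None:
            continue
        rec = apply_filters(rec, band_hz=tuple(pre["band_hz"]),
                            notches_hz=tuple(pre["notches_hz"]),
                            notch_halfwidth_hz=pre["notch_halfwidth_hz"])
        if pre["bad_channels"] != "none":
            rec = exclude_bad_channels(rec, bad=pre["bad_channels"])
        rec = rereference_common_average(rec)
        cleaned[task] = rec

    if cfg["ica"]["enabled"] and cleaned:
        # one decomposition over both tasks combined
        tasks = list(cleaned)
        concat = np.concatenate([cleaned[t].eeg for t in tasks], axis=1)
        decomp = decompose(concat, cleaned[tasks[0]].electrode_labels,
                           cleaned[tasks[0]].sample_rate_hz,
                           backend=cfg["ica"]["backend"], seed=ica_seed)
        classify_components(decomp)
        restored = reconstruct_clean(decomp, reject_labels=tuple(cfg["ica"]["reject"]))
        offset = 0
        for t in tasks:
            n = cleaned[t].n_samples
            cleaned[t].eeg[:] = restored[:, offset:offset + n]
            offset += n

    side = part.truth.affected_side
    rows = {}
    for task, rec in cleaned.items():
        stack = segment_periods(rec, spec, discard_first=pre["discard_first"])
        valid = True
        if task == "active":
            stack = reject_periods_by_torque(
                stack, rec.torque, rec.target_torque_nm,
                tolerance_fraction=pre["torque_tolerance_fraction"])
            valid = check_min_periods(stack, minimum=pre["min_periods"])
        if not valid:
            rows[task] = {"valid": False, "n_periods": stack.P}
            continue
        metrics = compute_metrics(stack, stimulated_side=side)
        lat = metrics.laterality
        rows[task] = {
            "valid": True, "n_periods": stack.P,
            "snr_contra": lat.snr_contra, "snr_ipsi": lat.snr_ipsi,
            "li": lat.li, "sum_snr": lat.sum_snr,
            "e_hat": metrics.e_hat,
        }
    delta = {}
    if rows.get("passive", {}).get("valid") and rows.get("active", {}).get("valid"):
        delta = hemisphere_delta_e(rows["active"]["e_hat"],
                                   rows["passive"]["e_hat"], side)
    return rows, delta


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run the full analysis; returns the result bundle and optionally writes it.

    Outputs: ``metrics.csv`` (per participant × task summaries), ``stats.csv``
    (group tests), ``regression.csv`` and ``manifest.json`` under ``out_dir``.
    """
    cfg = validate_config(config)
    root = np.random.SeedSequence(cfg["seed"])
    cohort_seed, spec_seed, ica_root, perm_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)]

    cohort_kwargs = {k: v for k, v in cfg["cohort"].items() if k != "severe_gain"}
    cohort_kwargs["group_sizes"] = dict(cohort_kwargs["group_sizes"])
    cohort_kwargs["artifacts"] = tuple(cohort_kwargs["artifacts"])
    if cfg["cohort"]["severe_gain"] is not None:
        cohort_kwargs["group_gains"] = {"severe": float(cfg["cohort"]["severe_gain"])}
    ccfg = CohortConfig(**cohort_kwargs)
    participants = simulate_cohort(ccfg, seed=cohort_seed)
    # segmentation only depends on the stimulus period, which is fixed
    spec = build_default_spec(spec_seed)

    ica_ss = np.random.SeedSequence(ica_root).spawn(len(participants))
    summary_rows, delta_rows = [], []
    for part, ss in zip(participants, ica_ss):
        pid = part.clinical.id
        group = (part.clinical.sensory_group if part.truth.sensory_group_label != "control"
                 else "control")
        try:
            rows, delta = _process_participant(
                part, spec, cfg, ica_seed=int(ss.generate_state(1)[0] % (2**31)))
        except Exception as err:
            raise RuntimeError(
                f"stage failure for participant P{pid:02d}: {err}") from err
        for task, r in rows.items():
            summary_rows.append({
                "participant": f"P{pid:02d}", "group": group, "task": task,
                "valid": r["valid"], "n_periods": r["n_periods"],
                "snr_contra": r.get("snr_contra", np.nan),
                "snr_ipsi": r.get("snr_ipsi", np.nan),
                "li": r.get("li", np.nan),
                "sum_snr": r.get("sum_snr", np.nan),
                "lesion_volume_ml": part.smt_lesion_volume_ml,
                "stroke": group != "control",
            })
        if delta:
            delta_rows.append({"participant": f"P{pid:02d}", "group": group,
                               "delta_e_contra": delta["contra"],
                               "delta_e_ipsi": delta["ipsi"]})

    metrics = pd.DataFrame(summary_rows)
    deltas = pd.DataFrame(delta_rows)

    stats_rows = []
    for task in ("passive", "active"):
        sub = metrics[(metrics["task"] == task) & metrics["valid"]]
        for name in ("li", "snr_contra", "snr_ipsi", "sum_snr"):
            by_group = {g: sub.loc[sub["group"] == g, name].to_numpy()
                        for g in sub["group"].unique()}
            try:
                res = anova_with_tukey(by_group, metric_name=f"{task}:{name}")
            except ValueError:
                continue
            stats_rows.append({
                "metric": f"{task}:{name}", "test": res.test_name,
                "statistic": res.statistic, "p_value": res.p_value,
                "significant_pairs": ";".join("|".join(p) for p in res.pairwise_significant),
            })
    for name in ("delta_e_contra", "delta_e_ipsi"):
        if deltas.empty:
            break
        for g in sorted(deltas["group"].unique()):
            vals = deltas.loc[deltas["group"] == g, name].dropna().to_numpy()
            if len(vals) < 3:
                continue
            res = wilcoxon_signed_rank(vals, metric_name=f"{g}:{name}")
            stats_rows.append({"metric": f"{g}:{name}", "test": res.test_name,
                               "statistic": res.statistic, "p_value": res.p_value,
                               "significant_pairs": ""})
    stats = pd.DataFrame(stats_rows)

    regression = pd.DataFrame()
    if cfg["regression"]["enabled"]:
        tidy = metrics[metrics["stroke"] & metrics["valid"]]
        try:
            feats = build_feature_tables(tidy, tasks=cfg["regression"]["tasks"])
            target = (tidy.drop_duplicates("participant")
                      .set_index("participant")["lesion_volume_ml"]
                      .reindex(feats.index))
            p, res, _ = permutation_significance(
                feats, target.to_numpy(),
                n_permutations=cfg["regression"]["n_permutations"],
                seed=perm_seed, n_folds=min(cfg["regression"]["n_folds"], len(feats)))
            regression = pd.DataFrame([{
                "tasks": cfg["regression"]["tasks"], "n": res.n,
                "lambda": res.lambda_, "vaf_percent": res.vaf_percent,
                "vaf_cv_percent": res.vaf_cv_percent, "permutation_p": p,
                **{f"coef_{nm}": c for nm, c in
                   zip(res.predictor_names, res.coefficients)},
            }])
        except ValueError as err:
            regression = pd.DataFrame([{"error": str(err)}])

    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seeds": {"cohort": cohort_seed, "spec": spec_seed,
                  "ica_root": ica_root, "permutation": perm_seed},
    }
    result = {"metrics": metrics, "deltas": deltas, "stats": stats,
              "regression": regression, "manifest": manifest}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        deltas.to_csv(out / "deltas.csv", index=False)
        stats.to_csv(out / "stats.csv", index=False)
        regression.to_csv(out / "regression.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result
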
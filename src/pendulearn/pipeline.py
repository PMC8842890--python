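"""End-to-end pipeline: configuration, simulation, metrics, statistics.

A :class:`PipelineConfig` fully determines a run: the same config and seed
reproduce byte-identical metrics and results.  Every output carries the
config's SHA-256 hash so downstream files can be traced to the run that made
them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .arm import ArmParams
from .cohort import (ALL_METRICS, CohortDataset, GroupEffects, generate_study)
from .exceptions import PendulearnError
from .pendulum import EARTH_GRAVITY, PendulumParams
from .stats import (ALPHA, StatResult, baseline_anova, factorial_test,
                    interaction_posthoc, learning_curve_compare,
                    phase_score_correlation, questionnaire_subscale_table,
                    retention_contrast, training_contrast,
                    transfer_kinematics_mixed_anova)

__all__ = [
    "PipelineConfig",
    "pendulum_params_from_config",
    "arm_params_from_config",
    "run_pipeline",
    "analyze_metrics",
    "results_to_frame",
]

log = logging.getLogger("pendulearn")


def pendulum_params_from_config(cfg: dict) -> PendulumParams:
    """Build pendulum parameters from simulator config keys."""
    return PendulumParams(
        m=cfg.get("mass", 2.5),
        l=cfg.get("rod_length", 0.35),
        c=cfg.get("damping", 0.16),
        g=cfg.get("gravity_fraction", 0.25) * EARTH_GRAVITY,
        k=cfg.get("score_gain", 19.0),
    )


def arm_params_from_config(cfg: dict) -> ArmParams:
    """Build arm parameters from arm config keys."""
    return ArmParams(
        m_upper=cfg.get("m_upper", 2.0),
        m_lower=cfg.get("m_lower", 1.5),
        l_upper=cfg.get("l_upper", 0.30),
        l_lower=cfg.get("l_lower", 0.25),
        r_upper=cfg.get("com_fraction_upper", 0.5),
        r_lower=cfg.get("com_fraction_lower", 0.5),
    )


@dataclass
class PipelineConfig:
    """Serializable run configuration."""

    n_per_group: int = 10
    seed: int = 0
    block_duration: float = 30.0
    sample_rate: float = 600.0
    null_effects: bool = False
    effects: Optional[dict] = None        # overrides of GroupEffects fields
    arm: dict = field(default_factory=dict)
    support_fraction: float = 1.0
    metrics: tuple = ALL_METRICS
    missing_item_rate: float = 0.02
    keep_recordings: bool = False

    @classmethod
    def demo(cls, seed: int = 0) -> "PipelineConfig":
        """Small, fast demonstration run (4 per group, 10-s blocks)."""
        return cls(n_per_group=4, seed=seed, block_duration=10.0,
                   sample_rate=600.0)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PendulearnError(f"unknown config keys: {sorted(unknown)}")
        if "metrics" in raw:
            raw["metrics"] = tuple(raw["metrics"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metrics"] = list(self.metrics)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def group_effects(self) -> GroupEffects:
        if self.null_effects:
            return GroupEffects.null()
        if self.effects:
            return GroupEffects(**self.effects)
        return GroupEffects()


def simulate_cohort(config: PipelineConfig) -> CohortDataset:
    """Generate the synthetic cohort described by a config."""
    log.info("[simulate] n_per_group=%d seed=%d duration=%.1fs rate=%.0fHz",
             config.n_per_group, config.seed, config.block_duration,
             config.sample_rate)
    return generate_study(
        n_per_group=config.n_per_group,
        effects=config.group_effects(),
        seed=config.seed,
        block_duration=config.block_duration,
        sample_rate=config.sample_rate,
        metrics=tuple(config.metrics),
        keep_recordings=config.keep_recordings,
        missing_item_rate=config.missing_item_rate,
        arm=arm_params_from_config(config.arm),
        support_fraction=config.support_fraction)


_CONTRASTS = (
    ("T-CT", training_contrast, {}),
    ("STR-BL", retention_contrast, {"endpoint": "STR", "baseline": "BL"}),
    ("LTR-BL", retention_contrast, {"endpoint": "LTR", "baseline": "BL"}),
)
_TRANSFER_CONTRASTS = (
    ("TSTR-TBL", {"endpoint": "TSTR", "baseline": "TBL"}),
    ("TLTR-TBL", {"endpoint": "TLTR", "baseline": "TBL"}),
)


def analyze_metrics(metrics: pd.DataFrame,
                    questionnaires: Optional[pd.DataFrame] = None) -> list:
    """Run the full statistical battery on a per-block metrics table.

    Returns a list of (contrast, metric, StatResult) triples covering the
    baseline group check, the factorial tests on T-CT / STR-BL / LTR-BL for
    every metric, the transfer-score tests, the phase-score correlations, the
    learning-curve model comparison, the transfer kinematics mixed ANOVA and
    (if questionnaires are given) the questionnaire contrasts.
    """
    out = []
    metric_names = [m for m in ALL_METRICS if m in metrics.columns
                    and metrics[m].notna().any()]

    for name in metric_names:
        try:
            out.append(("baseline", name, baseline_anova(metrics, name)))
        except PendulearnError as exc:
            log.warning("[analyze] baseline %s skipped: %s", name, exc)

    for contrast_name, fn, kwargs in _CONTRASTS:
        for name in metric_names:
            try:
                contrast = fn(metrics, name, **kwargs)
            except PendulearnError as exc:
                log.warning("[analyze] %s %s skipped: %s", contrast_name,
                            name, exc)
                continue
            results = factorial_test(contrast["value"], contrast["hr_train"],
                                     contrast["ws_train"])
            for res in results:
                out.append((contrast_name, name, res))
            inter = [r for r in results if r.effect == "HR x WS"]
            if inter and inter[0].significant:
                for res in interaction_posthoc(contrast["value"],
                                               contrast["hr_train"],
                                               contrast["ws_train"]):
                    out.append((contrast_name, name, res))

    if "score" in metric_names:
        for contrast_name, kwargs in _TRANSFER_CONTRASTS:
            try:
                contrast = retention_contrast(metrics, "score", **kwargs)
            except PendulearnError as exc:
                log.warning("[analyze] %s skipped: %s", contrast_name, exc)
                continue
            for res in factorial_test(contrast["value"], contrast["hr_train"],
                                      contrast["ws_train"]):
                out.append((contrast_name, "score", res))

        if "phase_diff" in metric_names:
            for endpoint in ("BL", "STR", "LTR"):
                try:
                    out.append(("correlation", "score",
                                phase_score_correlation(metrics, endpoint)))
                except PendulearnError as exc:
                    log.warning("[analyze] correlation @%s skipped: %s",
                                endpoint, exc)

        train = metrics[metrics["phase"].isin(["T", "CT"])]
        if len(train):
            out.append(("learning-curve", "score", learning_curve_compare(
                train["training_position"], train["score"])))

    for name in ("var_y", "hand_speed"):
        if name in metrics.columns and metrics[name].notna().any():
            try:
                for res in transfer_kinematics_mixed_anova(metrics, name):
                    out.append(("transfer-kinematics", name, res))
            except PendulearnError as exc:
                log.warning("[analyze] transfer kinematics %s skipped: %s",
                            name, exc)

    if questionnaires is not None and len(questionnaires):
        sub = questionnaire_subscale_table(questionnaires)
        factors = metrics[["participant", "hr_train",
                           "ws_train"]].drop_duplicates()
        sub = sub.merge(factors, on="participant")
        for subscale, grp in sub.groupby("subscale", observed=True):
            wide = grp.pivot_table(index=["participant", "hr_train",
                                          "ws_train"],
                                   columns="time_point",
                                   values="value").reset_index()
            for contrast_name, a, b in (("T-BL (questionnaire)", "T", "BL"),
                                        ("LTR-BL (questionnaire)", "LTR", "BL")):
                if a not in wide.columns or b not in wide.columns:
                    continue
                vals = (wide[a] - wide[b]).dropna()
                keep = wide.loc[vals.index]
                try:
                    for res in factorial_test(vals, keep["hr_train"],
                                              keep["ws_train"]):
                        out.append((contrast_name, subscale, res))
                except PendulearnError as exc:
                    log.warning("[analyze] questionnaire %s %s skipped: %s",
                                contrast_name, subscale, exc)
    return out


def results_to_frame(results: list) -> pd.DataFrame:
    rows = []
    for contrast, metric, res in results:
        rows.append({
            "contrast": contrast,
            "metric": metric,
            "effect": res.effect,
            "test": res.test,
            "statistic": res.statistic,
            "df": "x".join(str(d) for d in res.df),
            "p": res.p,
            "significant": res.p < ALPHA,
            "correction": res.correction or "",
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, out_dir,
                 cohort: Optional[CohortDataset] = None) -> dict:
    """Simulate (or reuse) a cohort, compute statistics, write all outputs.

    Writes ``metrics.csv``, ``questionnaires.csv``, ``results.csv`` and a
    ``manifest.json`` carrying the config, its hash and the package version.
    Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = simulate_cohort(config)
    log.info("[metrics] %d blocks from %d participants", cohort.n_blocks,
             cohort.n_participants)
    metrics_path = out_dir / "metrics.csv"
    cohort.metrics.to_csv(metrics_path, index=False, float_format="%.12g")
    quest_path = out_dir / "questionnaires.csv"
    cohort.questionnaires.to_csv(quest_path, index=False,
                                 float_format="%.12g")
    log.info("[analyze] running statistical battery")
    results = analyze_metrics(cohort.metrics, cohort.questionnaires)
    frame = results_to_frame(results)
    results_path = out_dir / "results.csv"
    frame.to_csv(results_path, index=False, float_format="%.12g")
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": __version__,
        "n_participants": cohort.n_participants,
        "n_blocks": cohort.n_blocks,
        "files": {
            "metrics": metrics_path.name,
            "questionnaires": quest_path.name,
            "results": results_path.name,
        },
        "n_tests": len(frame),
        "n_significant": int(frame["significant"].sum()),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("[report] %d tests, %d significant at alpha=%.2f",
             manifest["n_tests"], manifest["n_significant"], ALPHA)
    return manifest
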
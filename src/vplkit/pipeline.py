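"""End-to-end emulation of a staircase-based perceptual-learning study.

The schedule mirrors a two-stage design: an early stage (pretest 1, three
daily training sessions under stimulation, posttest 1), an intermediate
period of unstimulated daily training that continues until the learning
plateau criterion fires (threshold reduction < 1% on two consecutive days,
with a hard cap), and a later stage (pretest 2, three training sessions,
posttest 2). Tests are run at the trained and an untrained location; learning
transfers only partially to the untrained location.

The analysis back half fits power-law learning curves to the group-mean
thresholds of each stage (five points: pretest, three training days,
posttest), selects the best parameter-sharing model by nested F-tests, and
runs the group statistics battery (percent improvement, one-way ANOVA, LSD
post hocs, mixed pre/post x group ANOVA).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import group_stats, learning, staircase
from .observers import GroupDesign, ObserverParams, cohort_table, generate_cohort, transfer_observer

__all__ = ["ExperimentConfig", "RunReport", "run_emulation", "run_analysis"]

_ANALYSIS_GROUPS_DEFAULT = ("rDLPFC+rMT", "rDLPFC", "rMT", "sham")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of one emulation run."""

    design: GroupDesign = field(default_factory=GroupDesign)
    start_coherence: float = staircase.DEFAULT_START_COHERENCE
    transfer: float = 0.5  # fraction of log-threshold improvement at the untrained location
    alpha: float = 0.05
    max_intermediate_sessions: int = 20
    analysis_groups: tuple[str, ...] = _ANALYSIS_GROUPS_DEFAULT

    def __post_init__(self) -> None:
        if not 0 < self.start_coherence <= 1:
            raise ValueError("start_coherence must lie in (0, 1]")
        if not 0 <= self.transfer <= 1:
            raise ValueError("transfer must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.max_intermediate_sessions < 2:
            raise ValueError("max_intermediate_sessions must be >= 2")
        unknown = set(self.analysis_groups) - set(self.design.groups)
        if unknown:
            raise ValueError(f"analysis_groups not in design: {sorted(unknown)}")

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["design"]["rho_by_group"] = {
            k: list(v) for k, v in self.design.rho_by_group.items()
        }
        d["design"]["groups"] = list(self.design.groups)
        d["analysis_groups"] = list(self.analysis_groups)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        design = d.pop("design", {})
        design = dict(design)
        if "groups" in design:
            design["groups"] = tuple(design["groups"])
        if "rho_by_group" in design:
            design["rho_by_group"] = {
                k: tuple(v) for k, v in design["rho_by_group"].items()
            }
        if "analysis_groups" in d:
            d["analysis_groups"] = tuple(d["analysis_groups"])
        return cls(design=GroupDesign(**design), **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    """All tables and fitted objects produced by one run."""

    config: ExperimentConfig
    seed: int | None
    config_hash: str
    cohort: pd.DataFrame | None
    thresholds: pd.DataFrame
    improvement: pd.DataFrame
    anova: pd.DataFrame
    lsd: pd.DataFrame
    selections: dict[str, learning.ModelSelectionResult]
    plateau: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def save(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if self.cohort is not None:
            self.cohort.to_csv(out / "cohort.csv", index=False)
        self.thresholds.to_csv(out / "thresholds.csv", index=False)
        self.improvement.to_csv(out / "improvement.csv", index=False)
        self.anova.to_csv(out / "anova.csv", index=False)
        self.lsd.to_csv(out / "lsd.csv", index=False)
        for stage, sel in self.selections.items():
            sel.table.to_csv(out / f"model_comparison_{stage}.csv", index=False)
        meta = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "plateau": self.plateau,
            "selected_models": {
                stage: {
                    "spec": sel.best_spec.label(),
                    "k": sel.best_spec.k,
                    "r2": sel.best_fit.r2,
                    "c0": sel.best_fit.c0_by_group,
                    "rho": sel.best_fit.rho_by_group,
                }
                for stage, sel in self.selections.items()
            },
            "warnings": self.warnings,
        }
        (out / "report.json").write_text(json.dumps(meta, indent=2))
        (out / "summary.txt").write_text(self.summary())

    def summary(self) -> str:
        lines = [
            f"Emulation report (config {self.config_hash}, seed {self.seed})",
            "=" * 60,
            f"observers: {self.thresholds['observer_id'].nunique()}",
            (
                "intermediate training sessions to plateau: "
                f"{self.plateau['mean_sessions']:.2f} +/- {self.plateau['sd_sessions']:.2f} "
                f"({self.plateau['n_capped']:.0f} capped)"
            ),
            "",
        ]
        for stage, sel in self.selections.items():
            lines.append(f"[{stage} stage] selected model: {sel.best_spec.label()} "
                         f"(k={sel.best_spec.k}, r2={sel.best_fit.r2:.4f})")
            for g in sorted(sel.best_fit.rho_by_group):
                lines.append(
                    f"    {g:<12} C0={sel.best_fit.c0_by_group[g]:.4f} "
                    f"rho={sel.best_fit.rho_by_group[g]:.4f}"
                )
        lines.append("")
        lines.append("ANOVA table:")
        lines.append(self.anova.to_string(index=False))
        if self.warnings:
            lines.append("")
            lines.extend(f"WARNING: {w}" for w in self.warnings)
        return "\n".join(lines)


def _simulate_observer(
    obs: ObserverParams,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> tuple[list[dict[str, Any]], int, bool]:
    """Full schedule for one observer; returns threshold rows, the number of
    intermediate sessions run and whether the plateau was reached."""
    design = config.design
    rows: list[dict[str, Any]] = []
    obs_untrained = transfer_observer(obs, config.transfer)

    def add(est: staircase.ThresholdEstimate, stage: str, stage_session: int) -> None:
        rows.append(
            {
                "observer_id": obs.observer_id,
                "group": obs.group,
                "session": est.session,
                "stage": stage,
                "stage_session": stage_session,
                "kind": est.kind,
                "threshold": est.threshold,
                "n_reversals_total": est.n_reversals_total,
                "n_reversals_used": est.n_reversals_used,
            }
        )

    def _retry_once(run):
        # a staircase that ends with too few reversals is re-run once,
        # as an aborted block would be in the lab
        try:
            return run()
        except staircase.InsufficientReversalsError:
            return run()

    def tests(t: int, stage: str, stage_session: int) -> None:
        for location, who in (("trained", obs), ("untrained", obs_untrained)):
            _, est = _retry_once(
                lambda: staircase.run_test(
                    who, t, location, design, rng, config.start_coherence
                )
            )
            add(est, stage, stage_session)

    def training(t: int, stage: str, stage_session: int) -> float:
        _, est = _retry_once(
            lambda: staircase.run_session(
                obs, t, design, rng, config.start_coherence
            )
        )
        add(est, stage, stage_session)
        return est.threshold

    t = 1
    tests(t, "early", 1)  # pretest 1
    daily: list[float] = []
    for s in range(2, 5):  # three early training days
        t += 1
        daily.append(training(t, "early", s))
    t += 1
    tests(t, "early", 5)  # posttest 1

    # intermediate unstimulated training until the plateau criterion fires
    n_intermediate = 0
    plateau_reached = False
    while n_intermediate < config.max_intermediate_sessions:
        t += 1
        n_intermediate += 1
        daily.append(training(t, "intermediate", n_intermediate))
        if len(daily) >= 3:
            reductions = np.diff(daily[-3:])
            rel = -reductions / np.array(daily[-3:-1])
            if np.all(rel < 0.01):
                plateau_reached = True
                break

    t += 1
    tests(t, "later", 1)  # pretest 2
    for s in range(2, 5):
        t += 1
        training(t, "later", s)
    t += 1
    tests(t, "later", 5)  # posttest 2
    return rows, n_intermediate, plateau_reached


def _stage_curves(
    thresholds: pd.DataFrame, stage: str, groups: Sequence[str]
) -> list[learning.CurveData]:
    """Group-mean learning-curve points for one stage.

    Five points per group: the trained-location test thresholds at stage
    sessions 1 (pretest) and 5 (posttest) and the training-session thresholds
    at stage sessions 2-4, averaged over observers.
    """
    sub = thresholds[
        (thresholds["stage"] == stage)
        & (thresholds["group"].isin(groups))
        & (thresholds["kind"].isin(["training", "test_trained_location"]))
    ]
    means = (
        sub.groupby(["group", "stage_session"])["threshold"].mean().reset_index()
    )
    return learning.CurveData.from_dataframe(
        means.rename(columns={"stage_session": "session"})
    )


def _test_pairs(thresholds: pd.DataFrame, stage: str, kind: str) -> pd.DataFrame:
    """Wide per-observer pretest/posttest table for one stage and location."""
    sub = thresholds[(thresholds["stage"] == stage) & (thresholds["kind"] == kind)]
    wide = sub.pivot_table(
        index=["observer_id", "group"], columns="stage_session", values="threshold"
    ).reset_index()
    return wide.rename(columns={1: "pre", 5: "post"})


def run_analysis(
    thresholds: pd.DataFrame | str | Path,
    config: ExperimentConfig | None = None,
    *,
    cohort: pd.DataFrame | None = None,
    seed: int | None = None,
    plateau: dict[str, float] | None = None,
    warnings: list[str] | None = None,
) -> RunReport:
    """Analysis back half on a threshold table (simulated or user-supplied).

    The table must be long-format with columns observer_id, group, stage
    (early/intermediate/later), stage_session (1-5 within the early and later
    stages), kind (training / test_trained_location / test_untrained_location)
    and threshold.
    """
    if config is None:
        config = ExperimentConfig()
    if not isinstance(thresholds, pd.DataFrame):
        thresholds = pd.read_csv(thresholds)
    required = {"observer_id", "group", "stage", "stage_session", "kind", "threshold"}
    missing = required - set(thresholds.columns)
    if missing:
        raise ValueError(f"threshold table lacks columns: {sorted(missing)}")
    warnings = list(warnings or [])
    groups = [g for g in config.analysis_groups if g in set(thresholds["group"])]

    selections: dict[str, learning.ModelSelectionResult] = {}
    for stage in ("early", "later"):
        curves = _stage_curves(thresholds, stage, groups)
        if curves:
            selections[stage] = learning.select_best_model(curves, alpha=config.alpha)
            if selections[stage].no_candidate:
                warnings.append(f"{stage} stage: no reduced model matched the full model")

    improvement_rows = []
    anova_rows = []
    lsd_frames = []
    for stage in ("early", "later"):
        for kind, loc in (
            ("test_trained_location", "trained"),
            ("test_untrained_location", "untrained"),
        ):
            pairs = _test_pairs(thresholds, stage, kind)
            pairs = pairs[pairs["group"].isin(groups)].dropna(subset=["pre", "post"])
            if pairs.empty:
                continue
            pairs = pairs.assign(
                stage=stage,
                location=loc,
                improvement=[
                    group_stats.percent_improvement(a, b)
                    for a, b in zip(pairs["pre"], pairs["post"])
                ],
            )
            improvement_rows.append(pairs)
            # mixed pre/post x group ANOVA
            for res in group_stats.mixed_anova(
                pairs["pre"], pairs["post"], pairs["group"]
            ):
                anova_rows.append(
                    {"stage": stage, "location": loc, "analysis": "mixed",
                     "effect": res.effect, "F": res.f_stat, "df1": res.df_num,
                     "df2": res.df_den, "p": res.p, "eta_sq": res.eta_sq}
                )
            # one-way ANOVA + LSD on percent improvement
            samples = {
                g: sub["improvement"].to_numpy()
                for g, sub in pairs.groupby("group", sort=False)
            }
            if len(samples) >= 2 and all(len(v) >= 2 for v in samples.values()):
                res = group_stats.oneway_anova(samples)
                anova_rows.append(
                    {"stage": stage, "location": loc, "analysis": "oneway_improvement",
                     "effect": "group", "F": res.f_stat, "df1": res.df_num,
                     "df2": res.df_den, "p": res.p, "eta_sq": res.eta_sq}
                )
                lsd = group_stats.lsd_posthoc(samples)
                lsd.insert(0, "location", loc)
                lsd.insert(0, "stage", stage)
                lsd_frames.append(lsd)

    improvement = (
        pd.concat(improvement_rows, ignore_index=True)
        if improvement_rows
        else pd.DataFrame()
    )
    lsd = pd.concat(lsd_frames, ignore_index=True) if lsd_frames else pd.DataFrame()
    if plateau is None:
        inter = thresholds[thresholds["stage"] == "intermediate"]
        if len(inter):
            counts = inter.groupby("observer_id")["stage_session"].max()
            plateau = {
                "mean_sessions": float(counts.mean()),
                "sd_sessions": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
                "n_capped": 0.0,
            }
        else:
            plateau = {"mean_sessions": float("nan"), "sd_sessions": float("nan"),
                       "n_capped": 0.0}
    return RunReport(
        config=config,
        seed=seed,
        config_hash=config.config_hash(),
        cohort=cohort,
        thresholds=thresholds,
        improvement=improvement,
        anova=pd.DataFrame(anova_rows),
        lsd=lsd,
        selections=selections,
        plateau=plateau,
        warnings=warnings,
    )


def run_emulation(config: ExperimentConfig | None = None, seed: int = 0) -> RunReport:
    """Simulate the full study and run the analysis battery on the result."""
    if config is None:
        config = ExperimentConfig()
    cohort = generate_cohort(config.design, np.random.default_rng(seed))
    streams = np.random.SeedSequence(seed).spawn(len(cohort) + 1)
    rows: list[dict[str, Any]] = []
    n_inter: list[int] = []
    n_capped = 0
    for obs, stream in zip(cohort, streams[1:]):
        obs_rows, n, reached = _simulate_observer(
            obs, config, np.random.default_rng(stream)
        )
        rows.extend(obs_rows)
        n_inter.append(n)
        if not reached:
            n_capped += 1
    warnings = []
    if n_capped:
        warnings.append(
            f"{n_capped} observers hit the intermediate-session cap "
            f"({config.max_intermediate_sessions}) before the plateau criterion fired"
        )
    plateau = {
        "mean_sessions": float(np.mean(n_inter)),
        "sd_sessions": float(np.std(n_inter, ddof=1)) if len(n_inter) > 1 else 0.0,
        "n_capped": float(n_capped),
    }
    thresholds = pd.DataFrame(rows)
    return run_analysis(
        thresholds,
        config,
        cohort=cohort_table(cohort),
        seed=seed,
        plateau=plateau,
        warnings=warnings,
    )
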
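"""Batch experimentation: the four scenario-policy arms and their comparison.

The default plan runs four arms — baseline-ca, baseline-fifo, replacement-ca,
training-ca — 60 seeded replicates each.  Seeds are ``base_seed + replicate``
and shared across arms (common random numbers), so replicate *i* of every arm
sees the same patient-difficulty and noise draws until the dynamics diverge;
paired comparisons are then lower-variance than independent seeding.

The statistical layer reports everything and chooses nothing: Welch's t,
the Mann-Whitney rank-sum test, Cohen's d, and Shapiro-Wilk normality checks
per arm, with an omnibus one-way ANOVA / Kruskal-Wallis across more than two
arms.  No multiple-testing correction is applied by default (this is an
exploratory what-if tool); a Holm adjustment is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig, validate_config
from .engine import run_shift
from .eventlog import EXECUTE_START, EventLog
from .metrics import doctor_rows, nurse_rows, run_row

DEFAULT_COMBINATIONS: tuple[tuple[str, str], ...] = (
    ("baseline", "ca"),
    ("baseline", "fifo"),
    ("replacement", "ca"),
    ("training", "ca"),
)


@dataclass
class ExperimentPlan:
    combinations: tuple[tuple[str, str], ...] = DEFAULT_COMBINATIONS
    n_runs: int = 60
    base_seed: int = 0
    template: Optional[SimConfig] = None

    def configs(self):
        template = self.template if self.template is not None else SimConfig()
        for scenario, policy in self.combinations:
            for rep in range(self.n_runs):
                seed = self.base_seed + rep
                yield validate_config(
                    replace(
                        template,
                        scenario=scenario,
                        policy=policy,
                        seed=seed,
                        run_id=f"{scenario}-{policy}-s{seed}",
                    )
                )


@dataclass
class BatchResult:
    """Per-run, per-doctor and per-nurse metric tables for a whole batch."""

    runs: pd.DataFrame
    doctors: pd.DataFrame
    nurses: pd.DataFrame
    logs: dict[str, EventLog] = field(default_factory=dict)


def run_batch(plan: ExperimentPlan, keep_logs: bool = False) -> BatchResult:
    """Execute the plan; any failed run aborts with its seed and config echoed."""
    runs, doctors, nurses, logs = [], [], [], {}
    for config in plan.configs():
        try:
            metrics, log = run_shift(config)
        except Exception as exc:  # noqa: BLE001 - reraise with provenance
            raise RuntimeError(
                f"run {config.run_id!r} (seed {config.seed}, scenario {config.scenario}, "
                f"policy {config.policy}) failed: {exc}"
            ) from exc
        meta = {
            "run_id": config.run_id,
            "scenario": config.scenario,
            "policy": config.policy,
            "seed": config.seed,
        }
        row = run_row(metrics, meta)
        row["combo"] = config.combo()
        runs.append(row)
        for r in doctor_rows(metrics, meta):
            r["combo"] = config.combo()
            doctors.append(r)
        for r in nurse_rows(metrics, meta):
            r["combo"] = config.combo()
            nurses.append(r)
        if keep_logs:
            logs[config.run_id] = log
    return BatchResult(
        runs=pd.DataFrame(runs),
        doctors=pd.DataFrame(doctors),
        nurses=pd.DataFrame(nurses),
        logs=logs,
    )


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled == 0:
        return 0.0 if a.mean() == b.mean() else math.inf
    return float((a.mean() - b.mean()) / math.sqrt(pooled))


def compare(table: pd.DataFrame, metric: str, combo_a: str, combo_b: str) -> dict:
    """Two-arm comparison of one metric: Welch t, rank-sum, effect size.

    Reports every statistic rather than selecting one; degenerate inputs
    (identical zero-variance samples) are flagged instead of crashing.
    """
    a = table.loc[table["combo"] == combo_a, metric].to_numpy(dtype=float)
    b = table.loc[table["combo"] == combo_b, metric].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each combination needs at least 2 runs to compare")
    out = {
        "metric": metric,
        "combo_a": combo_a,
        "combo_b": combo_b,
        "n_a": len(a),
        "n_b": len(b),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)),
        "sd_b": float(b.std(ddof=1)),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "iqr_a": float(np.subtract(*np.percentile(a, [75, 25]))),
        "iqr_b": float(np.subtract(*np.percentile(b, [75, 25]))),
        "cohens_d": _cohens_d(a, b),
        "degenerate": False,
    }
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        out.update(
            degenerate=True, welch_t=math.nan, welch_p=math.nan,
            ranksum_u=math.nan, ranksum_p=math.nan,
            shapiro_p_a=math.nan, shapiro_p_b=math.nan,
        )
        return out
    welch = stats.ttest_ind(a, b, equal_var=False)
    u = stats.mannwhitneyu(a, b, alternative="two-sided")
    out["welch_t"] = float(welch.statistic)
    out["welch_p"] = float(welch.pvalue)
    out["ranksum_u"] = float(u.statistic)
    out["ranksum_p"] = float(u.pvalue)
    out["shapiro_p_a"] = (
        float(stats.shapiro(a).pvalue) if len(a) >= 3 and a.std() > 0 else math.nan
    )
    out["shapiro_p_b"] = (
        float(stats.shapiro(b).pvalue) if len(b) >= 3 and b.std() > 0 else math.nan
    )
    return out


def omnibus(table: pd.DataFrame, metric: str, combos: Sequence[str] | None = None) -> dict:
    """One-way ANOVA and Kruskal-Wallis across all (or the given) arms."""
    if combos is None:
        combos = sorted(table["combo"].unique())
    groups = [
        table.loc[table["combo"] == c, metric].to_numpy(dtype=float) for c in combos
    ]
    anova = stats.f_oneway(*groups)
    kruskal = stats.kruskal(*groups)
    return {
        "metric": metric,
        "combos": list(combos),
        "anova_F": float(anova.statistic),
        "anova_p": float(anova.pvalue),
        "kruskal_H": float(kruskal.statistic),
        "kruskal_p": float(kruskal.pvalue),
    }


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional, off by default)."""
    order = np.argsort(pvalues)
    m = len(pvalues)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def summarize_tradeoffs(batch: BatchResult) -> tuple[pd.DataFrame, dict]:
    """Per-arm means of the headline metrics plus directional flags.

    Flags name the arm that maximizes throughput, minimizes delay, minimizes
    time damage, and minimizes low-performer failures; ties yield no flag.
    """
    runs = batch.runs
    summary = (
        runs.groupby("combo")[["patients_served", "total_delay_s", "time_damage_s"]]
        .mean()
        .reset_index()
    )
    low = batch.nurses[batch.nurses["quality"] == "low"]
    low_failures = low.groupby("combo")["failures"].mean().rename("low_nurse_failures")
    summary = summary.merge(low_failures, on="combo", how="left")

    def _flag(series: pd.Series, best) -> Optional[str]:
        target = best(series)
        winners = summary.loc[series == target, "combo"].tolist()
        return winners[0] if len(winners) == 1 else None

    flags = {
        "max_served": _flag(summary["patients_served"], max),
        "min_delay": _flag(summary["total_delay_s"], min),
        "min_damage": _flag(summary["time_damage_s"], min),
        "min_low_nurse_failures": _flag(summary["low_nurse_failures"], min),
    }
    return summary, flags


def nurse_duration_thirds(
    log: EventLog, nurse_id: int, shift_length_s: float
) -> tuple[float, float, float]:
    """Mean executed task duration of one nurse per shift third (nan if none).

    Used to trace the mentored nurse's learning curve in the Training arm.
    """
    edges = (shift_length_s / 3.0, 2.0 * shift_length_s / 3.0)
    buckets: list[list[float]] = [[], [], []]
    for rec in log.of_kind(EXECUTE_START):
        if rec.actor != nurse_id:
            continue
        idx = 0 if rec.time_s < edges[0] else (1 if rec.time_s < edges[1] else 2)
        buckets[idx].append(float(rec.detail["duration_s"]))
    return tuple(float(np.mean(b)) if b else math.nan for b in buckets)
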
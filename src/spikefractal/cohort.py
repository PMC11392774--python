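"""Cohort-level experiment: paired baseline vs stimulation comparisons.

Generates (or accepts) a cohort of units of both cell types, computes every
per-unit metric under both conditions, and runs the group statistics:
Shapiro-Wilk normality checks per condition followed by a paired t-test on
the per-unit baseline/stimulation differences.  Raw two-sided p-values are
reported; no multiple-testing correction is applied.

Default cohort shape is 25 pyramidal-like and 14 interneuron-like units.
Default stimulation parameters: 50 Hz entrainment with per-cycle response
probability 0.10 (pyramidal) / 0.65 (interneuron) and strongly persistent
cycle-skipping (failure_H = 0.8); baselines are weakly correlated
spontaneous firing (bursty for pyramidal cells, scattered for
interneurons).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import (
    DegenerateDataError,
    InvalidParameterError,
    SpikeFractalError,
)
from . import fano as fano_mod
from . import hurst as hurst_mod
from . import metrics as metrics_mod
from .synthetic import (
    BaselineConfig,
    EntrainmentConfig,
    generate_baseline_train,
    generate_entrained_train,
)
from .trains import SpikeTrain

logger = logging.getLogger(__name__)

__all__ = [
    "METRICS",
    "ExperimentConfig",
    "CohortResult",
    "unit_metrics",
    "paired_comparison",
    "unpaired_comparison",
    "run_experiment",
]

#: Metric names, in report order.
METRICS = ("rate", "cv", "apen", "frac_0_8ms", "frac_19_21ms", "alpha", "H")


def unit_metrics(
    train: SpikeTrain,
    metrics: tuple[str, ...] = METRICS,
    fano_t_min: float = 0.1,
    fano_t_max: float = 10.0,
    fano_fit_lo: float = fano_mod.DEFAULT_FIT_LO,
    fano_fit_hi: float = fano_mod.DEFAULT_FIT_HI,
    curves: dict | None = None,
) -> dict[str, float]:
    """Compute the requested per-unit metrics; failures become NaN.

    A metric that cannot be computed for this train (too few spikes, a
    degenerate sequence) is recorded as NaN and later excluded pairwise
    from the group tests.  If ``curves`` is a dict, fitted Fano and R/S
    curves are stashed under ``(unit_id, condition)``.
    """
    out: dict[str, float] = {}
    isis = None
    try:
        isis = metrics_mod.to_isi(train)
    except SpikeFractalError as exc:
        logger.warning("unit %s/%s: %s", train.unit_id, train.condition, exc)

    def attempt(name: str, fn: Callable[[], float]) -> None:
        if name not in metrics:
            return
        try:
            out[name] = float(fn())
        except SpikeFractalError as exc:
            logger.warning(
                "unit %s/%s: metric %s failed (%s)",
                train.unit_id, train.condition, name, exc,
            )
            out[name] = float("nan")

    attempt("rate", lambda: metrics_mod.firing_rate(train))
    if isis is None:
        for name in metrics:
            out.setdefault(name, float("nan"))
        return out
    attempt("cv", lambda: metrics_mod.cv(isis))
    attempt("apen", lambda: metrics_mod.apen(isis))
    attempt("frac_0_8ms", lambda: metrics_mod.isi_fraction(isis, 0.0, 8.0))
    attempt("frac_19_21ms", lambda: metrics_mod.isi_fraction(isis, 19.0, 21.0))

    def _alpha() -> float:
        curve = fano_mod.fano_curve(train, T_min=fano_t_min, T_max=fano_t_max)
        a = fano_mod.fano_alpha(curve, fit_lo=fano_fit_lo, fit_hi=fano_fit_hi)
        if curves is not None:
            curves.setdefault((train.unit_id, train.condition), {})["fano"] = curve
        return a

    def _hurst() -> float:
        curve = hurst_mod.rs_curve(isis)
        h = hurst_mod.hurst_exponent(curve)
        if curves is not None:
            curves.setdefault((train.unit_id, train.condition), {})["rs"] = curve
        return h

    attempt("alpha", _alpha)
    attempt("H", _hurst)
    return out


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def paired_comparison(
    baseline: np.ndarray,
    stim: np.ndarray,
    alternative: str = "two-sided",
) -> dict[str, float]:
    """Shapiro-Wilk per condition plus a paired t-test on stim - baseline.

    The t statistic is d_bar / (s_d / sqrt(n)) with d = stim - baseline, so
    positive t means an increase under stimulation.
    """
    baseline = np.asarray(baseline, dtype=float)
    stim = np.asarray(stim, dtype=float)
    if baseline.shape != stim.shape:
        raise InvalidParameterError("paired samples must have equal length")
    if baseline.size < 3:
        raise InvalidParameterError("paired comparison needs >= 3 pairs")
    diff = stim - baseline
    if np.std(diff, ddof=1) == 0:
        raise DegenerateDataError(
            "all pairwise differences identical (zero variance): "
            "the paired t statistic is undefined"
        )
    t_stat, t_p = stats.ttest_rel(stim, baseline, alternative=alternative)

    def _shapiro_p(x: np.ndarray) -> float:
        # normality is undefined for a constant sample; report NaN
        if np.ptp(x) == 0:
            return float("nan")
        return float(stats.shapiro(x).pvalue)

    return {
        "n": int(baseline.size),
        "mean_baseline": float(np.mean(baseline)),
        "sd_baseline": float(np.std(baseline, ddof=1)),
        "mean_stim": float(np.mean(stim)),
        "sd_stim": float(np.std(stim, ddof=1)),
        "shapiro_p_baseline": _shapiro_p(baseline),
        "shapiro_p_stim": _shapiro_p(stim),
        "paired_t_stat": float(t_stat),
        "paired_t_p": float(t_p),
    }


def unpaired_comparison(
    a: np.ndarray, b: np.ndarray, equal_var: bool = False
) -> dict[str, float]:
    """Two-sample t-test between independent groups (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {
        "n_a": int(a.size),
        "n_b": int(b.size),
        "t_stat": float(t_stat),
        "t_p": float(t_p),
        "equal_var": bool(equal_var),
    }


# ---------------------------------------------------------------------------
# Experiment configuration and runner
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Full cohort experiment: generators per cell type and condition.

    ``baseline_*`` entries override :class:`BaselineConfig` fields;
    ``stimulation_*`` entries override :class:`EntrainmentConfig` fields
    (when ``stimulation_model`` is ``"entrained"``) or
    :class:`BaselineConfig` fields (when it is ``"baseline"``, used for
    null-calibration runs where both conditions share one generator).
    """

    n_pyramidal: int = 25
    n_interneuron: int = 14
    duration: float = 60.0
    seed: int = 0
    stimulation_model: str = "entrained"
    baseline_pyramidal: dict[str, Any] = field(default_factory=dict)
    baseline_interneuron: dict[str, Any] = field(default_factory=dict)
    stimulation_pyramidal: dict[str, Any] = field(
        default_factory=lambda: {"per_cycle_probability": 0.10, "failure_H": 0.8}
    )
    stimulation_interneuron: dict[str, Any] = field(
        default_factory=lambda: {"per_cycle_probability": 0.65, "failure_H": 0.8}
    )
    metrics: tuple[str, ...] = METRICS
    fano_t_min: float = 0.1
    fano_t_max: float = 10.0
    fano_fit_lo: float = fano_mod.DEFAULT_FIT_LO
    fano_fit_hi: float = fano_mod.DEFAULT_FIT_HI

    def __post_init__(self) -> None:
        if self.stimulation_model not in ("entrained", "baseline"):
            raise InvalidParameterError(
                "stimulation_model must be 'entrained' or 'baseline'"
            )
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise InvalidParameterError(f"unknown metrics: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        if "metrics" in d:
            d["metrics"] = tuple(d["metrics"])
        return cls(**d)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["metrics"] = list(d["metrics"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class CohortResult:
    """Per-unit metric table, group summaries, and paired test results."""

    per_unit: pd.DataFrame
    summaries: pd.DataFrame
    tests: dict[str, dict[str, Any]]
    config: ExperimentConfig
    curves: dict | None = None

    def save(self, outdir: str | Path) -> None:
        """Write per_unit.csv, summary.csv, tests.json, run.json, curves/."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_unit.to_csv(outdir / "per_unit.csv", index=False)
        self.summaries.to_csv(outdir / "summary.csv", index=False)
        (outdir / "tests.json").write_text(json.dumps(self.tests, indent=1))
        from . import __version__

        run_info = {
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "config": self.config.to_dict(),
            "version": __version__,
        }
        (outdir / "run.json").write_text(json.dumps(run_info, indent=1))
        if self.curves:
            cdir = outdir / "curves"
            cdir.mkdir(exist_ok=True)
            for (unit, cond), by_kind in self.curves.items():
                for kind, curve in by_kind.items():
                    curve.save(cdir / f"{unit}_{cond}_{kind}.csv")


def _unit_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-unit child seeds (kept below 2**31)."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF


def _generate_pair(
    cell_type: str, unit_id: str, cfg: ExperimentConfig, unit_seed: int
) -> tuple[SpikeTrain, SpikeTrain]:
    base_over = (
        cfg.baseline_pyramidal if cell_type == "pyramidal" else cfg.baseline_interneuron
    )
    stim_over = (
        cfg.stimulation_pyramidal
        if cell_type == "pyramidal"
        else cfg.stimulation_interneuron
    )
    base_factory = (
        BaselineConfig.pyramidal if cell_type == "pyramidal" else BaselineConfig.interneuron
    )
    base_cfg = base_factory(seed=int(unit_seed), duration=cfg.duration, **base_over)
    baseline = generate_baseline_train(
        base_cfg, cell_type=cell_type, unit_id=unit_id, condition="baseline"
    )
    stim_seed = int(unit_seed) + 1
    if cfg.stimulation_model == "entrained":
        stim = generate_entrained_train(
            EntrainmentConfig(seed=stim_seed, duration=cfg.duration, **stim_over),
            cell_type=cell_type,
            unit_id=unit_id,
        )
    else:
        stim_cfg = base_factory(seed=stim_seed, duration=cfg.duration, **stim_over)
        stim = generate_baseline_train(
            stim_cfg, cell_type=cell_type, unit_id=unit_id, condition="stimulation"
        )
    return baseline, stim


def run_experiment(
    config: ExperimentConfig | dict | None = None,
    trains: list[SpikeTrain] | None = None,
    keep_curves: bool = False,
    alternative: str = "two-sided",
) -> CohortResult:
    """Run the full cohort pipeline and assemble group statistics.

    If ``trains`` is given, those trains are analyzed instead of generated
    ones (they must carry unit_id / condition / cell_type labels).  Paired
    tests per (cell_type, metric) use only units with finite values in both
    conditions; a test with fewer than 3 complete pairs is skipped with a
    recorded reason.  The run fails only if no metric has 3 complete pairs.
    """
    if config is None:
        config = ExperimentConfig()
    elif isinstance(config, dict):
        config = ExperimentConfig.from_dict(config)

    curves: dict | None = {} if keep_curves else None
    records: list[dict[str, Any]] = []

    if trains is None:
        specs = [("pyramidal", i) for i in range(config.n_pyramidal)] + [
            ("interneuron", i) for i in range(config.n_interneuron)
        ]
        seeds = _unit_seeds(config.seed, 2 * len(specs))
        for k, (cell_type, i) in enumerate(specs):
            unit_id = f"{cell_type[:3]}{i:03d}"
            baseline, stim = _generate_pair(
                cell_type, unit_id, config, seeds[2 * k]
            )
            for tr in (baseline, stim):
                rec = {
                    "unit_id": unit_id,
                    "cell_type": cell_type,
                    "condition": tr.condition,
                }
                rec.update(
                    unit_metrics(
                        tr,
                        metrics=config.metrics,
                        fano_t_min=config.fano_t_min,
                        fano_t_max=config.fano_t_max,
                        fano_fit_lo=config.fano_fit_lo,
                        fano_fit_hi=config.fano_fit_hi,
                        curves=curves,
                    )
                )
                records.append(rec)
    else:
        for tr in trains:
            rec = {
                "unit_id": tr.unit_id,
                "cell_type": tr.cell_type,
                "condition": tr.condition,
            }
            rec.update(
                unit_metrics(
                    tr,
                    metrics=config.metrics,
                    fano_t_min=config.fano_t_min,
                    fano_t_max=config.fano_t_max,
                    fano_fit_lo=config.fano_fit_lo,
                    fano_fit_hi=config.fano_fit_hi,
                    curves=curves,
                )
            )
            records.append(rec)

    per_unit = pd.DataFrame.from_records(records)
    metric_cols = [m for m in config.metrics if m in per_unit.columns]

    # mean +/- SD summaries per (cell_type, condition, metric)
    rows = []
    for (cell_type, cond), grp in per_unit.groupby(["cell_type", "condition"]):
        for m in metric_cols:
            vals = grp[m].dropna()
            rows.append(
                {
                    "cell_type": cell_type,
                    "condition": cond,
                    "metric": m,
                    "n": int(vals.size),
                    "mean": float(vals.mean()) if vals.size else float("nan"),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                }
            )
    summaries = pd.DataFrame(rows)

    # paired tests per (cell_type, metric)
    tests: dict[str, dict[str, Any]] = {}
    any_tested = False
    wide = per_unit.pivot_table(
        index=["cell_type", "unit_id"], columns="condition", values=metric_cols
    )
    for cell_type in per_unit["cell_type"].unique():
        for m in metric_cols:
            key = f"{cell_type}:{m}"
            try:
                sub = wide.loc[cell_type, m]
            except KeyError:
                tests[key] = {"skipped": "metric/conditions missing"}
                continue
            if not {"baseline", "stimulation"} <= set(sub.columns):
                tests[key] = {"skipped": "both conditions required"}
                continue
            paired = sub[["baseline", "stimulation"]].dropna()
            if len(paired) < 3:
                tests[key] = {
                    "skipped": f"only {len(paired)} complete pairs (need >= 3)"
                }
                continue
            try:
                tests[key] = paired_comparison(
                    paired["baseline"].to_numpy(),
                    paired["stimulation"].to_numpy(),
                    alternative=alternative,
                )
                any_tested = True
            except SpikeFractalError as exc:
                tests[key] = {"skipped": str(exc)}
    if not any_tested:
        raise DegenerateDataError("no metric has >= 3 complete baseline/stim pairs")

    return CohortResult(
        per_unit=per_unit, summaries=summaries, tests=tests,
        config=config, curves=curves,
    )
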
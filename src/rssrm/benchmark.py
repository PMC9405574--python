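"""Twenty-behavior, six-model comparison harness.

For every behavior the harness fits each roster model to the simulated
membrane potential, converts the prediction into spike trains, scores RMSE,
van Rossum distance and tolerance-adjusted F1, and aggregates the records
into per-behavior, class-average (all / one-spike / multiple-spike) and
ranking tables.  The ground-truth simulator itself is carried through the
identical scoring pipeline as the ``izhikevich`` reference row.

Pruned families share one per-behavior parameter budget; the shipped default
budgets average about 100 parameters at full scale and shrink in proportion
to the duration ``scale``.
"""

from __future__ import annotations

import hashlib
import logging
import time
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

from .conversion import (
    BETA_GRID_NARROW,
    BETA_GRID_WIDE,
    ConversionConfig,
    select_beta,
)
from .izhikevich import (
    BEHAVIOR_NAMES,
    DegenerateTraceError,
    SimulationTrace,
    SpikeTrain,
    build_behavior_catalog,
    classify_behavior,
    extract_spike_train,
    simulate,
)
from .metrics import rmse, van_rossum
from .models import REDUCED_FAMILIES, NeuronModel

__all__ = [
    "EvaluationRecord",
    "BenchmarkConfig",
    "DEFAULT_TARGET_COUNTS",
    "run_model_on_behavior",
    "aggregate",
    "rank_models",
    "run_benchmark",
]

logger = logging.getLogger(__name__)

#: default per-behavior parameter budgets for the pruned families (full scale)
DEFAULT_TARGET_COUNTS = {
    "a": 95, "b": 109, "c": 100, "d": 101, "e": 137, "f": 127, "g": 200,
    "h": 201, "i": 102, "j": 97, "k": 10, "l": 20, "m": 22, "n": 105,
    "o": 30, "p": 172, "q": 10, "r": 51, "s": 160, "t": 156,
}

ALL_MODELS = ("izhikevich", "srm", "ssrm", "rsrm", "rssrm", "pcr", "rcr")

#: metrics ranked in the comparison tables; False = lower is better
RANK_METRICS = {"rmse": False, "vrd": False, "f1": True}

RECORD_COLUMNS = [
    "behavior", "behavior_class", "model", "n_params", "rmse", "vrd",
    "precision", "recall", "f1", "beta", "tau_max", "tau_capped",
]


@dataclass
class EvaluationRecord:
    """Scores of one (behavior, model) cell."""

    behavior: str
    behavior_class: str
    model: str
    n_params: float
    rmse: float
    vrd: float
    precision: float
    recall: float
    f1: float
    beta: float
    tau_max: float
    tau_capped: bool
    fit_seconds: float = 0.0  # informational; excluded from written tables
    eval_seconds: float = 0.0


@dataclass
class BenchmarkConfig:
    """Settings of one benchmark run."""

    scale: float = 1.0
    dt: float = 0.25
    models: tuple = ALL_MODELS
    target_counts: dict | None = None  # None: defaults scaled by `scale`
    l2: float = 0.01
    zero_tol: float = 1e-8
    slack: float = 0.02
    tolerance_cap: float = 30.0  # ms, applies to pcr / rcr only
    vrd_tau: float = 1.0  # ms
    display_zero_tol: float = 1e-6  # table display rounds tinier VRD to 0
    seed: int = 0

    def resolved_targets(self) -> dict:
        base = self.target_counts or DEFAULT_TARGET_COUNTS
        if self.target_counts is None and self.scale != 1.0:
            return {k: max(1, round(v * self.scale)) for k, v in base.items()}
        return dict(base)

    def conversion_for(self, model: str) -> ConversionConfig:
        if model in ("izhikevich", "srm", "ssrm"):
            return ConversionConfig(beta_grid=BETA_GRID_NARROW)
        cap = self.tolerance_cap if model in ("pcr", "rcr") else None
        return ConversionConfig(beta_grid=BETA_GRID_WIDE, tolerance_cap=cap)

    def digest(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _windowed_truth(trace: SimulationTrace, rows: np.ndarray) -> SpikeTrain:
    indicator = extract_spike_train(trace).indicator[rows]
    return SpikeTrain.from_indicator(
        indicator, dt=trace.dt, t0=rows[0] * trace.dt
    )


def run_model_on_behavior(
    model_name: str, trace: SimulationTrace, config: BenchmarkConfig
) -> EvaluationRecord:
    """Fit one model to one behavior and score it end to end."""
    behavior_class = classify_behavior(trace)  # raises on degenerate traces
    targets = config.resolved_targets()

    t_fit = time.perf_counter()
    if model_name == "izhikevich":
        rows = np.arange(trace.n_steps)
        u_hat = trace.v
        n_params = np.nan
    else:
        model = NeuronModel(
            family=model_name,
            target_count=(
                targets[trace.name] if model_name in REDUCED_FAMILIES else None
            ),
            l2=config.l2,
            zero_tol=config.zero_tol,
            slack=config.slack,
        )
        X = np.column_stack([trace.I, extract_spike_train(trace).indicator])
        model.fit(X, trace.v)
        rows = model.target_rows_
        u_hat = model.predict(X)
        n_params = model.n_params_
    fit_seconds = time.perf_counter() - t_fit

    t_eval = time.perf_counter()
    truth = _windowed_truth(trace, rows)
    score_rmse = rmse(trace.v[rows], u_hat)
    chosen = select_beta(
        u_hat,
        truth,
        config.conversion_for(model_name),
        dt=trace.dt,
        t0=rows[0] * trace.dt,
    )
    # VRD uses the raw (Algorithm-1) train: its cross terms already compare
    # every spike with every other, so no tolerance adjustment is applied
    vrd = van_rossum(truth.times, chosen["raw_train"].times, tau=config.vrd_tau)
    tol = chosen["tolerance"]
    eval_seconds = time.perf_counter() - t_eval

    report = chosen["report"]
    return EvaluationRecord(
        behavior=trace.name,
        behavior_class=behavior_class,
        model=model_name,
        n_params=float(n_params),
        rmse=score_rmse,
        vrd=vrd,
        precision=report.precision,
        recall=report.recall,
        f1=report.f1,
        beta=chosen["beta"],
        tau_max=tol.tau_max if tol is not None else np.nan,
        tau_capped=bool(tol.capped) if tol is not None else False,
        fit_seconds=fit_seconds,
        eval_seconds=eval_seconds,
    )


def records_frame(records) -> pd.DataFrame:
    """Assemble evaluation records into the per-behavior table."""
    df = pd.DataFrame([asdict(r) for r in records])
    return df[RECORD_COLUMNS + ["fit_seconds", "eval_seconds"]]


def aggregate(df: pd.DataFrame, which: str = "all") -> pd.DataFrame:
    """Arithmetic per-model means over a behavior class.

    ``which`` is ``all``, ``one-spike`` or ``multiple-spike``.  Raises if any
    model misses a behavior of the class.
    """
    if which != "all":
        df = df[df["behavior_class"] == which]
    if df.empty:
        raise ValueError(f"no records for class {which!r}")
    behaviors = set(df["behavior"].unique())
    gaps = {
        model: sorted(behaviors - set(sub["behavior"]))
        for model, sub in df.groupby("model")
        if behaviors - set(sub["behavior"])
    }
    if gaps:
        raise ValueError(f"incomplete records for class {which!r}: {gaps}")
    cols = ["n_params", "rmse", "vrd", "precision", "recall", "f1", "tau_max"]
    out = df.groupby("model")[cols].mean()
    order = [m for m in ALL_MODELS if m in out.index]
    return out.loc[order]


def rank_models(df: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-behavior competition ranks (ties share the minimal rank).

    Lower is better for rmse/vrd, higher for f1; a ``mean`` row is appended.
    """
    if metric not in RANK_METRICS:
        raise KeyError(f"unknown ranking metric {metric!r}")
    higher_better = RANK_METRICS[metric]
    wide = df.pivot(index="behavior", columns="model", values=metric)
    if wide.shape[1] < 2:
        raise ValueError("ranking needs at least two models")
    values = -wide.to_numpy() if higher_better else wide.to_numpy()
    ranks = np.vstack([rankdata(row, method="min") for row in values])
    out = pd.DataFrame(
        ranks.astype(float), index=wide.index, columns=wide.columns
    )
    out.loc["mean"] = out.mean(axis=0)
    order = [m for m in ALL_MODELS if m in out.columns]
    return out[order]


def run_benchmark(config: BenchmarkConfig, out_dir=None, plots: bool = False):
    """Run the full comparison; optionally persist tables and figures.

    Returns a dict with the record table, the three class summaries and the
    per-metric rankings of the parameter-reduced models.
    """
    rng_seed = int(config.seed)  # logged; the pipeline itself is deterministic
    catalog = build_behavior_catalog(dt=config.dt, scale=config.scale)
    records, failures = [], []
    traces = {}
    for spec in catalog:
        trace = simulate(spec)
        if len(trace.spike_times) == 0:
            warnings.warn(
                f"behavior {spec.name!r} is degenerate (no spikes) at "
                f"scale={config.scale}; skipping",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        traces[spec.name] = trace

    for name, trace in traces.items():
        for model_name in config.models:
            try:
                records.append(run_model_on_behavior(model_name, trace, config))
            except Exception as exc:  # isolate the failing cell
                failures.append((name, model_name, repr(exc)))
                logger.warning("cell (%s, %s) failed: %s", name, model_name, exc)

    df = records_frame(records)
    display_df = df.copy()
    tiny = display_df["vrd"].abs() < config.display_zero_tol
    display_df.loc[tiny, "vrd"] = 0.0

    results = {"records": df, "failures": failures}
    for which, key in (
        ("all", "summary_all"),
        ("one-spike", "summary_one_spike"),
        ("multiple-spike", "summary_multiple_spike"),
    ):
        try:
            results[key] = aggregate(df, which)
        except ValueError as exc:
            logger.warning("summary %r unavailable: %s", which, exc)

    reduced_present = [m for m in config.models if m in REDUCED_FAMILIES]
    if len(reduced_present) >= 2:
        sub = df[df["model"].isin(reduced_present)]
        for metric in RANK_METRICS:
            try:
                results[f"ranks_{metric}"] = rank_models(sub, metric)
            except ValueError as exc:
                logger.warning("ranking %r unavailable: %s", metric, exc)

    if out_dir is not None:
        _write_outputs(results, display_df, config, out_dir, plots, traces)
    return results


def _write_outputs(results, display_df, config, out_dir, plots, traces):
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # timing columns are wall-clock noise; the persisted tables must be
    # byte-identical across reruns of the same config
    display_df.drop(columns=["fit_seconds", "eval_seconds"]).to_csv(
        out / "records.csv", index=False, float_format="%.6g"
    )
    for key in (
        "summary_all", "summary_one_spike", "summary_multiple_spike",
        "ranks_rmse", "ranks_vrd", "ranks_f1",
    ):
        if key in results:
            results[key].to_csv(out / f"{key}.csv", float_format="%.6g")
    meta = {"config": asdict(config), "config_digest": config.digest(),
            "seed": config.seed, "failures": results["failures"]}
    (out / "run_config.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    if plots:
        _write_figures(display_df, config, out, traces)


def _write_figures(df, config, out, traces):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 5, figsize=(22, 12), sharex=False)
    for ax, (name, trace) in zip(axes.ravel(), sorted(traces.items())):
        ax.plot(trace.t, trace.v, lw=0.6)
        ax.set_title(name, fontsize=8)
    fig.suptitle("ground-truth membrane potentials (mV) vs time (ms)")
    fig.tight_layout()
    fig.savefig(out / "behaviors.png", dpi=110)
    plt.close(fig)

    sub = df[df["model"] != "izhikevich"]
    if not sub.empty:
        fig, ax = plt.subplots(figsize=(9, 4))
        for model, grp in sub.groupby("model"):
            ax.plot(grp["behavior"], grp["f1"], marker="o", lw=0.8, label=model)
        ax.set_xlabel("behavior")
        ax.set_ylabel("tolerance-adjusted F1")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "f1_by_behavior.png", dpi=110)
        plt.close(fig)
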
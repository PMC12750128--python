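"""CV1 cross-validation, prediction metrics and relative efficiency.

CV1 masks entire lines ("untested lines in tested environments"): every
observation of a test line, in every environment, is held out.  Partitions
are independent seeded random 80/20 splits of the line set, not folds.
Metrics on the masked set: Pearson correlation (COR), RMSE normalised by
the mean of the observed values (NRMSE), and the percentage of the true
top 10% / 20% of lines recovered in the predicted top set (PM_10, PM_20).
Relative efficiency compares each model to the per-metric best model:
RE_COR = (COR_best/COR_other - 1)*100 (likewise PM); for an error metric
the ratio inverts, RE_NRMSE = (NRMSE_other/NRMSE_best - 1)*100.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import RunConfig, log
from .kernels import Kernel, build_model_kernels, gaussian_kernel, linear_kernel
from .bayes_multikernel import PriorSpec, fit_gibbs, make_model_data

METRIC_NAMES = ("COR", "NRMSE", "PM10", "PM20")


class UndefinedMetricError(ValueError):
    """A metric is undefined for this test set (e.g. zero variance)."""


@dataclass(frozen=True)
class Partition:
    """One random train/test split of the line set."""

    train_lines: tuple[str, ...]
    test_lines: tuple[str, ...]
    index: int
    seed: int


def make_partitions(
    line_ids: list[str],
    n_partitions: int = 5,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> list[Partition]:
    """Independent seeded random splits; each holds out round(tf * J) lines."""
    J = len(line_ids)
    if J < 5:
        raise ValueError("need at least 5 lines to partition")
    n_test = int(round(test_fraction * J))
    if n_test == 0:
        raise ValueError(
            f"test_fraction={test_fraction} yields 0 test lines for J={J}"
        )
    parts = []
    for p in range(n_partitions):
        rng = np.random.default_rng([seed % 2**31, 101, p])
        order = rng.permutation(J)
        test = tuple(line_ids[i] for i in sorted(order[:n_test]))
        train = tuple(line_ids[i] for i in sorted(order[n_test:]))
        parts.append(Partition(train, test, p, seed))
    return parts


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _check_vectors(observed, predicted, min_len: int = 1):
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-D of equal length")
    if len(o) < min_len:
        raise UndefinedMetricError(f"need at least {min_len} pairs, got {len(o)}")
    return o, p


def cor_metric(observed, predicted) -> float:
    """Sample Pearson correlation between observed and predicted values."""
    o, p = _check_vectors(observed, predicted, min_len=3)
    if o.std() == 0 or p.std() == 0:
        raise UndefinedMetricError("zero variance in observed or predicted values")
    return float(np.corrcoef(o, p)[0, 1])


def nrmse_metric(observed, predicted) -> float:
    """RMSE divided by the mean of the observed values."""
    o, p = _check_vectors(observed, predicted)
    m = o.mean()
    if m == 0:
        raise UndefinedMetricError("mean of observed values is 0")
    return float(np.sqrt(np.mean((o - p) ** 2)) / m)


def pm_metric(
    observed, predicted, top_fraction: float, larger_is_better: bool = True
) -> float:
    """Percentage of the true top lines recovered in the predicted top set.

    The top-set size is ceil(top_fraction * n); ties are broken by stable
    original order.  ``larger_is_better=False`` flips the ranking for
    traits where small values are desirable.
    """
    o, p = _check_vectors(observed, predicted)
    n = len(o)
    if n < math.ceil(1.0 / top_fraction):
        raise UndefinedMetricError(
            f"test set of {n} too small for top fraction {top_fraction}"
        )
    s = math.ceil(top_fraction * n)
    sign = -1.0 if larger_is_better else 1.0
    top_obs = set(np.argsort(sign * o, kind="stable")[:s])
    top_pred = set(np.argsort(sign * p, kind="stable")[:s])
    return 100.0 * len(top_obs & top_pred) / s


def relative_efficiency(metric_best: float, metric_other: float, metric_kind: str) -> float:
    """RE in percent of the best model over another model for one metric.

    For COR/PM10/PM20: (best/other - 1) * 100; for NRMSE the ratio inverts:
    (other/best - 1) * 100.  A positive value quantifies the other model's
    shortfall (reports print COR/PM shortfalls with a minus sign attached
    to the other model).
    """
    if metric_kind not in METRIC_NAMES:
        raise ValueError(f"unknown metric kind {metric_kind!r}")
    if metric_kind == "NRMSE":
        if metric_best == 0:
            raise UndefinedMetricError("best NRMSE is 0; RE undefined")
        return (metric_other / metric_best - 1.0) * 100.0
    if metric_other <= 0:
        raise UndefinedMetricError(
            f"non-positive {metric_kind} for comparison model; RE undefined"
        )
    return (metric_best / metric_other - 1.0) * 100.0


def compute_metrics(
    observed, predicted, larger_is_better: bool = True
) -> dict[str, float]:
    """All four metrics; undefined ones are returned as NaN (and logged)."""
    out: dict[str, float] = {}
    for name, fn in (
        ("COR", lambda o, p: cor_metric(o, p)),
        ("NRMSE", lambda o, p: nrmse_metric(o, p)),
        ("PM10", lambda o, p: pm_metric(o, p, 0.10, larger_is_better)),
        ("PM20", lambda o, p: pm_metric(o, p, 0.20, larger_is_better)),
    ):
        try:
            out[name] = fn(observed, predicted)
        except UndefinedMetricError as exc:
            log.warning("metric %s undefined: %s", name, exc)
            out[name] = float("nan")
    return out


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-partition metric rows, their averages, RE tables and raw predictions."""

    rows: pd.DataFrame            # model, mode, environment, partition, metrics
    averages: pd.DataFrame        # partition column = "avg"
    re_tables: pd.DataFrame       # metric, environment, best_model, model, re_percent
    predictions: pd.DataFrame     # line, env, partition, model, observed, predicted

    def metric_average(self, model: str, metric: str, environment: str = "ALL") -> float:
        sel = self.averages[
            (self.averages["model"] == model)
            & (self.averages["environment"] == environment)
        ]
        if sel.empty:
            raise KeyError(f"no averaged row for {model}/{environment}")
        return float(sel.iloc[0][metric])


def build_base_kernels(
    X: pd.DataFrame, U: pd.DataFrame
) -> dict[str, Kernel]:
    """The four source kernels: linear/Gaussian x genomic/phenomic.

    X is the standardised marker matrix, U the standardised spectral
    matrix; Gaussian bandwidths use the median heuristic on each.
    """
    if list(X.index) != list(U.index):
        raise ValueError("marker and spectral matrices must share line order")
    return {
        "G": linear_kernel(X, "G"),
        "H": linear_kernel(U, "H"),
        "K": gaussian_kernel(X, "median", "K"),
        "K_H": gaussian_kernel(U, "median", "K_H"),
    }


def _fit_one(
    pheno: pd.DataFrame,
    kernels: list[Kernel],
    test_lines: tuple[str, ...],
    config: RunConfig,
    seed: int,
):
    data = make_model_data(pheno, kernels, test_lines)
    priors = PriorSpec(df0=config.sampler.df0, r2=config.sampler.r2)
    fit = fit_gibbs(
        data,
        priors=priors,
        n_iter=config.sampler.n_iter,
        burn_in=config.sampler.burn_in,
        thin=config.sampler.thin,
        seed=seed,
    )
    return data, fit


def run_experiment(
    config: RunConfig,
    phenotypes: pd.DataFrame,
    X: pd.DataFrame,
    U: pd.DataFrame,
) -> CVReport:
    """Full CV1 experiment over the configured models and mode.

    Builds the four base kernels once, then for every environment scope,
    model and partition masks the test lines, fits the multi-kernel model
    and scores the masked observations.  In multi-environment mode all
    environments are analysed jointly (environments as replications,
    scope "ALL"); in single-environment mode each environment is analysed
    separately and partitions are drawn within the environment's lines.
    """
    pheno = phenotypes[phenotypes["trait"] == config.trait].copy()
    if pheno.empty:
        raise ValueError(f"no phenotype records for trait {config.trait!r}")
    pheno["line"] = pheno["line"].astype(str)
    pheno["environment"] = pheno["environment"].astype(str)

    base = build_base_kernels(X, U)
    scopes: list[tuple[str, pd.DataFrame]]
    if config.mode == "multi_env":
        scopes = [("ALL", pheno)]
    else:
        scopes = [(env, grp) for env, grp in pheno.groupby("environment", sort=True)]

    rows, avg_rows, re_rows, pred_rows = [], [], [], []
    for env_name, sub in scopes:
        lines = sorted(sub["line"].unique())
        n_test = int(round(config.test_fraction * len(lines)))
        if len(lines) < 5 or n_test == 0:
            log.warning("environment %s skipped: only %d line(s) with records",
                        env_name, len(lines))
            continue
        sub_kernels = {nm: k.subset(lines) for nm, k in base.items()}
        partitions = make_partitions(
            lines, config.n_partitions, config.test_fraction, config.seed
        )
        for model_id in config.models:
            model_kernels = build_model_kernels(
                model_id,
                sub_kernels["G"], sub_kernels["H"],
                sub_kernels["K"], sub_kernels["K_H"],
                repair=config.kernels.psd_repair,
                diagonal_split=config.kernels.diagonal_split,
            )
            per_part = []
            for part in partitions:
                tag = zlib.crc32(f"{model_id}/{env_name}".encode()) % 2**31
                fit_seed = int(
                    np.random.default_rng(
                        [config.seed % 2**31, tag, part.index]
                    ).integers(2**31)
                )
                data, fit = _fit_one(
                    sub, model_kernels, part.test_lines, config, fit_seed
                )
                obs = data.y[data.mask]
                pred = fit.predictions.to_numpy()
                metrics = compute_metrics(obs, pred, config.larger_is_better)
                row = {
                    "model": model_id, "mode": config.mode,
                    "environment": env_name, "partition": part.index, **metrics,
                }
                per_part.append(row)
                rows.append(row)
                keys = fit.predictions.index
                pred_rows.append(pd.DataFrame({
                    "line": keys.get_level_values("line"),
                    "environment": keys.get_level_values("environment"),
                    "partition": part.index, "model": model_id,
                    "observed": obs, "predicted": pred,
                }))
                log.info(
                    "%s env=%s partition=%d COR=%.4f NRMSE=%.4f PM10=%.2f PM20=%.2f",
                    model_id, env_name, part.index, metrics["COR"],
                    metrics["NRMSE"], metrics["PM10"], metrics["PM20"],
                )
            dfp = pd.DataFrame(per_part)
            avg_rows.append({
                "model": model_id, "mode": config.mode, "environment": env_name,
                "partition": "avg",
                **{m: float(np.nanmean(dfp[m])) for m in METRIC_NAMES},
            })

        # per-metric relative-efficiency tables for this scope
        env_avg = [r for r in avg_rows if r["environment"] == env_name]
        for metric in METRIC_NAMES:
            vals = {r["model"]: r[metric] for r in env_avg
                    if np.isfinite(r[metric])}
            if not vals:
                continue
            best_model = (min if metric == "NRMSE" else max)(vals, key=vals.get)
            for model_id, v in vals.items():
                try:
                    re = relative_efficiency(vals[best_model], v, metric)
                except UndefinedMetricError:
                    re = float("nan")
                re_rows.append({
                    "metric": metric, "environment": env_name,
                    "best_model": best_model, "model": model_id,
                    "re_percent": re,
                })

    if not rows:
        raise ValueError("no environment had enough lines to evaluate")
    return CVReport(
        rows=pd.DataFrame(rows),
        averages=pd.DataFrame(avg_rows),
        re_tables=pd.DataFrame(re_rows),
        predictions=pd.concat(pred_rows, ignore_index=True),
    )
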
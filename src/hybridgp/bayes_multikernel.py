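"""Bayesian multi-kernel random-effects regression by Gibbs sampling.

Model:  y_i = mu + sum_k u_k[line(i)] + eps_i,  with u_k ~ N(0, sigma_k^2 K_k)
and eps_i ~ N(0, sigma^2).  Each kernel effect is sampled in the kernel's
eigenbasis (K = Phi Lambda Phi'; u = Phi delta) so the conditional of delta
is Gaussian with a diagonal precision whenever every line has the same
number of observations (the single-environment case), and a small m x m
Cholesky otherwise.  Variance components get scaled-inverse-chi-squared
full conditionals; masked responses are treated as latent and imputed each
iteration from their conditional normal, which is what makes line-masked
cross-validation (CV1) prediction a by-product of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_config import log
from .kernels import Kernel

_EIG_TOL = 1e-10
_MIN_EIG = -1e-8


@dataclass
class PriorSpec:
    """Scaled-inverse-chi-squared hyperpriors for the variance components.

    ``r2`` is the prior fraction of Var(y) attributed to the kernel effects
    jointly, split equally across kernels; scales are set so that the prior
    mode of each sigma_k^2 equals its share of Var(y) after accounting for
    the kernel's mean diagonal.
    """

    df0: float = 5.0
    r2: float = 0.5

    def __post_init__(self) -> None:
        if self.df0 <= 0:
            raise ValueError("df0 must be > 0")
        if not 0.0 < self.r2 < 1.0:
            raise ValueError("r2 must lie in (0, 1)")


@dataclass
class ModelData:
    """Responses, observation-to-line map, kernels and the CV mask."""

    y: np.ndarray
    line_index: np.ndarray          # observation -> row of the kernels
    kernels: list[Kernel]
    line_ids: list[str]
    mask: np.ndarray                # True = test observation (masked)
    obs_keys: list[tuple[str, str]] = field(default_factory=list)  # (line, env)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.line_index = np.asarray(self.line_index, dtype=int)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.y)
        if len(self.line_index) != n or len(self.mask) != n:
            raise ValueError("y, line_index and mask must have equal length")
        if not self.kernels:
            raise ValueError("at least one kernel is required")
        J = len(self.line_ids)
        for k in self.kernels:
            if k.line_ids != self.line_ids:
                raise ValueError(f"kernel {k.name!r} has mismatched line IDs")
        if self.line_index.min(initial=0) < 0 or self.line_index.max(initial=0) >= J:
            raise ValueError("line_index out of range")
        if not np.isfinite(self.y[~self.mask]).all():
            raise ValueError("non-finite response among unmasked observations")
        if (~self.mask).sum() == 0:
            raise ValueError("at least one unmasked observation is required")
        if not self.obs_keys:
            self.obs_keys = [
                (self.line_ids[j], "E0") for j in self.line_index
            ]

    @property
    def n(self) -> int:
        return len(self.y)


def make_model_data(
    phenotypes: pd.DataFrame,
    kernels: list[Kernel],
    test_lines: Sequence[str] = (),
) -> ModelData:
    """Assemble ModelData from a long phenotype table (single trait).

    All observations of a line in ``test_lines`` are masked (CV1).
    Phenotype rows whose line is absent from the kernels raise an error.
    """
    line_ids = kernels[0].line_ids
    pos = {lid: i for i, lid in enumerate(line_ids)}
    unknown = sorted(set(phenotypes["line"].astype(str)) - set(line_ids))
    if unknown:
        raise ValueError(f"phenotype line(s) missing from kernels: {unknown[:5]}")
    lines = phenotypes["line"].astype(str).to_numpy()
    envs = phenotypes["environment"].astype(str).to_numpy()
    idx = np.array([pos[l] for l in lines])
    test = set(map(str, test_lines))
    mask = np.array([l in test for l in lines])
    return ModelData(
        y=phenotypes["value"].to_numpy(dtype=float),
        line_index=idx,
        kernels=kernels,
        line_ids=line_ids,
        mask=mask,
        obs_keys=list(zip(lines, envs)),
    )


@dataclass
class FitResult:
    """Posterior summaries of one Gibbs run."""

    mu_mean: float
    mu_samples: np.ndarray
    sigma2_mean: float
    sigma2_samples: np.ndarray
    kernel_names: list[str]
    kernel_variance_means: dict[str, float]
    kernel_variance_samples: dict[str, np.ndarray]
    u_means: dict[str, pd.Series]        # posterior mean effect per line
    predictions: pd.Series               # posterior predictive mean, masked obs
    ess: dict[str, float]                # effective sample size per variance
    n_samples: int
    seed: int


def _ess(x: np.ndarray) -> float:
    """Effective sample size by the initial-positive-sequence estimator."""
    n = len(x)
    if n < 4:
        return float(n)
    x = x - x.mean()
    var = x @ x / n
    if var == 0:
        return float(n)
    acov = np.correlate(x, x, mode="full")[n - 1:] / n
    rho = acov / var
    s = 0.0
    for t in range(1, n):
        if rho[t] <= 0:
            break
        s += rho[t]
    return float(n / (1.0 + 2.0 * s))


def fit_gibbs(
    data: ModelData,
    priors: PriorSpec | None = None,
    n_iter: int = 6000,
    burn_in: int = 1000,
    thin: int = 5,
    seed: int = 0,
    fixed_kernel_variances: Sequence[float] | None = None,
    fixed_residual_variance: float | None = None,
    fix_mu: float | None = None,
) -> FitResult:
    """Run the Gibbs sampler and return posterior summaries.

    ``fixed_*`` arguments disable the corresponding variance updates (used
    for oracle-equivalence checks against the closed-form mixed model);
    ``fix_mu`` pins the intercept.  Fully reproducible given ``seed``.
    """
    priors = priors or PriorSpec()
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    rng = np.random.default_rng(seed)
    n, nk = data.n, len(data.kernels)

    # eigendecompositions (one O(J^3) per kernel)
    Phis, lams = [], []
    for kern in data.kernels:
        w, V = np.linalg.eigh(kern.values)
        if w[0] < _MIN_EIG:
            raise ValueError(
                f"kernel {kern.name!r} has eigenvalue {w[0]:.3e} < {_MIN_EIG}; "
                "apply psd_repair first"
            )
        keep = w > _EIG_TOL
        Phis.append(V[:, keep])
        lams.append(w[keep])

    counts = np.bincount(data.line_index, minlength=len(data.line_ids)).astype(float)
    uniform_reps = np.all(counts == counts[0])
    # line-level cross-products for the non-uniform (multi-environment) case
    Bs = None if uniform_reps else [
        Phi.T @ (counts[:, None] * Phi) for Phi in Phis
    ]

    y_obs = data.y[~data.mask]
    vy = max(float(np.var(y_obs)), 1e-8)  # degenerate constant y: ~zero scales
    S0_k = [
        vy * priors.r2 / nk * (priors.df0 + 2.0) / max(np.mean(np.diag(k.values)), 1e-12)
        for k in data.kernels
    ]
    S0_e = vy * (1.0 - priors.r2) * (priors.df0 + 2.0)

    # state
    mu = float(np.mean(y_obs)) if fix_mu is None else float(fix_mu)
    sigma2 = vy * (1.0 - priors.r2) if fixed_residual_variance is None \
        else float(fixed_residual_variance)
    sigma2_k = [
        vy * priors.r2 / nk / max(np.mean(np.diag(k.values)), 1e-12)
        for k in data.kernels
    ] if fixed_kernel_variances is None else [float(v) for v in fixed_kernel_variances]
    deltas = [np.zeros(len(l)) for l in lams]
    u_lines = np.zeros((nk, len(data.line_ids)))
    y_work = data.y.copy()
    y_work[data.mask] = mu

    n_keep = (n_iter - burn_in + thin - 1) // thin
    mu_s = np.empty(n_keep)
    sig_s = np.empty(n_keep)
    sigk_s = np.empty((nk, n_keep))
    u_sum = np.zeros_like(u_lines)
    pred_sum = np.zeros(int(data.mask.sum()))
    kept = 0

    total_effect = u_lines.sum(axis=0)  # per line
    for it in range(n_iter):
        # intercept
        if fix_mu is None:
            r_mean = y_work - total_effect[data.line_index]
            mu = rng.normal(float(r_mean.mean()), np.sqrt(sigma2 / n))

        # kernel effects in their eigenbases
        for k in range(nk):
            other = total_effect - u_lines[k]
            r = y_work - mu - other[data.line_index]
            t = np.bincount(data.line_index, weights=r,
                            minlength=len(data.line_ids))
            rhs = Phis[k].T @ t / sigma2
            d_prior = 1.0 / (sigma2_k[k] * lams[k])
            if uniform_reps:
                prec = counts[0] / sigma2 + d_prior
                mean = rhs / prec
                deltas[k] = mean + rng.standard_normal(len(mean)) / np.sqrt(prec)
            else:
                P = Bs[k] / sigma2 + np.diag(d_prior)
                L = np.linalg.cholesky(P)
                mean = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
                z = rng.standard_normal(len(mean))
                deltas[k] = mean + np.linalg.solve(L.T, z)
            u_lines[k] = Phis[k] @ deltas[k]
            total_effect = u_lines.sum(axis=0)

            if fixed_kernel_variances is None:
                ss = float(np.sum(deltas[k] ** 2 / lams[k]))
                df = priors.df0 + len(lams[k])
                sigma2_k[k] = (ss + S0_k[k]) / rng.chisquare(df)

        fitted = mu + total_effect[data.line_index]
        if fixed_residual_variance is None:
            resid = y_work - fitted
            sigma2 = (float(resid @ resid) + S0_e) / rng.chisquare(priors.df0 + n)

        # data augmentation for the masked (test) responses
        y_work[data.mask] = fitted[data.mask] + \
            np.sqrt(sigma2) * rng.standard_normal(int(data.mask.sum()))

        if it >= burn_in and (it - burn_in) % thin == 0:
            mu_s[kept] = mu
            sig_s[kept] = sigma2
            sigk_s[:, kept] = sigma2_k
            u_sum += u_lines
            pred_sum += fitted[data.mask]
            kept += 1

    mu_s, sig_s, sigk_s = mu_s[:kept], sig_s[:kept], sigk_s[:, :kept]
    names = [k.name for k in data.kernels]
    masked_keys = [data.obs_keys[i] for i in np.flatnonzero(data.mask)]
    if masked_keys:
        pred_index = pd.MultiIndex.from_tuples(
            masked_keys, names=["line", "environment"]
        )
    else:
        pred_index = pd.MultiIndex.from_arrays(
            [[], []], names=["line", "environment"]
        )
    predictions = pd.Series(
        pred_sum / max(kept, 1), index=pred_index, name="predicted"
    )
    result = FitResult(
        mu_mean=float(mu_s.mean()),
        mu_samples=mu_s,
        sigma2_mean=float(sig_s.mean()),
        sigma2_samples=sig_s,
        kernel_names=names,
        kernel_variance_means={nm: float(sigk_s[i].mean()) for i, nm in enumerate(names)},
        kernel_variance_samples={nm: sigk_s[i].copy() for i, nm in enumerate(names)},
        u_means={
            nm: pd.Series(u_sum[i] / max(kept, 1), index=data.line_ids, name=nm)
            for i, nm in enumerate(names)
        },
        predictions=predictions,
        ess={"sigma2": _ess(sig_s),
             **{nm: _ess(sigk_s[i]) for i, nm in enumerate(names)}},
        n_samples=kept,
        seed=seed,
    )
    log.debug(
        "fit_gibbs: %d kept samples; posterior means mu=%.4g sigma2=%.4g %s",
        kept, result.mu_mean, result.sigma2_mean,
        {nm: round(v, 4) for nm, v in result.kernel_variance_means.items()},
    )
    return result


def predict(
    fit: FitResult,
    data: ModelData,
    keys: Sequence[tuple[str, str]] | None = None,
) -> pd.Series:
    """Posterior predictive means for masked observations.

    With ``keys`` given, returns predictions for exactly those
    (line, environment) pairs; requesting an unmasked observation raises.
    """
    if keys is None:
        return fit.predictions
    available = set(fit.predictions.index)
    bad = [k for k in keys if tuple(map(str, k)) not in available]
    if bad:
        raise KeyError(f"observation(s) not masked in this fit: {bad[:5]}")
    return fit.predictions.loc[[tuple(map(str, k)) for k in keys]]


def blup_oracle(
    K: np.ndarray,
    line_index: np.ndarray,
    y: np.ndarray,
    sigma_g2: float,
    sigma2: float,
) -> np.ndarray:
    """Closed-form mixed-model (kriging) line effects with known variances:
    u_hat = sigma_g2 K Z' (sigma_g2 Z K Z' + sigma2 I)^-1 (y - ybar).

    Independent oracle for the sampler; not used in the fitting path.
    """
    J = K.shape[0]
    Z = np.zeros((len(y), J))
    Z[np.arange(len(y)), line_index] = 1.0
    V = sigma_g2 * Z @ K @ Z.T + sigma2 * np.eye(len(y))
    return sigma_g2 * K @ Z.T @ np.linalg.solve(V, y - y.mean())
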
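"""Synthetic genotype, phenomic and multi-environment phenotype generation.

The generator emulates the structure of a winter-wheat breeding trial:
biallelic SNPs coded 0/1/2 with missing calls, plot-level vegetation
indices correlated with the true genetic value, and BLUE-style phenotypes
replicated over environments with controllable sparsity (in the emulated
trials most lines are observed in only a subset of environments).

Everything is a pure function of ``(scenario, scenario.seed)``; each stage
draws from an independent substream so that, e.g., changing the number of
environments does not perturb the simulated markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_config import log, write_matrix_table, write_phenotypes

# substream ids, combined with the scenario seed
_MARKERS, _EFFECTS, _PHENOMICS, _PHENOTYPES = 11, 13, 17, 19

# plausible field ranges for the three simulated indices (center, half-width)
_INDEX_RANGES = {"NDVI": (0.65, 0.10), "NDRE1": (0.35, 0.08), "Can_Cover": (0.55, 0.12)}


@dataclass(frozen=True)
class SimulationScenario:
    """Variance structure and dimensions of one simulated trial.

    ``h2_g`` is the fraction of single-plot phenotypic variance that is
    genomic, i.e. sigma_g^2 / (sigma_g^2 + residual_sd^2); environment main
    effects come on top.  ``phenomic_loading`` is the target correlation
    between each spectral index and the true genetic value.
    """

    J: int = 300
    p: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_env: int = 2
    h2_g: float = 0.5
    phenomic_loading: float = 0.6
    mu: float = 5.0
    env_effect_sd: float = 0.25
    residual_sd: float = 1.0
    missing_marker_rate: float = 0.0
    sparsity: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 10 or self.p < 2:
            raise ValueError("scenario requires J >= 10 and p >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.h2_g < 1.0:
            raise ValueError("h2_g must lie in [0, 1)")
        if not 0.0 <= self.phenomic_loading <= 1.0:
            raise ValueError("phenomic_loading must lie in [0, 1]")
        if self.env_effect_sd < 0 or self.residual_sd <= 0:
            raise ValueError("env_effect_sd >= 0 and residual_sd > 0 required")
        if not 0.0 <= self.missing_marker_rate < 1.0:
            raise ValueError("missing_marker_rate must lie in [0, 1)")
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in (0, 1]")
        if self.n_env < 1:
            raise ValueError("n_env must be >= 1")

    @property
    def sigma_g2(self) -> float:
        """Genomic variance implied by h2_g and residual_sd."""
        return self.h2_g / (1.0 - self.h2_g) * self.residual_sd**2

    @property
    def line_ids(self) -> list[str]:
        return [f"L{j:04d}" for j in range(self.J)]


def _rng(scenario: SimulationScenario, stream: int) -> np.random.Generator:
    return np.random.default_rng([scenario.seed % 2**31, stream])


def simulate_markers(scenario: SimulationScenario) -> pd.DataFrame:
    """Draw a J x p SNP matrix: per-SNP allele frequency uniform in
    maf_range, genotypes Binomial(2, f); missing cells masked as NaN."""
    rng = _rng(scenario, _MARKERS)
    f = rng.uniform(*scenario.maf_range, size=scenario.p)
    geno = rng.binomial(2, f[None, :], size=(scenario.J, scenario.p)).astype(float)
    if scenario.missing_marker_rate > 0:
        mask = rng.random((scenario.J, scenario.p)) < scenario.missing_marker_rate
        geno[mask] = np.nan
    return pd.DataFrame(
        geno,
        index=pd.Index(scenario.line_ids, name="line"),
        columns=[f"SNP{k:05d}" for k in range(scenario.p)],
    )


def simulate_true_values(
    markers: pd.DataFrame, scenario: SimulationScenario
) -> pd.Series:
    """Infinitesimal genetic values g = X beta with iid normal SNP effects.

    Markers must be complete (impute first).  Columns are standardised
    internally; zero-variance columns carry no information and are dropped
    (logged).  Effects are scaled so Var(g) ~= scenario.sigma_g2.
    """
    if markers.isna().any().any():
        raise ValueError("markers contain missing values; impute before use")
    X = markers.to_numpy(dtype=float)
    sd = X.std(axis=0)  # population SD
    keep = sd > 0
    if not keep.all():
        log.info("simulate_true_values: dropped %d zero-variance SNPs", (~keep).sum())
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    p_eff = X.shape[1]
    rng = _rng(scenario, _EFFECTS)
    beta = rng.normal(0.0, np.sqrt(scenario.sigma_g2 / max(p_eff, 1)), size=p_eff)
    g = X @ beta if p_eff else np.zeros(X.shape[0])
    return pd.Series(g, index=markers.index, name="g")


def simulate_phenomics(g: pd.Series, scenario: SimulationScenario) -> pd.DataFrame:
    """Three plot-level vegetation indices sharing a common genetic signal.

    Each column is phenomic_loading * standardize(g) plus independent noise
    with complementary variance, affinely mapped into a plausible range for
    that index, so corr(column, g) ~= phenomic_loading.
    """
    rng = _rng(scenario, _PHENOMICS)
    lam = scenario.phenomic_loading
    gv = g.to_numpy(dtype=float)
    sd = gv.std()
    z = (gv - gv.mean()) / sd if sd > 0 else np.zeros_like(gv)
    cols = {}
    for name, (center, half_width) in _INDEX_RANGES.items():
        noise = rng.normal(size=len(gv))
        signal = lam * z + np.sqrt(1.0 - lam**2) * noise
        cols[name] = center + half_width / 3.0 * signal  # +-3 SD spans the range
    return pd.DataFrame(cols, index=g.index)


def simulate_phenotypes(g: pd.Series, scenario: SimulationScenario) -> pd.DataFrame:
    """Forward-simulate BLUEs: Y_ij = mu + g_j + e_i + eps_ij.

    Environment effects are additive shifts (environments act as
    replications, no GxE); a fraction ``sparsity`` of the J x n_env cells
    is observed, drawn uniformly without replacement.  Lines left with zero
    observations trigger a warning but stay in the kernels.
    """
    rng = _rng(scenario, _PHENOTYPES)
    J, E = len(g), scenario.n_env
    env_ids = [f"E{i:02d}" for i in range(E)]
    env_eff = rng.normal(0.0, scenario.env_effect_sd, size=E)
    n_cells = J * E
    n_obs = max(1, int(round(scenario.sparsity * n_cells)))
    cells = rng.choice(n_cells, size=n_obs, replace=False)
    cells.sort()
    line_idx, env_idx = np.divmod(cells, E)
    eps = rng.normal(0.0, scenario.residual_sd, size=n_obs)
    y = scenario.mu + g.to_numpy()[line_idx] + env_eff[env_idx] + eps
    df = pd.DataFrame(
        {
            "line": g.index.to_numpy()[line_idx],
            "environment": np.array(env_ids)[env_idx],
            "trait": "GY",
            "value": y,
        }
    )
    n_unobserved = J - df["line"].nunique()
    if n_unobserved:
        warnings.warn(
            f"{n_unobserved} line(s) have no phenotype observations at "
            f"sparsity={scenario.sparsity}; they remain in the kernels",
            stacklevel=2,
        )
    return df


def simulate_dataset(scenario: SimulationScenario) -> dict:
    """Run the full generator; returns markers, indices, phenotypes and truth."""
    markers = simulate_markers(scenario)
    complete = markers.fillna(markers.mean()) if markers.isna().any().any() else markers
    g = simulate_true_values(complete, scenario)
    indices = simulate_phenomics(g, scenario)
    phenotypes = simulate_phenotypes(g, scenario)
    return {
        "markers": markers,
        "indices": indices,
        "phenotypes": phenotypes,
        "true_values": g,
    }


def write_dataset(data: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_table(data["markers"], out / "markers.csv")
    write_matrix_table(data["indices"], out / "spectral_indices.csv")
    write_phenotypes(data["phenotypes"], out / "phenotypes.csv")
    data["true_values"].to_frame().to_csv(out / "true_values.csv")
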
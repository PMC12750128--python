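"""Tabular I/O, run configuration and logging.

All on-disk tables are comma-separated UTF-8 with "." decimals; missing
values are written as empty cells and read as ``NA``/empty.  Matrix tables
(markers, spectral bands/indices, kernels) carry line IDs in the first
column; phenotype tables are long format with one BLUE per
(line, environment, trait) record.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("hybridgp")

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5", "M6", "M7", "M8")
MISSING_TOKENS = ("", "NA", "NaN", "nan")

PHENOTYPE_COLUMNS = ("line", "environment", "trait", "value")


class FormatError(ValueError):
    """A file does not conform to the expected tabular schema."""


@dataclass
class SamplerSettings:
    """Gibbs sampler run lengths and priors (defaults follow the
    conventions of standard Bayesian genomic-regression software)."""

    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    df0: float = 5.0
    r2: float = 0.5

    def validate(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.df0 <= 0:
            raise ValueError("prior degrees of freedom df0 must be > 0")
        if not 0.0 < self.r2 < 1.0:
            raise ValueError("prior R2 must lie in (0, 1)")


@dataclass
class QCSettings:
    """SNP quality-control thresholds (study defaults suit inbred panels;
    outbred or simulated Hardy-Weinberg genotypes need a looser max_het)."""

    max_missing: float = 0.5
    min_maf: float = 0.05
    max_het: float = 0.05
    max_homo: float = 0.80


@dataclass
class KernelSettings:
    """Kernel construction switches."""

    psd_repair: bool = True          # repair hybrid kernels to PSD
    bandwidth: str = "median"        # Gaussian bandwidth rule
    diagonal_split: str = "half"     # hybrid UT/LT diagonal convention


@dataclass
class RunConfig:
    """Resolved configuration for one run; written alongside every output."""

    mode: str = "single_env"
    models: tuple[str, ...] = MODEL_IDS
    n_partitions: int = 5
    test_fraction: float = 0.2
    seed: int = 0
    trait: str = "GY"
    larger_is_better: bool = True
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    kernels: KernelSettings = field(default_factory=KernelSettings)
    qc: QCSettings = field(default_factory=QCSettings)

    def __post_init__(self) -> None:
        self.models = tuple(self.models)
        if self.mode not in ("single_env", "multi_env"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie strictly between 0 and 1")
        if self.n_partitions < 1:
            raise ValueError("n_partitions must be >= 1")
        unknown = [m for m in self.models if m not in MODEL_IDS]
        if unknown:
            raise ValueError(
                f"unknown model ids {unknown}; valid ids are {list(MODEL_IDS)}"
            )
        if not self.models:
            raise ValueError("at least one model must be requested")
        self.sampler.validate()

    # -- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sampler" in d and isinstance(d["sampler"], dict):
            d["sampler"] = SamplerSettings(**d["sampler"])
        if "kernels" in d and isinstance(d["kernels"], dict):
            d["kernels"] = KernelSettings(**d["kernels"])
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCSettings(**d["qc"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a long-format BLUE table with columns line, environment, trait, value.

    Raises
    ------
    FormatError
        If a required column is missing, a value fails to parse (the error
        names the offending data row), or a (line, environment, trait) key
        is duplicated.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(
            f"{path}: missing required column(s) {missing_cols}; "
            f"expected {list(PHENOTYPE_COLUMNS)}"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & ~df["value"].isin(MISSING_TOKENS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1  # 1-based data row
        raise FormatError(
            f"{path}: non-numeric value {df['value'][bad.idxmax()]!r} in row {row}"
        )
    out = df[["line", "environment", "trait"]].copy()
    out["value"] = values
    out = out[~out["value"].isna()]  # absence of a record encodes missing
    dup = out.duplicated(subset=["line", "environment", "trait"])
    if dup.any():
        key = out.loc[dup.idxmax(), ["line", "environment", "trait"]].tolist()
        raise FormatError(f"{path}: duplicated (line, environment, trait) key {key}")
    if not np.isfinite(out["value"]).all():
        raise FormatError(f"{path}: non-finite phenotype value")
    return out.reset_index(drop=True)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory phenotype table against the same invariants."""
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"phenotype table missing column(s) {missing_cols}")
    if df.duplicated(subset=["line", "environment", "trait"]).any():
        raise FormatError("duplicated (line, environment, trait) key")
    if not np.isfinite(df["value"]).all():
        raise FormatError("non-finite phenotype value")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Labeled matrix tables (markers / spectral / kernel)
# ---------------------------------------------------------------------------

def read_matrix_table(path: str | Path, kind: str = "markers") -> pd.DataFrame:
    """Read a labeled numeric matrix (first column = line IDs).

    ``kind`` is one of ``markers`` (missing entries allowed), ``spectral``
    (complete), or ``kernel`` (complete, square, symmetric within 1e-8 with
    matching row/column labels).
    """
    if kind not in ("markers", "spectral", "kernel"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = pd.read_csv(
        path, index_col=0, na_values=list(MISSING_TOKENS), keep_default_na=False
    )
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from exc
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicated line IDs")
    if kind in ("spectral", "kernel") and df.isna().any().any():
        n = int(df.isna().sum().sum())
        raise FormatError(f"{path}: {n} missing entries not allowed for kind={kind}")
    if kind == "kernel":
        if df.shape[0] != df.shape[1]:
            raise FormatError(
                f"{path}: kernel must be square, got shape {df.shape}"
            )
        if list(df.index) != [str(c) for c in df.columns]:
            raise FormatError(f"{path}: kernel row/column labels differ")
        a = df.to_numpy()
        if np.abs(a - a.T).max() > 1e-8:
            raise FormatError(f"{path}: kernel asymmetric beyond 1e-8")
    return df


def write_matrix_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=True, na_rep="NA")


def setup_logging(out_dir: str | Path | None = None, level: int = logging.INFO) -> None:
    """Attach a stream handler (and a run log file if ``out_dir`` given)."""
    log.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(h)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(Path(out_dir) / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
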
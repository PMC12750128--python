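"""Marker quality control, imputation and standardisation.

Markers are pandas DataFrames of lines x SNPs with entries in {0, 1, 2}
(NaN for missing calls).  The QC rules exclude a SNP when its missing
fraction, minor allele frequency, heterozygote fraction or homozygote
fraction falls outside the configured thresholds; note that the default
homozygosity ceiling of 0.80 removes fully homozygous SNPs, so inbred
panels typically need a higher ceiling.  All thresholds are explicit
arguments for that reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import log


@dataclass
class FilterReport:
    """Counts of SNPs removed per QC rule (a SNP may fail several rules)."""

    n_input: int
    n_retained: int
    failed_missing: int
    failed_maf: int
    failed_het: int
    failed_homo: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["missing", "maf", "het", "homo"],
                "n_removed": [
                    self.failed_missing,
                    self.failed_maf,
                    self.failed_het,
                    self.failed_homo,
                ],
            }
        )


@dataclass
class StandardizedMarkers:
    """Column-standardised marker matrix plus the centering metadata."""

    X: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    @property
    def line_ids(self) -> list[str]:
        return list(self.X.index)


def _validate_calls(m: pd.DataFrame) -> np.ndarray:
    a = m.to_numpy(dtype=float)
    obs = ~np.isnan(a)
    if not np.isin(a[obs], (0.0, 1.0, 2.0)).all():
        raise ValueError("marker entries must be 0, 1, 2 or missing")
    if m.index.has_duplicates or m.columns.has_duplicates:
        raise ValueError("line and SNP labels must be unique")
    return a


def filter_markers(
    m: pd.DataFrame,
    max_missing: float = 0.5,
    min_maf: float = 0.05,
    max_het: float = 0.05,
    max_homo: float = 0.80,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the four SNP QC rules; returns (filtered matrix, report).

    A SNP is retained iff missing fraction <= max_missing AND allele-based
    MAF >= min_maf AND heterozygote fraction <= max_het AND homozygote
    fraction <= max_homo.  Genotype-class fractions use non-missing calls
    only; the missing fraction uses all lines.  SNPs with zero non-missing
    calls fall under the missing rule.  Column order is preserved.
    """
    for name, t in (("max_missing", max_missing), ("min_maf", min_maf),
                    ("max_het", max_het), ("max_homo", max_homo)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    a = _validate_calls(m)
    J = a.shape[0]
    obs = ~np.isnan(a)
    n_called = obs.sum(axis=0)
    missing_frac = 1.0 - n_called / J

    with np.errstate(invalid="ignore"):
        n_het = np.nansum(a == 1.0, axis=0)
        n_alt = np.nansum(a == 2.0, axis=0)
    safe = np.maximum(n_called, 1)
    alt_freq = (2.0 * n_alt + n_het) / (2.0 * safe)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    het_frac = n_het / safe
    homo_frac = (n_called - n_het) / safe

    fail_missing = (missing_frac > max_missing) | (n_called == 0)
    # rules below are only meaningful where at least one call exists
    called = n_called > 0
    fail_maf = called & (maf < min_maf)
    fail_het = called & (het_frac > max_het)
    fail_homo = called & (homo_frac > max_homo)

    keep = ~(fail_missing | fail_maf | fail_het | fail_homo)
    report = FilterReport(
        n_input=a.shape[1],
        n_retained=int(keep.sum()),
        failed_missing=int(fail_missing.sum()),
        failed_maf=int(fail_maf.sum()),
        failed_het=int(fail_het.sum()),
        failed_homo=int(fail_homo.sum()),
    )
    log.info(
        "filter_markers: kept %d/%d SNPs (missing %d, maf %d, het %d, homo %d)",
        report.n_retained, report.n_input, report.failed_missing,
        report.failed_maf, report.failed_het, report.failed_homo,
    )
    return m.loc[:, keep], report


def impute_markers(
    m: pd.DataFrame,
    method: str = "column_mean",
    max_iter: int = 50,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Fill missing marker calls; returns a real-valued complete matrix.

    ``column_mean`` fills each missing cell with the column mean of the
    non-missing calls.  ``em`` iterates a deterministic low-rank EM:
    mean-fill, truncated eigenreconstruction of the column-centered matrix
    (rank chosen to capture >= 90% of variance, capped at min(J, p) - 1),
    overwrite only the originally-missing cells, repeat until the largest
    absolute change drops below ``tol`` or ``max_iter`` sweeps.  Imputed
    values are clipped to [0, 2]; observed cells are never altered.
    """
    if method not in ("column_mean", "em"):
        raise ValueError(f"unknown imputation method {method!r}")
    a = m.to_numpy(dtype=float).copy()
    miss = np.isnan(a)
    if not miss.any():
        return m.copy()
    n_called = (~miss).sum(axis=0)
    if (n_called == 0).any():
        snp = m.columns[int(np.flatnonzero(n_called == 0)[0])]
        raise ValueError(f"SNP {snp!r} has no non-missing calls; filter first")

    col_means = np.nanmean(a, axis=0)
    filled = np.where(miss, col_means[None, :], a)
    if method == "column_mean":
        return pd.DataFrame(filled, index=m.index, columns=m.columns)

    J, p = a.shape
    max_rank = max(1, min(J, p) - 1)
    for _ in range(max_iter):
        mu = filled.mean(axis=0)
        C = filled - mu[None, :]
        # SVD of the centered matrix == eigendecomposition of its Gram matrix
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        var = s**2
        total = var.sum()
        if total <= 0:
            break
        cum = np.cumsum(var) / total
        rank = min(int(np.searchsorted(cum, 0.90) + 1), max_rank)
        recon = (U[:, :rank] * s[:rank]) @ Vt[:rank, :] + mu[None, :]
        new_vals = np.clip(recon[miss], 0.0, 2.0)
        delta = np.abs(new_vals - filled[miss]).max()
        filled[miss] = new_vals
        if delta < tol:
            break
    return pd.DataFrame(filled, index=m.index, columns=m.columns)


def standardize_markers(m: pd.DataFrame) -> StandardizedMarkers:
    """Center and scale each SNP column to mean 0, SD 1 (population SD).

    Population SD (divide by J) makes the mean diagonal of G = XX'/p
    exactly 1.  Zero-variance columns are an error: filter them first.
    """
    a = m.to_numpy(dtype=float)
    if np.isnan(a).any():
        raise ValueError("markers contain missing values; impute first")
    means = a.mean(axis=0)
    sds = a.std(axis=0)  # population convention
    if (sds == 0).any():
        snp = m.columns[int(np.flatnonzero(sds == 0)[0])]
        raise ValueError(
            f"zero-variance column {snp!r}; remove constant SNPs before standardising"
        )
    X = (a - means[None, :]) / sds[None, :]
    return StandardizedMarkers(
        X=pd.DataFrame(X, index=m.index, columns=m.columns),
        means=pd.Series(means, index=m.columns, name="mean"),
        sds=pd.Series(sds, index=m.columns, name="sd"),
    )
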
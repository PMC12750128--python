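"""Kernel construction: linear, Gaussian, and hybrid triangular-product.

A ``Kernel`` is a named symmetric J x J similarity matrix over line IDs,
used as the covariance of a per-line random effect.  The hybrid kernels
are built from the ordinary (generally asymmetric) matrix product M of two
source kernels: K_upper symmetrises the upper triangle of M, K_lower the
lower triangle, each taking half of M's diagonal so that

    K_upper + K_lower = M + M'     (exactly)

holds and both halves have consistent diagonals.  These two kernels carry
the asymmetric genomic-by-phenomic interaction patterns that additive
kernel sums discard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_config import log

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5", "M6", "M7", "M8")


@dataclass
class Kernel:
    """Named symmetric similarity matrix with construction provenance."""

    values: np.ndarray
    line_ids: list[str]
    name: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = [str(x) for x in self.line_ids]
        J = len(self.line_ids)
        if self.values.shape != (J, J):
            raise ValueError(
                f"kernel {self.name!r}: shape {self.values.shape} != ({J}, {J})"
            )
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-10:
            raise ValueError(f"kernel {self.name!r} is not symmetric within 1e-10")

    @property
    def J(self) -> int:
        return len(self.line_ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def subset(self, ids: Sequence[str]) -> "Kernel":
        """Restrict the kernel to ``ids`` (order follows ``ids``)."""
        pos = {lid: i for i, lid in enumerate(self.line_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"kernel {self.name!r} lacks line(s) {missing[:5]}")
        idx = np.array([pos[i] for i in ids])
        return Kernel(
            self.values[np.ix_(idx, idx)], list(ids), self.name,
            dict(self.provenance, subset=len(idx)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str, **prov) -> "Kernel":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)), name, prov)


def linear_kernel(X: pd.DataFrame | np.ndarray, name: str = "G") -> Kernel:
    """VanRaden-style linear kernel XX'/p (p = number of columns of X).

    With column-standardised X (population SD) the mean diagonal is exactly
    1.  For the spectral matrix U (p = 3) this yields H = UU'/3.
    """
    if isinstance(X, pd.DataFrame):
        ids, a = list(X.index.astype(str)), X.to_numpy(dtype=float)
    else:
        a = np.asarray(X, dtype=float)
        ids = [str(i) for i in range(a.shape[0])]
    if a.ndim != 2 or a.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with at least one column")
    if np.isnan(a).any():
        raise ValueError("X contains missing values")
    K = a @ a.T / a.shape[1]
    K = (K + K.T) / 2.0  # exact symmetry against rounding
    return Kernel(K, ids, name, {"rule": "linear", "p": a.shape[1]})


def median_bandwidth(X: pd.DataFrame | np.ndarray) -> float:
    """Median of the J(J-1)/2 off-diagonal pairwise squared Euclidean
    distances (the median heuristic); self-distances are excluded."""
    a = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if a.ndim == 1:
        a = a[:, None]
    if a.shape[0] < 2:
        raise ValueError("need at least 2 rows for a pairwise bandwidth")
    d2 = pdist(a, metric="sqeuclidean")
    sigma2 = float(np.median(d2))
    if sigma2 <= 0:
        raise ValueError(
            "median pairwise squared distance is 0 (duplicate rows dominate); "
            "jitter the inputs or use the linear kernel"
        )
    return sigma2


def gaussian_kernel(
    X: pd.DataFrame | np.ndarray,
    sigma2: float | str = "median",
    name: str = "K",
) -> Kernel:
    """Gaussian (RBF) kernel K_jk = exp(-||x_j - x_k||^2 / sigma2).

    ``sigma2="median"`` applies the median heuristic.  The diagonal is
    exactly 1 and all entries lie in (0, 1].
    """
    if isinstance(X, pd.DataFrame):
        ids, a = list(X.index.astype(str)), X.to_numpy(dtype=float)
    else:
        a = np.asarray(X, dtype=float)
        if a.ndim == 1:
            a = a[:, None]
        ids = [str(i) for i in range(a.shape[0])]
    if a.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if sigma2 == "median":
        sigma2 = median_bandwidth(a)
    sigma2 = float(sigma2)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    d2 = squareform(pdist(a, metric="sqeuclidean"))
    K = np.exp(-d2 / sigma2)
    np.fill_diagonal(K, 1.0)
    K = (K + K.T) / 2.0
    return Kernel(K, ids, name, {"rule": "gaussian", "sigma2": sigma2})


def hybrid_kernels(
    KA: Kernel, KB: Kernel, diagonal_split: str = "half",
    names: tuple[str, str] = ("K_CC", "K_PP"),
) -> tuple[Kernel, Kernel]:
    """Triangular-product hybrid kernels from the matrix product M = KA @ KB.

    ``half`` (default) assigns half of diag(M) to each triangle, so
    K_upper + K_lower = M + M' holds exactly and both kernels share the
    diagonal diag(M).  ``upper`` assigns the whole diagonal to the upper
    part only (K_upper then carries 2*diag(M) on its diagonal, K_lower a
    zero diagonal; their sum still equals M + M').
    """
    if KA.line_ids != KB.line_ids:
        raise ValueError(
            f"kernels {KA.name!r} and {KB.name!r} have mismatched line IDs"
        )
    if diagonal_split not in ("half", "upper"):
        raise ValueError(f"unknown diagonal_split {diagonal_split!r}")
    M = KA.values @ KB.values
    d = np.diag(M)
    w_upper = 0.5 if diagonal_split == "half" else 1.0
    UT = np.triu(M, k=1) + np.diag(w_upper * d)
    LT = np.tril(M, k=-1) + np.diag((1.0 - w_upper) * d)
    K_upper = UT + UT.T
    K_lower = LT + LT.T
    prov = {
        "rule": "triangular_product",
        "sources": (KA.name, KB.name),
        "diagonal_split": diagonal_split,
    }
    return (
        Kernel(K_upper, KA.line_ids, names[0], dict(prov, part="upper")),
        Kernel(K_lower, KA.line_ids, names[1], dict(prov, part="lower")),
    )


def psd_repair(K: Kernel, floor: float = 0.0) -> Kernel:
    """Clip eigenvalues below ``floor`` up to ``floor`` and reconstruct.

    Returns the input unchanged (same object) when already at or above the
    floor.  Provenance records the minimum eigenvalue before and after.
    """
    w, V = np.linalg.eigh(K.values)
    if w[0] >= floor:
        return K
    w_clipped = np.maximum(w, floor)
    repaired = (V * w_clipped) @ V.T
    repaired = (repaired + repaired.T) / 2.0
    log.info(
        "psd_repair(%s): min eigenvalue %.3e -> %.3e", K.name, w[0], w_clipped[0]
    )
    return Kernel(
        repaired, K.line_ids, K.name,
        dict(K.provenance, psd_repaired=True,
             min_eig_before=float(w[0]), min_eig_after=float(w_clipped[0])),
    )


def build_model_kernels(
    model_id: str,
    G: Kernel,
    H: Kernel,
    K: Kernel,
    K_H: Kernel,
    repair: bool = True,
    diagonal_split: str = "half",
) -> list[Kernel]:
    """Assemble the ordered kernel list for one of the eight models.

    M1=[G] linear genomic; M2=[H] linear phenomic; M3=[K] Gaussian genomic;
    M4=[H, K] additive; M5=[K_H, K] additive Gaussian; M6 adds the hybrid
    pair from H x K; M7 adds the hybrid pair from K_H x K (keeping H as the
    first term); M8 = M7 with the linear phenomic first term replaced by
    the Gaussian phenomic kernel K_H.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}; valid ids: {list(MODEL_IDS)}")
    if model_id == "M1":
        return [G]
    if model_id == "M2":
        return [H]
    if model_id == "M3":
        return [K]
    if model_id == "M4":
        return [H, K]
    if model_id == "M5":
        return [K_H, K]

    if model_id == "M6":
        cc, pp = hybrid_kernels(H, K, diagonal_split, names=("K_CC", "K_PP"))
        head = [H, K]
    else:  # M7, M8: hybrids from the Gaussian phenomic x Gaussian genomic product
        cc, pp = hybrid_kernels(K_H, K, diagonal_split, names=("K_CCH", "K_PPH"))
        head = [H, K] if model_id == "M7" else [K_H, K]
    if repair:
        cc, pp = psd_repair(cc), psd_repair(pp)
    return head + [cc, pp]
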
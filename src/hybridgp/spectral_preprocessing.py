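"""Radiometric calibration and vegetation-index computation.

Inputs are plot-level band reflectances (one row per line).  The three
indices used downstream are NDVI = (R800 - R680)/(R800 + R680),
NDRE1 = (R800 - R700)/(R800 + R700) and Can_Cover, the mean GNDVI over a
plot's N pixels/subplots (N = 1 when only plot-level values exist, the
contract here).  GNDVI = (NIR - Green)/(NIR + Green), its standard
literature definition.  The standardised J x 3 index matrix U feeds the
phenomic kernels H = UU'/3 and K_H.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_config import log

#: Visible-band regression coefficients for estimating NIR reflectance
#: when no NIR calibration panel is available (2019-season convention).
NIR_BLUE_COEF = 2.921
NIR_RED_COEF = 0.754

#: Optional multiplicative normalisation for the estimated NIR band.
NIR_CORRECTION_FACTOR = 3.07

INDEX_NAMES = ("NDVI", "NDRE1", "Can_Cover")


def calibrate_reflectance(dn, slope: float, intercept: float):
    """Linear radiometric calibration SR = DN * slope + intercept.

    The intercept carries its own sign (it comes from a fitted regression
    of panel reflectance on digital number).  Values outside [0, 1.5] are
    physically implausible and logged as warnings, not rejected.
    """
    if not np.isfinite(slope) or slope == 0:
        raise ValueError("slope must be finite and nonzero")
    sr = np.asarray(dn, dtype=float) * slope + intercept
    n_bad = int(np.sum((sr < 0) | (sr > 1.5)))
    if n_bad:
        log.warning("calibrate_reflectance: %d value(s) outside [0, 1.5]", n_bad)
    return sr if sr.ndim else float(sr)


def nir_from_visible(blue, red, correction_factor: float | None = None):
    """Estimate NIR reflectance from blue and red bands.

    NIR = 2.921*Blue - 0.754*Red; ``correction_factor`` (e.g. 3.07), when
    given, multiplies the estimate as a post-hoc normalisation.
    """
    nir = NIR_BLUE_COEF * np.asarray(blue, dtype=float) - NIR_RED_COEF * np.asarray(
        red, dtype=float
    )
    if correction_factor is not None:
        nir = nir * correction_factor
    return nir if np.ndim(nir) else float(nir)


def _norm_diff(a: np.ndarray, b: np.ndarray, name: str, index) -> np.ndarray:
    denom = a + b
    if np.any(denom == 0):
        line = index[int(np.flatnonzero(denom == 0)[0])]
        raise ValueError(f"{name} undefined for line {line!r}: zero band sum")
    return (a - b) / denom


def compute_indices(bands: pd.DataFrame) -> pd.DataFrame:
    """Compute NDVI, NDRE1 and Can_Cover per line from a band table.

    Requires columns ``red`` (R680), ``red_edge`` (R700), ``nir`` (R800)
    and ``green``.  Columns named ``gndvi_<k>`` are treated as per-subplot
    GNDVI values and averaged into Can_Cover; otherwise Can_Cover is the
    plot-level GNDVI (N = 1).
    """
    required = ("red", "red_edge", "nir", "green")
    missing = [c for c in required if c not in bands.columns]
    if missing:
        raise ValueError(f"band table missing column(s) {missing}")
    r680 = bands["red"].to_numpy(dtype=float)
    r700 = bands["red_edge"].to_numpy(dtype=float)
    r800 = bands["nir"].to_numpy(dtype=float)
    green = bands["green"].to_numpy(dtype=float)

    ndvi = _norm_diff(r800, r680, "NDVI", bands.index)
    ndre1 = _norm_diff(r800, r700, "NDRE1", bands.index)

    gndvi_cols = [c for c in bands.columns if str(c).startswith("gndvi_")]
    if gndvi_cols:
        can_cover = bands[gndvi_cols].to_numpy(dtype=float).mean(axis=1)
    else:
        can_cover = _norm_diff(r800, green, "GNDVI", bands.index)
    return pd.DataFrame(
        {"NDVI": ndvi, "NDRE1": ndre1, "Can_Cover": can_cover}, index=bands.index
    )


def build_spectral_matrix(indices: pd.DataFrame) -> pd.DataFrame:
    """Standardise index columns to mean 0, SD 1 (population SD).

    Lines with any missing index are dropped (logged).  The result is the
    U matrix of standardised multispectral information.
    """
    df = indices.copy()
    incomplete = df.isna().any(axis=1)
    if incomplete.any():
        log.info("build_spectral_matrix: dropped %d incomplete line(s)",
                 int(incomplete.sum()))
        df = df[~incomplete]
    if len(df) < 2:
        raise ValueError("need at least 2 lines to standardise index columns")
    a = df.to_numpy(dtype=float)
    sds = a.std(axis=0)
    if (sds == 0).any():
        col = df.columns[int(np.flatnonzero(sds == 0)[0])]
        raise ValueError(f"index column {col!r} has zero variance")
    U = (a - a.mean(axis=0)[None, :]) / sds[None, :]
    return pd.DataFrame(U, index=df.index, columns=df.columns)
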
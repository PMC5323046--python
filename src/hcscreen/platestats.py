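"""Plate-level normalization and screen-quality statistics.

Normalizes well summaries to the plate's non-targeting control (sicon),
computes z'-factors, z-score and B-score normalizations, and replicate
correlation.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import NormalizationError

log = logging.getLogger(__name__)

PARAMETERS = ("spots_per_cell", "iss_per_cell")

NORMALIZED_COLUMNS = ["gene", "sirna", "marker", "treatment", "plate",
                      "parameter", "value", "control_mean", "control_sd",
                      "n_wells", "flagged"]


def normalize_to_control(wells: pd.DataFrame, sd_mode: str = "pooled",
                         parameters=PARAMETERS,
                         expected_replicates: int = 4) -> pd.DataFrame:
    """Average replicate wells and express them as fold of the plate's sicon.

    Replicate wells of each (gene, siRNA, marker, treatment) condition are
    averaged first, then divided by the sicon mean of the same plate and
    treatment.  The attached ``control_sd`` is the SD of per-well normalized
    sicon values, pooled per marker (``sd_mode='pooled'``) or computed per
    plate (``'per_plate'``); it is the dispersion the SD hit criterion
    uses.  Conditions with fewer than ``expected_replicates`` wells are
    flagged, not dropped.
    """
    if sd_mode not in ("pooled", "per_plate"):
        raise ValueError("sd_mode must be 'pooled' or 'per_plate'")

    sicon = wells[wells["control_class"] == "sicon"]
    counts = sicon.groupby("plate").size()
    for plate in wells["plate"].unique():
        if counts.get(plate, 0) < 2:
            raise NormalizationError(f"plate {plate!r} has <2 sicon wells")

    # per-plate sicon means, then per-well normalized sicon values for the SD
    sicon_means = sicon.groupby(["plate", "treatment"])[list(parameters)].mean()
    for (plate, _), row in sicon_means.iterrows():
        for p in parameters:
            if not np.isfinite(row[p]) or row[p] <= 0:
                raise NormalizationError(
                    f"plate {plate!r} sicon mean for {p} is missing or <= 0")

    sic_norm = sicon.merge(
        sicon_means, on=["plate", "treatment"], suffixes=("", "_ctl"))
    control_sd = {}
    for p in parameters:
        normed = sic_norm[p] / sic_norm[f"{p}_ctl"]
        if sd_mode == "pooled":
            sd = sic_norm.assign(v=normed).groupby("marker")["v"].std(ddof=1)
            control_sd[p] = sd.to_dict()
        else:
            sd = sic_norm.assign(v=normed).groupby(["marker", "plate"])["v"].std(ddof=1)
            control_sd[p] = sd.to_dict()

    rows = []
    grouped = wells.groupby(
        ["gene", "sirna", "marker", "treatment", "plate", "control_class"],
        sort=False)
    for (gene, sirna, marker, treatment, plate, cls), grp in grouped:
        ctl = sicon_means.loc[(plate, treatment)]
        for p in parameters:
            vals = grp[p].dropna()
            n = len(vals)
            if n == 0:
                continue
            value = float(vals.mean()) / float(ctl[p])
            key = marker if sd_mode == "pooled" else (marker, plate)
            sd = float(control_sd[p].get(key, np.nan))
            flagged = (cls == "test") and (n < expected_replicates)
            rows.append((gene, sirna, marker, treatment, plate, p, value,
                         float(ctl[p]), sd, n, flagged))
    return pd.DataFrame(rows, columns=NORMALIZED_COLUMNS)


def zprime(pos, neg) -> float:
    """Assay window statistic 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg|.

    Values above 0.5 indicate a screenable assay window; returns NaN with a
    warning when the group means coincide.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 values per control group")
    mu_p, mu_n = pos.mean(), neg.mean()
    if np.isclose(mu_p, mu_n):
        warnings.warn("z'-factor undefined: control means coincide")
        return float("nan")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1))
                 / abs(mu_p - mu_n))


def zscore_plate(values, robust: bool = False) -> np.ndarray:
    """Per-plate (x - center)/scale; robust mode uses median and scaled MAD."""
    x = np.asarray(values, dtype=float)
    if robust:
        center = np.nanmedian(x)
        scale = 1.4826 * np.nanmedian(np.abs(x - center))
        if scale == 0:
            log.warning("zero MAD on plate; returning zero scores")
            return np.zeros_like(x)
    else:
        center = np.nanmean(x)
        scale = np.nanstd(x, ddof=1)
        if scale == 0:
            raise NormalizationError("zero scale: cannot z-score a flat plate")
    return (x - center) / scale


def median_polish(matrix: np.ndarray, max_iter: int = 10, tol: float = 1e-4):
    """Tukey two-way median polish.

    Returns ``(residuals, row_effects, col_effects, overall, converged)``.
    NaNs are tolerated and ignored in the medians.
    """
    z = np.array(matrix, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("need a matrix of at least 2x2")
    if np.isnan(z).mean() >= 0.5:
        raise ValueError("more than half of the plate is missing")
    nr, nc = z.shape
    row_eff = np.zeros(nr)
    col_eff = np.zeros(nc)
    overall = 0.0
    converged = False
    for _ in range(max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rmed = np.nanmedian(z, axis=1)
        rmed = np.where(np.isnan(rmed), 0.0, rmed)
        z -= rmed[:, None]
        row_eff += rmed
        delta = np.nanmedian(row_eff)
        row_eff -= delta
        overall += delta

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cmed = np.nanmedian(z, axis=0)
        cmed = np.where(np.isnan(cmed), 0.0, cmed)
        z -= cmed[None, :]
        col_eff += cmed
        delta = np.nanmedian(col_eff)
        col_eff -= delta
        overall += delta

        if max(np.abs(rmed).max(), np.abs(cmed).max()) < tol:
            converged = True
            break
    return z, row_eff, col_eff, overall, converged


def bscore_plate(matrix, max_iter: int = 10, tol: float = 1e-4):
    """B-score residual matrix: median-polish residuals over their scaled MAD.

    Returns ``(bscores, converged)``.  Non-convergence returns the last
    iterate, flagged via ``converged=False``.  A plate with zero residual
    MAD (e.g. a purely additive row+column surface) returns the raw
    residuals, which are then ~0 anyway.
    """
    resid, _, _, _, converged = median_polish(matrix, max_iter, tol)
    mad = np.nanmedian(np.abs(resid - np.nanmedian(resid)))
    scale = 1.4826 * mad
    if scale == 0:
        return resid, converged
    return resid / scale, converged


def replicate_correlation(rep1, rep2) -> float:
    """Squared Pearson correlation over genes shared by two replicates.

    Accepts mappings or Series of gene -> value; pairs with missing values
    are dropped; returns NaN when either replicate has zero variance.
    """
    s1, s2 = pd.Series(rep1, dtype=float), pd.Series(rep2, dtype=float)
    joined = pd.concat([s1, s2], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 shared genes")
    a, b = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
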
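"""Phenotype preparation: validity filtering, covariate residualization,
outlier removal, and tertile binarization into poor/good performers.

The phenotype table is a pandas DataFrame with columns ``individual_id,
raw_score, age, sex, valid_code, medical_rating``; the preparation steps add
``residual_score`` and ``label`` (``poor``/``good``/``unassigned``). Steps run
in the fixed order: validity filter -> residualize -> outlier removal ->
binarize.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["individual_id", "raw_score", "age", "sex", "valid_code",
                    "medical_rating"]
VALID_CODES = ("V", "V2")
LABELS = ("poor", "good", "unassigned")


def _check_schema(pheno: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")


def _sex_indicator(sex: pd.Series) -> np.ndarray:
    """0/1 indicator for a two-level sex covariate (numeric passthrough)."""
    if pd.api.types.is_numeric_dtype(sex):
        return sex.to_numpy(dtype=float)
    codes, _ = pd.factorize(sex, sort=True)
    return codes.astype(float)


def filter_invalid(pheno: pd.DataFrame) -> pd.DataFrame:
    """Drop severe medical exclusions and blank invalid test scores.

    Individuals with ``medical_rating == 4`` are removed; rows whose
    ``valid_code`` is not V or V2 keep their covariates but have the raw score
    set to missing.
    """
    _check_schema(pheno)
    out = pheno.copy()
    n0 = len(out)
    out = out[out["medical_rating"] != 4].reset_index(drop=True)
    n_medical = n0 - len(out)
    invalid = ~out["valid_code"].isin(VALID_CODES)
    out.loc[invalid, "raw_score"] = np.nan
    logger.info(
        "filter_invalid: dropped %d rows with medical_rating=4; "
        "set %d scores to missing for invalid codes",
        n_medical, int(invalid.sum()),
    )
    return out


def residualize(pheno: pd.DataFrame) -> pd.DataFrame:
    """Regress age and sex out of the raw score by ordinary least squares.

    ``residual_score`` is the OLS residual of ``raw_score`` on an intercept,
    age, and a 0/1 sex indicator, fitted on rows with a non-missing score.
    """
    _check_schema(pheno)
    out = pheno.copy()
    scored = out["raw_score"].notna()
    if int(scored.sum()) < 3:
        raise ValueError("residualize needs at least 3 non-missing scores")
    y = out.loc[scored, "raw_score"].to_numpy(dtype=float)
    age = out.loc[scored, "age"].to_numpy(dtype=float)
    sex = _sex_indicator(out.loc[scored, "sex"])
    if np.isnan(age).any() or np.isnan(sex).any():
        raise ValueError("age/sex must be non-missing where the score is present")
    X = np.column_stack([np.ones_like(y), age, sex])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError(
            "rank-deficient covariate design (age and sex carry no joint "
            "variation); cannot residualize"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    out["residual_score"] = np.nan
    out.loc[scored, "residual_score"] = y - X @ beta
    return out


def remove_outliers(pheno: pd.DataFrame, k_sd: float = 4.0) -> pd.DataFrame:
    """Blank residual scores farther than ``k_sd`` SDs from the residual mean.

    Mean and SD are computed once on the pre-filter residuals. A zero SD makes
    the rule a no-op (with a warning).
    """
    if "residual_score" not in pheno.columns:
        raise ValueError("run residualize before remove_outliers")
    out = pheno.copy()
    res = out["residual_score"].to_numpy(dtype=float)
    scored = ~np.isnan(res)
    mu = res[scored].mean()
    sd = res[scored].std(ddof=0)
    if sd == 0:
        warnings.warn("residual SD is zero; outlier rule is a no-op")
        return out
    outlier = scored & (np.abs(res - mu) > k_sd * sd)
    out.loc[outlier, "residual_score"] = np.nan
    logger.info("remove_outliers: blanked %d residuals beyond %.3g SD",
                int(outlier.sum()), k_sd)
    return out


def binarize(
    pheno: pd.DataFrame, lower_q: float = 1 / 3, upper_q: float = 2 / 3
) -> pd.DataFrame:
    """Label the bottom tertile of residual scores ``poor`` and the top ``good``.

    Thresholds are empirical quantiles with linear interpolation; boundary ties
    are inclusive, so every score at or below the lower threshold is ``poor``
    and at or above the upper threshold ``good``. Rows in between, or without a
    residual score, are ``unassigned``. An all-tied input yields no labels.
    """
    if "residual_score" not in pheno.columns:
        raise ValueError("run residualize before binarize")
    out = pheno.copy()
    res = out["residual_score"].to_numpy(dtype=float)
    scored = ~np.isnan(res)
    if int(scored.sum()) < 3:
        raise ValueError("binarize needs at least 3 scored rows")
    out["label"] = "unassigned"
    vals = res[scored]
    if np.unique(vals).size == 1:
        warnings.warn("all residual scores identical; no labels assigned")
        return out
    lo = np.quantile(vals, lower_q)
    hi = np.quantile(vals, upper_q)
    out.loc[scored & (res <= lo), "label"] = "poor"
    out.loc[scored & (res >= hi), "label"] = "good"
    n_poor = int((out["label"] == "poor").sum())
    n_good = int((out["label"] == "good").sum())
    logger.info("binarize: %d poor / %d good / %d unassigned",
                n_poor, n_good, len(out) - n_poor - n_good)
    return out


def prepare_phenotype(
    pheno: pd.DataFrame,
    k_sd: float = 4.0,
    lower_q: float = 1 / 3,
    upper_q: float = 2 / 3,
) -> pd.DataFrame:
    """Full preparation chain: validity filter, residualize, de-outlier, binarize."""
    out = filter_invalid(pheno)
    out = residualize(out)
    out = remove_outliers(out, k_sd=k_sd)
    return binarize(out, lower_q=lower_q, upper_q=upper_q)
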
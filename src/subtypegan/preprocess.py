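"""Covariate residualization and CN-referenced normalization of ROI volumes.

Age and sex effects are estimated by per-ROI ordinary least squares on the
cognitively-normal (CN) reference rows only, then removed from every row
(CN and patient, cross-sectional and longitudinal) as deviations from the CN
covariate means, so the CN-referenced intercept is preserved. Each ROI is
then rescaled so the CN reference block has mean 1 and standard deviation
0.1; on that scale a value of 1.0 reads as "typical CN volume" and each 0.1
is one CN standard deviation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .io import ROITable

logger = logging.getLogger(__name__)

TARGET_MEAN = 1.0
TARGET_SD = 0.1
MIN_CN_ROWS = 10
_SCHEMA_VERSION = 1


@dataclass
class CovariateModel:
    """Per-ROI OLS coefficients of volume on (age, sex), fit on CN rows."""

    roi_names: list[str]
    beta_age: np.ndarray
    beta_sex: np.ndarray
    intercept: np.ndarray
    mean_age: float
    mean_sex: float
    n_fit: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": "subtypegan.covariate_model",
                "version": _SCHEMA_VERSION,
                "mean_age": self.mean_age,
                "mean_sex": self.mean_sex,
                "n_fit": self.n_fit,
                "coefficients": {
                    name: {
                        "beta_age": float(self.beta_age[i]),
                        "beta_sex": float(self.beta_sex[i]),
                        "intercept": float(self.intercept[i]),
                    }
                    for i, name in enumerate(self.roi_names)
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CovariateModel":
        doc = json.loads(text)
        if doc.get("schema") != "subtypegan.covariate_model":
            raise ValueError("not a covariate-model document")
        names = list(doc["coefficients"])
        coef = doc["coefficients"]
        return cls(
            roi_names=names,
            beta_age=np.array([coef[n]["beta_age"] for n in names]),
            beta_sex=np.array([coef[n]["beta_sex"] for n in names]),
            intercept=np.array([coef[n]["intercept"] for n in names]),
            mean_age=doc["mean_age"],
            mean_sex=doc["mean_sex"],
            n_fit=doc["n_fit"],
        )


@dataclass
class Normalizer:
    """Per-ROI CN mean/SD used to map volumes to the mean-1 / SD-0.1 scale."""

    roi_names: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    target_mean: float = TARGET_MEAN
    target_sd: float = TARGET_SD

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": "subtypegan.normalizer",
                "version": _SCHEMA_VERSION,
                "target_mean": self.target_mean,
                "target_sd": self.target_sd,
                "moments": {
                    name: {"mu": float(self.mu[i]), "sigma": float(self.sigma[i])}
                    for i, name in enumerate(self.roi_names)
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Normalizer":
        doc = json.loads(text)
        if doc.get("schema") != "subtypegan.normalizer":
            raise ValueError("not a normalizer document")
        names = list(doc["moments"])
        m = doc["moments"]
        return cls(
            roi_names=names,
            mu=np.array([m[n]["mu"] for n in names]),
            sigma=np.array([m[n]["sigma"] for n in names]),
            target_mean=doc["target_mean"],
            target_sd=doc["target_sd"],
        )


def _check_roi_names(rows: ROITable, names: list[str]) -> None:
    if rows.roi_names != names:
        raise ValueError("ROI names of the table do not match the fitted model")


def fit_covariate_model(cn_rows: ROITable) -> CovariateModel:
    """Fit per-ROI OLS of volume on (intercept, age, sex) over CN rows.

    Refuses non-CN rows and fewer than 10 rows. A constant covariate (e.g.
    a single-sex cohort) gets a zero coefficient with a logged warning.
    """
    diag = cn_rows.data["diagnosis"]
    if not (diag == "CN").all():
        raise ValueError("covariate model must be fit on CN rows only")
    n = len(cn_rows)
    if n < MIN_CN_ROWS:
        raise ValueError(f"need at least {MIN_CN_ROWS} CN rows, got {n}")

    age = cn_rows.data["age"].to_numpy(dtype=float)
    sex = cn_rows.data["sex"].to_numpy(dtype=float)
    y = cn_rows.values  # (n, R)

    cols = [np.ones(n)]
    use = {"age": np.ptp(age) > 0, "sex": np.ptp(sex) > 0}
    for name, keep in use.items():
        if not keep:
            logger.warning("covariate %r is constant in CN rows; coefficient set to 0", name)
    if use["age"]:
        cols.append(age)
    if use["sex"]:
        cols.append(sex)
    X = np.column_stack(cols)
    # collinearity beyond constant columns: drop sex if it is an affine
    # function of age (rank deficiency), with a warning
    if np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning("age and sex are collinear in CN rows; dropping sex coefficient")
        use["sex"] = False
        X = X[:, :2] if use["age"] else X[:, :1]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    k = 1
    intercept = beta[0]
    if use["age"]:
        beta_age = beta[k]
        k += 1
    else:
        beta_age = np.zeros(y.shape[1])
    beta_sex = beta[k] if use["sex"] else np.zeros(y.shape[1])

    return CovariateModel(
        roi_names=list(cn_rows.roi_names),
        beta_age=np.asarray(beta_age, dtype=float),
        beta_sex=np.asarray(beta_sex, dtype=float),
        intercept=np.asarray(intercept, dtype=float),
        mean_age=float(age.mean()),
        mean_sex=float(sex.mean()),
        n_fit=n,
    )


def apply_residualization(rows: ROITable, model: CovariateModel) -> ROITable:
    """Remove age/sex effects as deviations from the CN covariate means.

    value' = value − beta_age·(age − mean_age) − beta_sex·(sex − mean_sex),
    so the per-ROI CN mean is preserved and 1.0 keeps its meaning after
    normalization. Applied identically to every row.
    """
    _check_roi_names(rows, model.roi_names)
    age = rows.data["age"].to_numpy(dtype=float)
    sex = rows.data["sex"].to_numpy(dtype=float)
    adj = (
        np.outer(age - model.mean_age, model.beta_age)
        + np.outer(sex - model.mean_sex, model.beta_sex)
    )
    return rows.with_values(rows.values - adj)


def fit_normalizer(cn_residualized: ROITable) -> Normalizer:
    """Store per-ROI mean and sample SD (ddof=1) over the CN rows."""
    vals = cn_residualized.values
    mu = vals.mean(axis=0)
    sigma = vals.std(axis=0, ddof=1)
    # relative guard: a numerically-constant ROI is as bad as an exactly
    # constant one
    bad = np.flatnonzero(sigma <= 1e-12 * np.maximum(1.0, np.abs(mu)))
    if bad.size:
        names = [cn_residualized.roi_names[i] for i in bad]
        raise ValueError(f"zero-variance ROI(s) in CN rows: {names}")
    return Normalizer(roi_names=list(cn_residualized.roi_names), mu=mu, sigma=sigma)


def apply_normalizer(rows: ROITable, norm: Normalizer) -> ROITable:
    """Map each ROI to value' = 1 + 0.1·(value − mu)/sigma."""
    _check_roi_names(rows, norm.roi_names)
    vals = norm.target_mean + norm.target_sd * (rows.values - norm.mu) / norm.sigma
    return rows.with_values(vals)


def preprocess(
    table: ROITable, reference: ROITable | None = None
) -> tuple[ROITable, CovariateModel, Normalizer]:
    """Fit on the CN rows of ``reference`` (default: of ``table``) and
    transform every row of ``table``. Returns the transformed table plus the
    fitted objects, which can be re-applied to held-out or longitudinal data.
    """
    cn = (reference if reference is not None else table).select_diagnosis("CN")
    cov = fit_covariate_model(cn)
    cn_resid = apply_residualization(cn, cov)
    norm = fit_normalizer(cn_resid)
    out = apply_normalizer(apply_residualization(table, cov), norm)
    return out, cov, norm


def apply_preprocessing(table: ROITable, cov: CovariateModel, norm: Normalizer) -> ROITable:
    """Apply previously fitted residualization + normalization to new rows."""
    return apply_normalizer(apply_residualization(table, cov), norm)
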
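"""Survey-weighted association of cluster membership with BMI and WC.

Outcomes are regressed on cluster membership plus categorical covariates
(survey year, age group, sex, race/ethnicity, income category) and the
continuous energy-misreporting ratio EI/EER, using survey weights.
Variance is design-based: Taylor-series linearization over strata and
primary sampling units (PSUs) with the with-replacement first-stage
approximation; design degrees of freedom are #PSUs - #strata.

Least-squares means are the model predictions per cluster with every
covariate held at its weighted mean; all pairwise cluster differences
carry Tukey-Kramer adjusted p-values from the studentized range
distribution, the standard family-wise correction for all-pairs
contrasts.

The misreporting ratio EI/EER uses the Institute of Medicine adult
estimated-energy-requirement equations:

    male:   EER = 662 - 9.53*age + PA*(15.91*weight_kg + 539.6*height_m)
    female: EER = 354 - 6.91*age + PA*( 9.36*weight_kg + 726.0*height_m)

with the physical-activity coefficient PA defaulting to 1.0 (sedentary),
since 24-h recall data carry no activity measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyDesign",
    "AssociationResult",
    "compute_eer",
    "misreporting_ratio",
    "tukey_kramer_adjust",
    "fit_adjusted_model",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = [
    "survey_year",
    "age_group",
    "sex",
    "race_ethnicity",
    "pir_category",
    "misreporting_ratio",
]

_ADULT_AGE_RANGE = (20.0, 65.0)


def compute_eer(
    sex: str, age_years: float, weight_kg: float, height_m: float, pa_factor: float = 1.0
) -> float:
    """IOM adult estimated energy requirement in kcal/day."""
    if not _ADULT_AGE_RANGE[0] <= age_years <= _ADULT_AGE_RANGE[1]:
        raise ValueError(f"age {age_years} outside the adult 20-65 y scope")
    if weight_kg <= 0 or height_m <= 0 or pa_factor <= 0:
        raise ValueError("weight, height and PA must be positive")
    if str(sex).lower() in ("male", "m"):
        return 662.0 - 9.53 * age_years + pa_factor * (15.91 * weight_kg + 539.6 * height_m)
    if str(sex).lower() in ("female", "f"):
        return 354.0 - 6.91 * age_years + pa_factor * (9.36 * weight_kg + 726.0 * height_m)
    raise ValueError(f"unknown sex {sex!r}")


def misreporting_ratio(energy_intake_kcal: float, eer_kcal: float) -> float:
    """Energy-misreporting covariate: reported intake over requirement."""
    if energy_intake_kcal <= 0 or eer_kcal <= 0:
        raise ValueError("energy intake and EER must be positive")
    return energy_intake_kcal / eer_kcal


def tukey_kramer_adjust(
    differences: Sequence[float],
    ses: Sequence[float],
    df: float,
    n_groups: int,
) -> np.ndarray:
    """Tukey-Kramer adjusted p-values for all-pairs contrasts.

    p_adj = P(Q_{k, df} >= |diff| * sqrt(2) / SE) with Q the studentized
    range.  With two groups this reduces exactly to the two-sided t-test.
    """
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if df <= 0:
        raise ValueError("df must be positive")
    diffs = np.asarray(differences, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if (ses <= 0).any():
        raise ValueError("standard errors must be positive")
    q = np.abs(diffs) * np.sqrt(2.0) / ses
    p = stats.studentized_range.sf(q, n_groups, df)
    return np.clip(p, 0.0, 1.0)


@dataclass(frozen=True)
class SurveyDesign:
    """Column names of the complex-survey fields plus lonely-PSU policy."""

    weight: str = "weight"
    stratum: str = "stratum"
    psu: str = "psu"
    lonely_psu: str = "error"  # or "center": deviations from the overall mean
    residual_adjustment: str = "hc3"  # or "hc2" / "none"

    def __post_init__(self) -> None:
        if self.lonely_psu not in ("error", "center"):
            raise ValueError("lonely_psu must be 'error' or 'center'")
        if self.residual_adjustment not in ("none", "hc2", "hc3"):
            raise ValueError("residual_adjustment must be 'none', 'hc2' or 'hc3'")


@dataclass
class AssociationResult:
    """Adjusted cluster means and all-pairs contrasts for one outcome."""

    outcome: str
    clusters: list
    lsmeans: pd.DataFrame          # cluster, n, lsmean, se
    pairwise: pd.DataFrame         # cluster_a, cluster_b, estimate, se, ci, p_adj
    r_squared: float
    n_used: int
    df_design: float
    coefficients: pd.Series = field(repr=False, default=None)
    covariance: pd.DataFrame = field(repr=False, default=None)

    def to_tables(self, path_prefix) -> None:
        self.lsmeans.to_csv(f"{path_prefix}_lsmeans.csv", index=False)
        self.pairwise.to_csv(f"{path_prefix}_pairwise.csv", index=False)


def _design_matrix(records: pd.DataFrame, covariates: Sequence[str], cluster_col: str):
    """Reference-coded design: intercept, cluster dummies, covariate columns."""
    cols = {"(Intercept)": np.ones(len(records))}
    clusters = sorted(records[cluster_col].unique())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters present")
    cluster_cols = []
    for c in clusters[1:]:
        name = f"{cluster_col}[{c}]"
        cols[name] = (records[cluster_col] == c).to_numpy(dtype=float)
        cluster_cols.append(name)
    cov_cols = []
    for cov in covariates:
        col = records[cov]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 8:
            cols[cov] = col.to_numpy(dtype=float)
            cov_cols.append(cov)
        else:
            levels = sorted(col.unique(), key=str)
            for lev in levels[1:]:
                name = f"{cov}[{lev}]"
                v = (col == lev).to_numpy(dtype=float)
                if v.sum() == 0:
                    raise ValueError(f"empty covariate level {cov}={lev!r}")
                cols[name] = v
                cov_cols.append(name)
    X = pd.DataFrame(cols, index=records.index)
    return X, clusters, cluster_cols, cov_cols


def _linearized_cov(
    X: np.ndarray,
    resid: np.ndarray,
    w: np.ndarray,
    strata: np.ndarray,
    psus: np.ndarray,
    XtWX_inv: np.ndarray,
    lonely_psu: str,
    residual_adjustment: str = "hc3",
) -> tuple[np.ndarray, float]:
    """Taylor-linearization covariance of WLS coefficients; returns (V, df).

    Fitted residuals are shrunk by their own leverage, which biases the
    linearized variance low in finite samples; the default "hc3"
    adjustment divides each residual by (1 - h_ii), approximating the
    delete-one jackknife.  "hc2" divides by sqrt(1 - h_ii); "none"
    uses raw residuals.
    """
    if residual_adjustment != "none":
        h = np.einsum("ij,jk,ik->i", X, XtWX_inv, X * w[:, None])
        h = np.clip(h, 0.0, 0.999)
        resid = resid / (1.0 - h) if residual_adjustment == "hc3" else resid / np.sqrt(1.0 - h)
    score = X * (w * resid)[:, None]                       # per-unit estimating scores
    frame = pd.DataFrame({"stratum": strata, "psu": psus})
    psu_tot = (
        pd.DataFrame(score, index=frame.index)
        .groupby([frame["stratum"], frame["psu"]])
        .sum()
    )
    M = np.zeros((X.shape[1], X.shape[1]))
    n_psu_total = 0
    n_strata = 0
    grand_mean = None
    for stratum, z in psu_tot.groupby(level=0):
        n_strata += 1
        zh = z.to_numpy()
        n_h = zh.shape[0]
        n_psu_total += n_h
        if n_h == 1:
            if lonely_psu == "error":
                raise ValueError(
                    f"stratum {stratum!r} has a single PSU; enable lonely_psu='center'"
                )
            if grand_mean is None:
                grand_mean = psu_tot.to_numpy().mean(axis=0)
            dev = zh - grand_mean
            M += dev.T @ dev
            continue
        dev = zh - zh.mean(axis=0)
        M += (n_h / (n_h - 1)) * dev.T @ dev
    V = XtWX_inv @ M @ XtWX_inv
    df = float(n_psu_total - n_strata)
    return V, df


def fit_adjusted_model(
    records: pd.DataFrame,
    outcome: str,
    cluster_col: str = "cluster",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    design: SurveyDesign = SurveyDesign(),
    ci_level: float = 0.95,
) -> AssociationResult:
    """Survey-weighted linear model of an outcome on cluster + covariates.

    Point estimates solve the weighted normal equations; variance is by
    stratum/PSU Taylor linearization; least-squares means evaluate the
    fit at the weighted covariate means; all pairwise cluster contrasts
    get Tukey-Kramer adjusted p-values on the design degrees of freedom.
    """
    records = records.reset_index(drop=True)
    y = records[outcome].to_numpy(dtype=float)
    w = records[design.weight].to_numpy(dtype=float)
    if (w <= 0).any():
        raise ValueError("survey weights must be strictly positive")
    X_df, clusters, cluster_cols, cov_cols = _design_matrix(
        records, covariates, cluster_col
    )
    X = X_df.to_numpy()
    XtWX = X.T @ (X * w[:, None])
    rank = np.linalg.matrix_rank(XtWX)
    if rank < X.shape[1]:
        raise ValueError("singular design matrix (collinear or empty covariate level)")
    XtWX_inv = np.linalg.inv(XtWX)
    beta = XtWX_inv @ (X.T @ (w * y))
    resid = y - X @ beta

    V, df = _linearized_cov(
        X,
        resid,
        w,
        records[design.stratum].to_numpy(),
        records[design.psu].to_numpy(),
        XtWX_inv,
        design.lonely_psu,
        design.residual_adjustment,
    )

    ybar = np.average(y, weights=w)
    r2 = 1.0 - np.sum(w * resid**2) / np.sum(w * (y - ybar) ** 2)

    # ls-means: covariate columns at weighted means, cluster dummies switched
    xbar = np.average(X, axis=0, weights=w)
    names = list(X_df.columns)
    idx = {name: i for i, name in enumerate(names)}
    base_row = xbar.copy()
    for name in cluster_cols:
        base_row[idx[name]] = 0.0
    rows = {}
    for c in clusters:
        row = base_row.copy()
        name = f"{cluster_col}[{c}]"
        if name in idx:
            row[idx[name]] = 1.0
        rows[c] = row
    counts = records[cluster_col].value_counts()
    lsmeans = pd.DataFrame(
        {
            "cluster": clusters,
            "n": [int(counts[c]) for c in clusters],
            "lsmean": [float(rows[c] @ beta) for c in clusters],
            "se": [float(np.sqrt(rows[c] @ V @ rows[c])) for c in clusters],
        }
    )

    k = len(clusters)
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df)
    pair_rows = []
    for a, b in combinations(clusters, 2):
        L = rows[a] - rows[b]
        est = float(L @ beta)
        se = float(np.sqrt(L @ V @ L))
        pair_rows.append(
            {
                "cluster_a": a,
                "cluster_b": b,
                "estimate": est,
                "se": se,
                "ci_low": est - tcrit * se,
                "ci_high": est + tcrit * se,
            }
        )
    pairwise = pd.DataFrame(pair_rows)
    pairwise["p_adj"] = tukey_kramer_adjust(
        pairwise["estimate"], pairwise["se"], df=df, n_groups=k
    )

    return AssociationResult(
        outcome=outcome,
        clusters=clusters,
        lsmeans=lsmeans,
        pairwise=pairwise,
        r_squared=float(r2),
        n_used=len(records),
        df_design=df,
        coefficients=pd.Series(beta, index=names),
        covariance=pd.DataFrame(V, index=names, columns=names),
    )
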
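"""Alpha diversity (effective richness ^1D) and its time model.

^1D, the Hill number of order 1, is the exponential of Shannon entropy: the
number of equally abundant taxa that would give the sample's observed
entropy. Biofilm maturation time is modelled with a linear mixed model of
log(^1D) on day — subjects as random intercepts, optionally random slopes —
fitted by restricted maximum likelihood (REML). The log-normal response is
a close working approximation to a log-link gamma model for this positive,
right-skewed quantity; the approximation is recorded on the fit object.
Candidate random structures are compared by AIC with the fixed effects held
identical, and the day effect is assessed by its Wald p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .tables_io import CountTable


def effective_richness(counts: np.ndarray) -> float:
    """^1D = exp(Shannon entropy, natural log), zeros omitted."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector has no diversity")
    p = x[x > 0] / total
    return float(np.exp(-(p * np.log(p)).sum()))


def diversity_records(table: CountTable) -> pd.DataFrame:
    """Per-sample observed and effective richness with subject/day."""
    if table.metadata is None:
        raise ValueError("metadata required")
    rows = []
    for sample, row in table.counts.iterrows():
        vec = row.to_numpy()
        rows.append({
            "sample": sample,
            "subject": table.metadata.loc[sample, "subject"],
            "day": int(table.metadata.loc[sample, "day"]),
            "observed_richness": int((vec > 0).sum()),
            "effective_richness": effective_richness(vec),
        })
    return pd.DataFrame(rows).set_index("sample")


@dataclass
class MixedFit:
    """REML fit of log(^1D) ~ day with subject random effects."""

    intercept: float
    day_slope: float
    day_pvalue: float
    intercept_var: float
    slope_var: float | None
    intercept_slope_cov: float | None
    residual_var: float
    reml_criterion: float  # -2 * restricted log-likelihood
    aic: float
    n_obs: int
    n_subjects: int
    random_slope: bool
    converged: bool
    response: str = "log effective richness (log-normal approximation to gamma/log-link)"

    def summary_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def fit_mixed_model(records: pd.DataFrame, random_slope: bool = False) -> MixedFit:
    """Fit log(^1D)_sj = b0 + b1*day + u_s (+ v_s*day) + e by REML.

    ``records`` needs columns ``subject``, ``day``, ``effective_richness``.
    Day enters as a numeric covariate. A boundary fit (zero random-effect
    variance) is returned with a warning rather than raised.
    """
    y = records["effective_richness"].to_numpy(dtype=float)
    if (y <= 0).any():
        raise ValueError("effective richness must be positive")
    if records["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    data = pd.DataFrame({
        "logd": np.log(y),
        "day": records["day"].to_numpy(dtype=float),
        "subject": records["subject"].to_numpy(),
    })
    exog = sm.add_constant(data[["day"]])
    model = sm.MixedLM(data["logd"], exog, groups=data["subject"],
                       exog_re=sm.add_constant(data[["day"]]) if random_slope
                       else np.ones((len(data), 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method=["lbfgs", "powell"])
        except Exception:
            res = model.fit(reml=True, method="powell")
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    intercept_var = float(cov_re[0, 0])
    slope_var = float(cov_re[1, 1]) if random_slope else None
    cov_is = float(cov_re[0, 1]) if random_slope else None
    if intercept_var <= 1e-10:
        warnings.warn("random-intercept variance at boundary (~0)", stacklevel=2)
    # k: fixed effects + variance components (+1 residual variance)
    k = 2 + (3 if random_slope else 1) + 1
    reml_crit = float(-2.0 * res.llf)
    return MixedFit(
        intercept=float(res.fe_params.iloc[0]),
        day_slope=float(res.fe_params.iloc[1]),
        day_pvalue=float(res.pvalues.iloc[1]),
        intercept_var=intercept_var,
        slope_var=slope_var,
        intercept_slope_cov=cov_is,
        residual_var=float(res.scale),
        reml_criterion=reml_crit,
        aic=reml_crit + 2 * k,
        n_obs=len(data),
        n_subjects=int(data["subject"].nunique()),
        random_slope=random_slope,
        converged=bool(res.converged),
        # re_formula recorded implicitly via random_slope
    )


def compare_random_structures(records: pd.DataFrame) -> dict:
    """Fit random-intercept and random-intercept+slope models, pick by AIC."""
    ri = fit_mixed_model(records, random_slope=False)
    rs = fit_mixed_model(records, random_slope=True)
    best = ri if ri.aic <= rs.aic else rs
    return {"random_intercept": ri, "random_intercept_slope": rs, "best": best}
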
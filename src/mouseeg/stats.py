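"""Mixed-model treatment contrasts with Bonferroni families.

The design is within-subject: every animal is measured under every treatment
(vehicle at baseline, one or more doses, vehicle after final washout). For
each biomarker a linear mixed model is fitted with treatment as a fixed
factor and a random intercept per animal,

    value_ij = mu + tau_j + b_i + e_ij,   b_i ~ N(0, s_b²), e_ij ~ N(0, s²),

and the predefined contrasts are each dose minus vehicle-at-baseline, plus
washout minus baseline as an uncorrected return-to-baseline check.

Inference: the REML Wald statistic for a treatment contrast is referred to a
t distribution with the randomized-complete-block residual degrees of
freedom, (n_treatments − 1)·(n_animals − 1) for a complete design (the
number of observations minus treatment and animal parameters otherwise) — in
the balanced case this reproduces the exact paired ANOVA t test, so the
nominal type-I error holds at small n. If the mixed fit fails or the
between-animal variance collapses to the boundary, the equivalent
fixed-effects (animal as a blocking factor) analysis is used with a warning;
its contrast estimates and t statistics coincide in the balanced case.

Multiplicity: one Bonferroni family per protocol and compound — the divided
level is ``0.05 / (n_doses * n_parameters)``. Washout-vs-baseline contrasts
are deliberately exempt and tested at 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as spstats

from .errors import AnalysisError, ParameterError

__all__ = [
    "ContrastResult",
    "make_biomarker_table",
    "fit_contrasts",
    "bonferroni_alpha",
    "summarize",
]

BIOMARKER_COLUMNS = ["animal_id", "treatment", "protocol", "parameter", "value"]


@dataclass(frozen=True)
class ContrastResult:
    """One estimated treatment difference with its two-sided 95% CI."""

    label: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float
    is_washout: bool = False
    method: str = "mixed"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise AnalysisError("confidence interval does not bracket the estimate")


def make_biomarker_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble tidy per-animal, per-treatment readouts.

    Enforces one value per animal × treatment × parameter.
    """
    df = pd.DataFrame(rows)
    missing = [c for c in BIOMARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"biomarker rows missing fields: {missing}")
    dup = df.duplicated(subset=["animal_id", "treatment", "parameter"])
    if dup.any():
        raise ParameterError("duplicate animal x treatment x parameter entries")
    return df[BIOMARKER_COLUMNS]


def _fixed_effects_fit(df: pd.DataFrame, baseline: str):
    model = smf.ols(
        f"value ~ C(treatment, Treatment(reference='{baseline}')) + C(animal_id)",
        data=df,
    )
    return model.fit()


def fit_contrasts(
    table: pd.DataFrame,
    parameter: str,
    *,
    baseline: str = "vehicle_baseline",
    washout: str = "vehicle_washout",
    conf_level: float = 0.95,
) -> list[ContrastResult]:
    """Fit the per-parameter mixed model and estimate the treatment contrasts.

    Returns one :class:`ContrastResult` per non-baseline treatment level
    (doses plus, when present, the washout contrast, flagged as such).
    """
    df = table[table["parameter"] == parameter].copy()
    if df.empty:
        raise AnalysisError(f"no rows for parameter {parameter!r}")
    treatments = list(pd.unique(df["treatment"]))
    animals = pd.unique(df["animal_id"])
    if baseline not in treatments:
        raise AnalysisError(f"baseline treatment {baseline!r} absent")
    if len(animals) < 2 or len(treatments) < 2:
        raise AnalysisError("need >= 2 animals and >= 2 treatments")

    n_obs = len(df)
    df_resid = n_obs - len(treatments) - len(animals) + 1
    if df_resid < 1:
        raise AnalysisError("not enough observations for the block design")

    term = f"C(treatment, Treatment(reference='{baseline}'))"
    method = "mixed"
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(f"value ~ {term}", df, groups=df["animal_id"])
            fit = model.fit(reml=True)
            if not np.isfinite(fit.params).all() or not np.isfinite(fit.bse).all():
                raise RuntimeError("non-finite mixed-model estimates")
        except Exception:
            fit = None
    if fit is None:
        warnings.warn(
            "mixed model failed to converge; falling back to the fixed-effects "
            "(animal-block) analysis",
            stacklevel=2,
        )
        fit = _fixed_effects_fit(df, baseline)
        method = "fixed-block"

    tcrit = spstats.t.ppf(0.5 + conf_level / 2, df_resid)
    out = []
    for treat in treatments:
        if treat == baseline:
            continue
        name = f"{term}[T.{treat}]"
        est = float(fit.params[name])
        se = float(fit.bse[name])
        if se == 0 or not np.isfinite(se):
            p, lo, hi = 1.0, est, est
        else:
            tval = est / se
            p = float(2 * spstats.t.sf(abs(tval), df_resid))
            lo, hi = est - tcrit * se, est + tcrit * se
        out.append(
            ContrastResult(
                label=f"{treat} - {baseline}",
                estimate=est,
                ci_low=lo,
                ci_high=hi,
                p_value=p,
                df=df_resid,
                is_washout=(treat == washout),
                method=method,
            )
        )
    return out


def bonferroni_alpha(
    n_doses: int, n_parameters: int, family_alpha: float = 0.05
) -> float:
    """Divided significance level for one protocol × compound family.

    The family is the set of dose × parameter tests: ``alpha* =
    family_alpha / (n_doses * n_parameters)``. Washout-vs-baseline
    comparisons are a return-to-baseline check and are exempt (tested at
    ``family_alpha``).
    """
    if n_doses < 1 or n_parameters < 1:
        raise ParameterError("counts must be >= 1")
    if not 0 < family_alpha < 1:
        raise ParameterError("family_alpha must be in (0, 1)")
    return family_alpha / (n_doses * n_parameters)


def summarize(
    contrasts: list[ContrastResult],
    alpha_star: float,
    washout_alpha: float = 0.05,
) -> pd.DataFrame:
    """Report table: estimate / confidence limits / p / significance flag.

    Dose contrasts are flagged at the Bonferroni-corrected ``alpha_star``;
    washout contrasts at ``washout_alpha`` (no correction).
    """
    if not contrasts:
        raise ParameterError("no contrasts to summarize")
    rows = []
    for c in contrasts:
        alpha = washout_alpha if c.is_washout else alpha_star
        rows.append(
            {
                "contrast": c.label,
                "estimate": c.estimate,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "p_value": c.p_value,
                "alpha": alpha,
                "significant": c.p_value < alpha,
                "washout": c.is_washout,
                "method": c.method,
            }
        )
    return pd.DataFrame(rows)
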
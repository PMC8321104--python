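"""Mixed-effects association suite with a per-annotator random intercept.

Repeated measures (one observation per annotator x triplet) are analysed
with random-intercept models: linear mixed models (REML) for continuous
outcomes (duration, EDA), and a Bayesian binomial mixed GLM (variational
fit, Wald-style intervals from the posterior) for the binary correctness
outcome, reported on the odds-ratio scale.  Significance is read at
p < 0.05; no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

from .datatypes import AnnotationMatrix

logger = logging.getLogger(__name__)

DEFAULT_SKIP_FIRST = 3
ALPHA_LEVEL = 0.05


class ConvergenceError(RuntimeError):
    """The mixed-model fit did not converge."""


class DegenerateOutcomeError(ValueError):
    """Outcome is constant (or otherwise uninformative)."""


@dataclass
class FitResult:
    """One fitted exposure -> outcome association."""

    exposure: str
    outcome: str
    adjust: tuple[str, ...]
    estimate: float          # odds ratio for the logistic family
    ci_low: float
    ci_high: float
    p_value: float
    family: Literal["linear", "logistic"]
    n_obs: int = 0
    n_groups: int = 0
    random_intercept_var: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA_LEVEL

    def summary_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "adjust": "+".join(self.adjust) if self.adjust else "",
            "family": self.family,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_value,
        }


def _events_frame(events) -> pd.DataFrame:
    if isinstance(events, AnnotationMatrix):
        return events.to_frame()
    return pd.DataFrame(events).copy()


def fit_random_intercept(
    events,
    exposure: str,
    outcome: str,
    adjust: Sequence[str] = (),
    family: Literal["linear", "logistic"] = "linear",
) -> FitResult:
    """Fit outcome ~ exposure (+ adjustments) with a per-annotator random
    intercept and return the exposure effect with its 95% CI and p-value.

    Linear family: REML linear mixed model.  Logistic family: binomial
    mixed GLM fitted by variational Bayes; the effect is reported as an
    odds ratio with a Wald-style interval from the posterior mean and sd.
    """
    df = _events_frame(events)
    needed = {exposure, outcome, "annotator_id", *adjust}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"events table missing column(s): {sorted(missing)}")
    df = df.dropna(subset=[exposure, outcome, *adjust])
    if df["annotator_id"].nunique() < 2:
        raise ValueError("need at least two annotators for a random intercept")
    y = df[outcome].to_numpy(float)
    if np.allclose(y, y[0]):
        raise DegenerateOutcomeError(f"outcome {outcome!r} is constant")

    rhs = " + ".join([exposure, *adjust])
    formula = f"{outcome} ~ {rhs}"

    if family == "linear":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["annotator_id"])
            # powell handles the zero-variance boundary cleanly where
            # gradient-based optimizers can stall on a degenerate profile
            fit = model.fit(reml=True, method=["powell", "nm"])
        if not fit.converged:
            raise ConvergenceError(
                f"linear mixed model {formula!r} did not converge"
            )
        est = float(fit.params[exposure])
        ci = fit.conf_int().loc[exposure]
        return FitResult(
            exposure=exposure,
            outcome=outcome,
            adjust=tuple(adjust),
            estimate=est,
            ci_low=float(ci[0]),
            ci_high=float(ci[1]),
            p_value=float(fit.pvalues[exposure]),
            family="linear",
            n_obs=len(df),
            n_groups=df["annotator_id"].nunique(),
            random_intercept_var=float(np.asarray(fit.cov_re).ravel()[0]),
        )

    if family == "logistic":
        uniq = np.unique(y)
        if not set(uniq).issubset({0.0, 1.0}):
            raise ValueError(
                f"logistic family requires a 0/1 outcome; {outcome!r} has values {uniq}"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BinomialBayesMixedGLM.from_formula(
                formula, {"annotator": "0 + C(annotator_id)"}, df
            )
            fit = model.fit_vb()
        names = list(model.exog_names)
        k = names.index(exposure)
        beta = float(fit.fe_mean[k])
        sd = float(fit.fe_sd[k])
        z = beta / sd
        p = 2.0 * stats.norm.sf(abs(z))
        half = stats.norm.ppf(0.975) * sd
        return FitResult(
            exposure=exposure,
            outcome=outcome,
            adjust=tuple(adjust),
            estimate=float(np.exp(beta)),
            ci_low=float(np.exp(beta - half)),
            ci_high=float(np.exp(beta + half)),
            p_value=float(p),
            family="logistic",
            n_obs=len(df),
            n_groups=df["annotator_id"].nunique(),
            random_intercept_var=float(np.exp(2.0 * fit.vcp_mean[0])),
        )

    raise ValueError(f"unknown family {family!r}")


def _skip(df: pd.DataFrame, skip_first: int) -> pd.DataFrame:
    kept = sorted(df["triplet_id"].unique())[skip_first:]
    if not kept:
        raise ValueError("skip_first leaves no triplets")
    return df[df["triplet_id"].isin(kept)]


def association_suite(events, skip_first: int = DEFAULT_SKIP_FIRST) -> list[FitResult]:
    """Fit the full association grid on the annotation events.

    Unadjusted: stated_u -> duration, eda -> duration, stated_u -> eda.
    Ordinal-position effects: triplet_id -> duration, triplet_id -> eda.
    Correctness interplay (adjusted for triplet_id): correct -> duration,
    correct -> eda, stated_u -> correct (logistic).  Stated-U revisited
    (adjusted for triplet_id): stated_u -> duration, stated_u -> eda.
    The first ``skip_first`` triplets (acclimatization) are excluded.
    """
    df = _skip(_events_frame(events), skip_first)
    has_eda = "eda_mean" in df.columns and df["eda_mean"].notna().any()
    if not has_eda:
        logger.info("events carry no EDA means; EDA associations skipped")

    grid: list[tuple[str, str, tuple[str, ...], str]] = [
        ("stated_u", "duration_s", (), "linear"),
        ("eda_mean", "duration_s", (), "linear"),
        ("stated_u", "eda_mean", (), "linear"),
        ("triplet_id", "duration_s", (), "linear"),
        ("triplet_id", "eda_mean", (), "linear"),
        ("correct", "duration_s", ("triplet_id",), "linear"),
        ("correct", "eda_mean", ("triplet_id",), "linear"),
        ("stated_u", "correct", ("triplet_id",), "logistic"),
        ("stated_u", "duration_s", ("triplet_id",), "linear"),
        ("stated_u", "eda_mean", ("triplet_id",), "linear"),
    ]
    results = []
    for exposure, outcome, adjust, family in grid:
        if not has_eda and "eda_mean" in (exposure, outcome):
            continue
        results.append(
            fit_random_intercept(df, exposure, outcome, adjust, family)
        )
    return results


def suite_frame(results: Sequence[FitResult]) -> pd.DataFrame:
    """Association results as a tidy DataFrame (one row per fit)."""
    return pd.DataFrame([r.summary_row() for r in results])


@dataclass
class AcclimatizationSummary:
    """Early-experiment behaviour: does excluding the first k tasks matter?"""

    k: int
    duration_quartiles: pd.DataFrame   # index triplet_id: q1, median, q3
    eda_quartiles: pd.DataFrame | None
    correctness: pd.DataFrame          # per-annotator ratios with/without first k
    improved_count: int                # annotators whose ratio rises on exclusion

    @property
    def n_annotators(self) -> int:
        return len(self.correctness)


def acclimatization_summary(events, k: int = 3) -> AcclimatizationSummary:
    """Quartile summaries per triplet and correctness with/without the
    first ``k`` triplets."""
    df = _events_frame(events)
    triplet_ids = sorted(df["triplet_id"].unique())
    if k >= len(triplet_ids):
        raise ValueError(f"k = {k} must be below the triplet count {len(triplet_ids)}")

    def quartiles(col: str) -> pd.DataFrame:
        g = df.groupby("triplet_id")[col]
        return pd.DataFrame(
            {"q1": g.quantile(0.25), "median": g.quantile(0.5), "q3": g.quantile(0.75)}
        )

    duration_q = quartiles("duration_s")
    eda_q = None
    if "eda_mean" in df.columns and df["eda_mean"].notna().any():
        eda_q = quartiles("eda_mean")

    all_ratio = df.groupby("annotator_id")["correct"].mean()
    kept = triplet_ids[k:]
    skip_ratio = (
        df[df["triplet_id"].isin(kept)].groupby("annotator_id")["correct"].mean()
    )
    correctness = pd.DataFrame(
        {"ratio_all": all_ratio, "ratio_skip_first": skip_ratio}
    )
    improved = int((correctness["ratio_skip_first"] > correctness["ratio_all"]).sum())
    return AcclimatizationSummary(
        k=k,
        duration_quartiles=duration_q,
        eda_quartiles=eda_q,
        correctness=correctness,
        improved_count=improved,
    )
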
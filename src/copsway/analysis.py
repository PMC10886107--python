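"""Group-contrast inference on trial-level stabilometric outcomes.

Each of the 16 sway variables is analysed separately: observations far
from the bulk are first excluded with a robust Mahalanobis-type screen,
then a linear mixed model is fitted with movement-disorder group, age and
therapy (plus all pairwise interactions) as fixed effects and a
per-subject random intercept to absorb the correlation between a
subject's repeated trials:

    y ~ group + age + therapy + group:age + group:therapy + age:therapy
        + (1 | subject)

The reference level is the dystonia group, so the two group coefficients
are the chorea-vs-dystonia and chorea–dystonia-vs-dystonia contrasts.
Estimation is by restricted maximum likelihood (REML); inference is by
Wald z tests with a flat α = 0.05 and no multiplicity correction across
outcomes. Age is centered at the sample mean. These conventions are
recorded on every result.

The outlier screen is univariate and robust: squared distance
``((x − median) / (1.4826·MAD))²`` compared against a χ²(1) quantile
(default 0.975). A bivariate classical variant over (outcome, age) is
also provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import FEATURE_NAMES

__all__ = [
    "TERMS",
    "MAIN_TERMS",
    "INTERACTION_TERMS",
    "OutlierReport",
    "TermEstimate",
    "ModelResult",
    "AnalysisResults",
    "mahalanobis_screen",
    "mahalanobis_screen_bivariate",
    "build_design_matrix",
    "fit_lmm",
    "analyze_all",
]

logger = logging.getLogger(__name__)

#: Consistency constant making the MAD unbiased for the sd under normality.
MAD_SCALE = 1.4826

#: Fixed-effect terms of the group × age × therapy model, dystonia reference.
TERMS: tuple[str, ...] = (
    "Intercept",
    "chorea_vs_dystonia",
    "chorea_dystonia_vs_dystonia",
    "age",
    "therapy",
    "chorea_vs_dystonia:age",
    "chorea_dystonia_vs_dystonia:age",
    "chorea_vs_dystonia:therapy",
    "chorea_dystonia_vs_dystonia:therapy",
    "age:therapy",
)

#: Main-effects report layout (group contrasts, age, therapy).
MAIN_TERMS: tuple[str, ...] = TERMS[1:5]

#: Interactions report layout (group × age, group × therapy, age × therapy).
INTERACTION_TERMS: tuple[str, ...] = TERMS[5:]

_CANONICAL_GROUPS: tuple[str, ...] = ("dystonia", "chorea", "chorea_dystonia")


@dataclass
class OutlierReport:
    """Result of screening one outcome's observations."""

    outcome: str
    flagged: np.ndarray        # positional indices of excluded observations
    distances_sq: np.ndarray   # squared robust distance of every observation
    threshold: float           # χ² cutoff the distances were compared against
    alpha_q: float
    scale_method: str          # 'mad', 'iqr' (MAD degenerate) or 'degenerate'

    @property
    def n_flagged(self) -> int:
        return int(len(self.flagged))


def mahalanobis_screen(
    values, alpha_q: float = 0.975, outcome: str = ""
) -> OutlierReport:
    """Flag observations whose squared robust distance exceeds χ²(1, alpha_q).

    The distance is ``((x − median)/(1.4826·MAD))²``, the univariate
    Mahalanobis distance with robust location and scale. If the MAD is
    zero (more than half the values tied) the scale falls back to the
    normalized interquartile range, IQR/1.349; if that is also zero the
    sample is treated as degenerate and nothing is flagged. The fallback
    is applied automatically and logged.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if len(x) < 5:
        raise ValueError(f"need at least 5 observations, got {len(x)}")
    if not 0.5 < alpha_q < 1:
        raise ValueError("alpha_q must lie in (0.5, 1)")

    median = float(np.median(x))
    mad = float(np.median(np.abs(x - median)))
    scale = MAD_SCALE * mad
    scale_method = "mad"
    if scale == 0.0:
        q75, q25 = np.percentile(x, [75, 25])
        scale = (q75 - q25) / (2.0 * stats.norm.ppf(0.75))
        scale_method = "iqr"
        logger.warning(
            "MAD of %s is zero (degenerate scale); falling back to the "
            "interquartile-range scale", outcome or "outcome")
    threshold = float(stats.chi2.ppf(alpha_q, df=1))
    if scale == 0.0:
        scale_method = "degenerate"
        d_sq = np.zeros_like(x)
    else:
        d_sq = ((x - median) / scale) ** 2
    flagged = np.flatnonzero(d_sq > threshold)
    return OutlierReport(
        outcome=outcome, flagged=flagged, distances_sq=d_sq,
        threshold=threshold, alpha_q=alpha_q, scale_method=scale_method)


def mahalanobis_screen_bivariate(
    values, age, alpha_q: float = 0.975, outcome: str = ""
) -> OutlierReport:
    """Classical-covariance Mahalanobis screen over (outcome, age) pairs
    against a χ²(2) cutoff. Offered as a configuration alternative to the
    default univariate robust screen."""
    x = np.column_stack([np.asarray(values, float), np.asarray(age, float)])
    if len(x) < 5:
        raise ValueError(f"need at least 5 observations, got {len(x)}")
    if not 0.5 < alpha_q < 1:
        raise ValueError("alpha_q must lie in (0.5, 1)")
    center = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        logger.warning(
            "singular covariance in bivariate screen of %s; nothing flagged",
            outcome or "outcome")
        d_sq = np.zeros(len(x))
        threshold = float(stats.chi2.ppf(alpha_q, df=2))
        return OutlierReport(outcome, np.array([], int), d_sq, threshold,
                             alpha_q, "degenerate")
    diff = x - center
    d_sq = np.einsum("ij,jk,ik->i", diff, cov_inv, diff)
    threshold = float(stats.chi2.ppf(alpha_q, df=2))
    flagged = np.flatnonzero(d_sq > threshold)
    return OutlierReport(outcome, flagged, d_sq, threshold, alpha_q,
                         "classical_bivariate")


def _ordered_groups(present: Sequence[str], reference: str) -> list[str]:
    """Non-reference groups in canonical order, unknown labels last."""
    ordered = [g for g in _CANONICAL_GROUPS if g != reference]
    ordered += sorted(set(present) - set(_CANONICAL_GROUPS) - {reference})
    return ordered


def term_names(reference: str = "dystonia") -> tuple[str, ...]:
    """The 10 fixed-effect term names for a given reference group."""
    contrasts = [f"{g}_vs_{reference}" for g in _ordered_groups([], reference)]
    return (
        "Intercept", *contrasts, "age", "therapy",
        *[f"{c}:age" for c in contrasts],
        *[f"{c}:therapy" for c in contrasts],
        "age:therapy",
    )


def build_design_matrix(
    df: pd.DataFrame,
    reference: str = "dystonia",
    age_center: float | None = None,
) -> tuple[np.ndarray, tuple[str, ...], float]:
    """Fixed-effect design matrix for the group × age × therapy model.

    Columns follow :func:`term_names`. Age is centered at ``age_center``
    (default: the sample mean of the rows provided). Group dummies for
    groups absent from the data are included as all-zero columns so the
    10-term report structure is preserved; rank-deficient columns are
    resolved downstream.
    """
    if age_center is None:
        age_center = float(df["age_years"].mean())
    age_c = df["age_years"].to_numpy(float) - age_center
    therapy = df["therapy"].to_numpy(float)
    group = df["group"].astype(str)

    names = term_names(reference)
    contrasts = _ordered_groups(group.unique(), reference)
    cols = [np.ones(len(df))]
    dummies = {g: (group == g).to_numpy(float) for g in contrasts}
    cols += [dummies[g] for g in contrasts]
    cols += [age_c, therapy]
    cols += [dummies[g] * age_c for g in contrasts]
    cols += [dummies[g] * therapy for g in contrasts]
    cols += [age_c * therapy]
    x_mat = np.column_stack(cols)
    # names built from canonical order may exceed columns if extra groups
    # appear; rebuild to match the actual contrast list
    contrast_names = [f"{g}_vs_{reference}" for g in contrasts]
    names = (
        "Intercept", *contrast_names, "age", "therapy",
        *[f"{c}:age" for c in contrast_names],
        *[f"{c}:therapy" for c in contrast_names],
        "age:therapy",
    )
    return x_mat, names, age_center


@dataclass
class TermEstimate:
    """One fixed-effect coefficient of a fitted model."""

    term: str
    estimate: float = float("nan")
    se: float = float("nan")
    stat: float = float("nan")
    p: float = float("nan")
    significant: bool = False
    estimable: bool = True


@dataclass
class ModelResult:
    """Per-outcome mixed-model fit in the main-effects/interactions layout.

    ``terms`` always contains the full 10-term set; coefficients that the
    realized design cannot identify (e.g. a group × therapy interaction
    when therapy is constant within that group) are present but flagged
    not-estimable.
    """

    outcome: str
    terms: list[TermEstimate]
    random_intercept_var: float
    residual_var: float
    converged: bool
    singular: bool
    n_obs: int
    n_subjects: int
    reference: str
    age_center: float
    alpha: float
    method: str = "REML, Wald z"
    log_likelihood: float = float("nan")
    fitted_values: np.ndarray | None = None

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"outcome": self.outcome, "term": t.term,
             "estimate": t.estimate, "se": t.se, "stat": t.stat,
             "p": t.p, "significant": t.significant,
             "estimable": t.estimable}
            for t in self.terms
        ])


def fit_lmm(
    data: pd.DataFrame,
    outcome: str,
    *,
    reference: str = "dystonia",
    alpha: float = 0.05,
    age_center: float | None = None,
) -> ModelResult:
    """Fit the per-outcome linear mixed model with a subject random intercept.

    ``data`` needs columns ``subject_id``, ``group``, ``age_years``,
    ``therapy`` and the outcome. REML estimation; Wald z tests per
    coefficient. A singular fit (random-intercept variance at zero) is
    returned with ``singular=True`` and a logged warning, never raised.
    Rank-deficient columns are dropped from the fit and reported as
    not-estimable, keeping the 10-term structure intact.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = data.reset_index(drop=True)
    y = df[outcome].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError(
            f"outcome {outcome!r} contains missing or non-finite values")
    x_mat, names, used_center = build_design_matrix(
        df, reference=reference, age_center=age_center)

    # greedy rank filter: keep each column only if it adds rank
    keep: list[int] = []
    for j in range(x_mat.shape[1]):
        cand = keep + [j]
        if np.linalg.matrix_rank(x_mat[:, cand]) == len(cand):
            keep.append(j)
    dropped = [names[j] for j in range(x_mat.shape[1]) if j not in keep]
    if dropped:
        logger.warning(
            "outcome %s: non-identifiable terms dropped: %s",
            outcome, ", ".join(dropped))

    exog = pd.DataFrame(x_mat[:, keep], columns=[names[j] for j in keep])
    model = MixedLM(endog=y, exog=exog, groups=df["subject_id"].to_numpy())
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = model.fit(reml=True)
            converged = bool(getattr(fit, "converged", True))
        except Exception:  # pragma: no cover - last-resort optimizer path
            fit = model.fit(reml=True, method="nm", maxiter=2000)
            converged = bool(getattr(fit, "converged", True))

    re_var = float(np.asarray(fit.cov_re)[0, 0])
    resid_var = float(fit.scale)
    # boundary heuristic: the optimizer rarely pins the variance exactly to
    # zero; a ratio below 1% of the residual variance is treated as singular
    singular = re_var <= 1e-2 * max(resid_var, 1e-300)
    if singular:
        logger.warning(
            "outcome %s: singular fit (random-intercept variance ~ 0)",
            outcome)

    estimates = dict(zip(exog.columns, np.asarray(fit.fe_params, float)))
    ses = dict(zip(exog.columns, np.asarray(fit.bse_fe, float)))
    pvals = dict(zip(exog.columns,
                     np.asarray(fit.pvalues, float)[: len(exog.columns)]))
    terms = []
    for name in names:
        if name in estimates:
            est, se, p = estimates[name], ses[name], pvals[name]
            stat = est / se if se > 0 else float("nan")
            terms.append(TermEstimate(
                term=name, estimate=est, se=se, stat=stat, p=p,
                significant=bool(np.isfinite(p) and p < alpha),
                estimable=True))
        else:
            terms.append(TermEstimate(term=name, estimable=False))

    return ModelResult(
        outcome=outcome,
        terms=terms,
        random_intercept_var=re_var,
        residual_var=resid_var,
        converged=converged,
        singular=singular,
        n_obs=len(df),
        n_subjects=df["subject_id"].nunique(),
        reference=reference,
        age_center=used_center,
        alpha=alpha,
        log_likelihood=float(fit.llf),
        fitted_values=np.asarray(fit.fittedvalues, float),
    )


@dataclass
class AnalysisResults:
    """Per-outcome model fits, outlier reports and run statuses."""

    results: dict[str, ModelResult]
    outliers: dict[str, OutlierReport]
    statuses: dict[str, str]
    alpha: float = 0.05

    def main_effects(self) -> pd.DataFrame:
        """Main-effects report: group contrasts, age and therapy."""
        return self._report(MAIN_TERMS)

    def interactions(self) -> pd.DataFrame:
        """Interactions report: group × age, group × therapy, age × therapy."""
        return self._report(INTERACTION_TERMS)

    def _report(self, layout: Sequence[str]) -> pd.DataFrame:
        rows = []
        for outcome, result in self.results.items():
            frame = result.to_frame()
            rows.append(frame[frame["term"].isin(layout)])
        if not rows:
            return pd.DataFrame(
                columns=["outcome", "term", "estimate", "se", "stat", "p",
                         "significant", "estimable"])
        return pd.concat(rows, ignore_index=True)

    def outlier_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"outcome": name, "n_flagged": rep.n_flagged,
             "flagged_rows": ";".join(map(str, rep.flagged)),
             "threshold": rep.threshold, "alpha_q": rep.alpha_q,
             "scale_method": rep.scale_method}
            for name, rep in self.outliers.items()
        ])


def _validate_cohort_table(table: pd.DataFrame, outcomes: Sequence[str]):
    required = {"subject_id", "group", "age_years", "therapy"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if table["group"].nunique() < 2:
        raise ValueError("cohort table must contain at least 2 groups")
    meta = table.groupby("subject_id")[["group", "age_years", "therapy"]]
    if (meta.nunique() > 1).to_numpy().any():
        raise ValueError(
            "group, age and therapy must be constant within subject")
    for outcome in outcomes:
        if outcome not in table.columns:
            raise ValueError(f"outcome column {outcome!r} missing")
        if table[outcome].isna().any():
            raise ValueError(f"outcome {outcome!r} has missing values")


def _screen_within_groups(
    values: np.ndarray, groups: np.ndarray, alpha_q: float, outcome: str
) -> OutlierReport:
    """Univariate robust screen applied within each group's observations.

    The robust distance is group-referenced (each observation compared to
    its own group's median and MAD), so well-separated group means are not
    themselves mistaken for outliers.
    """
    d_sq = np.zeros(len(values))
    threshold = float(stats.chi2.ppf(alpha_q, df=1))
    methods = set()
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < 5:
            # too few observations for a robust scale; leave unflagged
            logger.warning(
                "%s: group %s has %d < 5 observations, not screened",
                outcome, g, mask.sum())
            methods.add("unscreened")
            continue
        rep = mahalanobis_screen(values[mask], alpha_q, f"{outcome}[{g}]")
        d_sq[mask] = rep.distances_sq
        methods.add(rep.scale_method)
    flagged = np.flatnonzero(d_sq > threshold)
    method = "mad" if methods == {"mad"} else "+".join(sorted(methods))
    return OutlierReport(
        outcome=outcome, flagged=flagged, distances_sq=d_sq,
        threshold=threshold, alpha_q=alpha_q,
        scale_method=f"within_group:{method}")


def analyze_all(
    table: pd.DataFrame,
    *,
    outcomes: Sequence[str] | None = None,
    alpha_q: float = 0.975,
    alpha: float = 0.05,
    reference: str = "dystonia",
    screen: str = "univariate",
) -> AnalysisResults:
    """Screen and model every outcome; never abort on a single failure.

    For each outcome the screen is applied to that outcome's observations
    only, the flagged trials are excluded from that outcome's model data
    alone, and the mixed model is fitted on the remainder. The default
    ``'univariate'`` screen references each observation to its own group's
    robust location and scale (a pooled screen on group-separated data
    would flag entire groups; group-referenced screening yields the few
    isolated exclusions per outcome the method expects). ``'pooled'``
    ignores group structure; ``'bivariate_age'`` uses the classical
    (outcome, age) variant. Failures are recorded per outcome in
    ``statuses``.
    """
    outcomes = tuple(outcomes) if outcomes is not None else FEATURE_NAMES
    _validate_cohort_table(table, outcomes)
    if screen not in ("univariate", "pooled", "bivariate_age"):
        raise ValueError(
            "screen must be 'univariate', 'pooled' or 'bivariate_age'")
    # one centering convention across outcomes: the full-cohort mean age
    age_center = float(table["age_years"].mean())

    results: dict[str, ModelResult] = {}
    reports: dict[str, OutlierReport] = {}
    statuses: dict[str, str] = {}
    for outcome in outcomes:
        try:
            if screen == "univariate":
                report = _screen_within_groups(
                    table[outcome].to_numpy(float),
                    table["group"].to_numpy(str), alpha_q, outcome)
            elif screen == "pooled":
                report = mahalanobis_screen(
                    table[outcome].to_numpy(float), alpha_q, outcome)
            else:
                report = mahalanobis_screen_bivariate(
                    table[outcome].to_numpy(float),
                    table["age_years"].to_numpy(float), alpha_q, outcome)
            reports[outcome] = report
            kept = table.drop(table.index[report.flagged])
            results[outcome] = fit_lmm(
                kept, outcome, reference=reference, alpha=alpha,
                age_center=age_center)
            statuses[outcome] = "ok"
        except Exception as exc:  # record and continue with other outcomes
            statuses[outcome] = f"failed: {exc}"
            logger.error("outcome %s failed: %s", outcome, exc)
    return AnalysisResults(
        results=results, outliers=reports, statuses=statuses, alpha=alpha)
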
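"""Stage-wise association statistics.

* repeated-measures correlation (ANCOVA formulation: common within-subject
  slope after removing subject means), with a subject-level bootstrap CI;
* Pearson correlation with the t-transform p-value;
* random-intercept linear mixed models over task stages (ML), with estimated
  marginal means, Tukey-adjusted pairwise stage contrasts and Johnson-Neyman
  regions of significance for stage × moderator interactions;
* Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
import statsmodels.formula.api as smf


class StatsError(ValueError):
    pass


# --------------------------------------------------------------------------
# repeated-measures correlation
# --------------------------------------------------------------------------

@dataclass
class RmCorrResult:
    r: float
    df: int
    p: float
    ci: tuple[float, float] = (float("nan"), float("nan"))
    n_subjects: int = 0
    n_observations: int = 0


def _rmcorr_core(subjects: np.ndarray, x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """(r_rm, df, p) by the ANCOVA decomposition with subject fixed effects."""
    uniq, inv = np.unique(subjects, return_inverse=True)
    k, n = len(uniq), len(x)
    dummies = np.zeros((n, k))
    dummies[np.arange(n), inv] = 1.0
    full = np.column_stack([dummies, x])
    beta_full, *_ = np.linalg.lstsq(full, y, rcond=None)
    sse_full = float(np.sum((y - full @ beta_full) ** 2))
    beta_red, *_ = np.linalg.lstsq(dummies, y, rcond=None)
    sse_red = float(np.sum((y - dummies @ beta_red) ** 2))
    ss_x = max(sse_red - sse_full, 0.0)
    df = n - k - 1
    if df <= 0:
        raise StatsError("not enough observations for rmcorr")
    total = ss_x + sse_full
    if total == 0:
        raise StatsError("zero within-subject variance")
    r = float(np.sign(beta_full[-1]) * np.sqrt(ss_x / total))
    if sse_full == 0:
        return r, df, 0.0
    f_stat = ss_x / (sse_full / df)
    return r, df, float(stats.f.sf(f_stat, 1, df))


def _clean_rm_table(
    table: pd.DataFrame, x: str, y: str, subject: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    data = table[[subject, x, y]].dropna()
    counts = data.groupby(subject).size()
    bad = counts.index[counts < 2]
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} subject(s) with fewer than 2 complete pairs", stacklevel=3
        )
        data = data[~data[subject].isin(bad)]
    if data[subject].nunique() < 2:
        raise StatsError("rmcorr needs at least 2 subjects with 2 complete pairs")
    return (
        data[subject].to_numpy(),
        data[x].to_numpy(float),
        data[y].to_numpy(float),
    )


def rmcorr(table: pd.DataFrame, x: str, y: str, subject: str = "subject") -> RmCorrResult:
    """Common within-subject correlation across stages (subject means removed).

    The p-value comes from the F test of the common slope; the sign from the
    slope itself.  df = n_observations − n_subjects − 1.
    """
    subjects, xv, yv = _clean_rm_table(table, x, y, subject)
    r, df, p = _rmcorr_core(subjects, xv, yv)
    return RmCorrResult(
        r=r, df=df, p=p, n_subjects=len(np.unique(subjects)), n_observations=len(xv)
    )


def rmcorr_bootstrap(
    table: pd.DataFrame,
    x: str,
    y: str,
    subject: str = "subject",
    n_boot: int = 5000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, float]:
    """Percentile CI of r_rm, resampling subjects with replacement."""
    subjects, xv, yv = _clean_rm_table(table, x, y, subject)
    uniq = np.unique(subjects)
    by_subject = {s: (xv[subjects == s], yv[subjects == s]) for s in uniq}
    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    i = 0
    guard = 0
    while i < n_boot:
        draw = rng.choice(uniq, size=len(uniq), replace=True)
        if len(set(draw)) < 2:
            guard += 1
            if guard > 100 * n_boot:
                raise StatsError("bootstrap cannot draw 2 distinct subjects")
            continue  # degenerate resample: redraw
        xs, ys, labels = [], [], []
        for j, s in enumerate(draw):
            sx, sy = by_subject[s]
            xs.append(sx)
            ys.append(sy)
            labels.append(np.full(len(sx), j))
        try:
            values[i], _, _ = _rmcorr_core(
                np.concatenate(labels), np.concatenate(xs), np.concatenate(ys)
            )
        except StatsError:
            guard += 1
            continue
        i += 1
    lo, hi = np.percentile(values, [(1 - ci) / 2 * 100, (1 + ci) / 2 * 100])
    return float(lo), float(hi)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation and its two-sided t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise StatsError("pearson needs at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# linear mixed models over stages
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LmmSpec:
    """Random-intercept model: outcome ~ predictor [*] stage + (1 | subject)."""

    outcome: str
    predictor: str | None = None
    stage: str | None = "stage"
    interaction: bool = False
    subject: str = "subject"
    reference: str | None = "baseline"

    def formula(self, data: pd.DataFrame) -> str:
        terms = []
        stage_term = None
        if self.stage is not None:
            if self.reference is not None and self.reference in set(data[self.stage]):
                stage_term = f"C({self.stage}, Treatment(reference='{self.reference}'))"
            else:
                stage_term = f"C({self.stage})"
        if self.predictor and stage_term:
            terms.append(f"{self.predictor} * {stage_term}" if self.interaction else f"{self.predictor} + {stage_term}")
        elif self.predictor:
            terms.append(self.predictor)
        elif stage_term:
            terms.append(stage_term)
        else:
            terms.append("1")
        return f"{self.outcome} ~ {' + '.join(terms)}"


@dataclass
class LmmResult:
    params: pd.Series
    se: pd.Series
    df: float
    p: pd.Series
    cov: pd.DataFrame
    spec: LmmSpec
    data: pd.DataFrame
    fit: object
    converged: bool = True

    def stage_param(self, level: str, interaction: bool = False) -> str:
        """Name of the treatment-coded parameter for a stage level."""
        for name in self.params.index:
            if f"[T.{level}]" in name and ((":" in name) == interaction):
                return name
        raise StatsError(f"no {'interaction' if interaction else 'main'} term for level {level!r}")


def stage_lmm(data: pd.DataFrame, spec: LmmSpec) -> LmmResult:
    """ML-fitted random-intercept model with treatment-coded stages.

    The residual degrees of freedom are approximated as
    n_obs − rank(X) − (n_groups − 1); statsmodels performs the numerical
    optimization, this module owns model construction, coding and
    post-processing.  A singular random-intercept fit triggers a warning and
    an OLS refit (zero intercept variance).
    """
    data = data.dropna(subset=[c for c in (spec.outcome, spec.predictor, spec.stage, spec.subject) if c])
    formula = spec.formula(data)
    fit = None
    converged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups=data[spec.subject])
            fit = model.fit(reml=False)
        converged = bool(getattr(fit, "converged", True))
    except (np.linalg.LinAlgError, ValueError):
        pass
    if fit is not None and converged:
        fe = fit.fe_params
        cov = fit.cov_params().loc[fe.index, fe.index]
        se = pd.Series(np.sqrt(np.diag(cov)), index=fe.index)
        converged = bool(np.all(np.isfinite(se)))
    if fit is None or not converged:
        warnings.warn("singular mixed-model fit; falling back to OLS", stacklevel=2)
        ols = smf.ols(formula, data).fit()
        fe = ols.params
        cov = ols.cov_params()
        se = ols.bse
        df = float(ols.df_resid)
        p = pd.Series(2.0 * stats.t.sf(np.abs(fe / se), df), index=fe.index)
        return LmmResult(params=fe, se=se, df=df, p=p, cov=cov, spec=spec, data=data,
                         fit=ols, converged=False)
    n_obs = len(data)
    rank = np.linalg.matrix_rank(model.exog)
    n_groups = data[spec.subject].nunique()
    df = max(float(n_obs - rank - (n_groups - 1)), 1.0)
    t = fe / se
    p = pd.Series(2.0 * stats.t.sf(np.abs(t), df), index=fe.index)
    return LmmResult(
        params=fe, se=se, df=df, p=p, cov=cov, spec=spec, data=data, fit=fit, converged=True
    )


def marginal_contrasts(result: LmmResult, adjust: str = "tukey") -> pd.DataFrame:
    """All pairwise stage contrasts of estimated marginal means.

    Continuous covariates are held at their sample mean.  Tukey adjustment
    uses the studentized-range distribution with k = number of stage levels.
    """
    spec = result.spec
    if spec.stage is None:
        raise StatsError("model has no stage factor")
    levels = sorted(result.data[spec.stage].unique())
    design_info = result.fit.model.data.design_info
    rows = {}
    for level in levels:
        new = {spec.stage: [level]}
        if spec.predictor:
            new[spec.predictor] = [float(result.data[spec.predictor].mean())]
        (mat,) = build_design_matrices([design_info], pd.DataFrame(new))
        rows[level] = np.asarray(mat)[0]
    k = len(levels)
    cov = result.cov.to_numpy()
    beta = result.params.to_numpy()
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            c = rows[levels[i]] - rows[levels[j]]
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            t = est / se if se > 0 else 0.0
            p_raw = float(2.0 * stats.t.sf(abs(t), result.df))
            if adjust == "tukey":
                q = abs(t) * np.sqrt(2.0)
                p_adj = float(np.clip(stats.studentized_range.sf(q, k, result.df), 0.0, 1.0))
            elif adjust == "none":
                p_adj = p_raw
            else:
                raise StatsError(f"unknown adjustment {adjust!r}")
            out.append(
                {
                    "stage_a": levels[i],
                    "stage_b": levels[j],
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p_raw": p_raw,
                    "p_adj": p_adj,
                }
            )
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# Johnson-Neyman region of significance
# --------------------------------------------------------------------------

@dataclass
class RegionOfSignificance:
    moderator: str
    stage_a: str
    stage_b: str
    boundaries: tuple[float, ...]
    significant: str  # e.g. "below 0.27", "above 0.25", "nowhere", "everywhere"
    alpha: float = 0.05


def _pair_contrast(result: LmmResult, stage_a: str, stage_b: str, moderator_value: float) -> np.ndarray:
    """Contrast vector for the (a − b) stage difference at a moderator value."""
    c = np.zeros(len(result.params))
    names = list(result.params.index)
    ref_levels = {stage_a, stage_b}
    for level, sign in ((stage_a, 1.0), (stage_b, -1.0)):
        try:
            c[names.index(result.stage_param(level))] += sign
            c[names.index(result.stage_param(level, interaction=True))] += sign * moderator_value
        except StatsError:
            pass  # the reference level contributes zero
    if not c.any():
        raise StatsError(f"stages {ref_levels} not found in model terms")
    return c


def region_of_significance(
    result: LmmResult,
    stage_a: str,
    stage_b: str,
    alpha: float = 0.05,
    moderator_range: tuple[float, float] | None = None,
) -> RegionOfSignificance:
    """Johnson-Neyman boundaries of the conditional stage difference.

    Solves |t(f)| = t_crit analytically (quadratic in the moderator f) for the
    model's stage × moderator interaction; boundaries outside the observed
    moderator range are dropped, and the significant side is labelled from
    pointwise tests.
    """
    spec = result.spec
    if not spec.interaction or spec.predictor is None:
        raise StatsError("region of significance requires a stage x moderator interaction")
    moderator = spec.predictor
    values = result.data[moderator].to_numpy(float)
    lo, hi = moderator_range if moderator_range else (float(values.min()), float(values.max()))
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, result.df)

    beta = result.params.to_numpy()
    cov = result.cov.to_numpy()
    c0 = _pair_contrast(result, stage_a, stage_b, 0.0)
    c1 = _pair_contrast(result, stage_a, stage_b, 1.0) - c0  # moderator-slope part
    b0, b1 = float(c0 @ beta), float(c1 @ beta)
    v00 = float(c0 @ cov @ c0)
    v01 = float(c0 @ cov @ c1)
    v11 = float(c1 @ cov @ c1)
    t2 = t_crit**2
    # (b0 + b1 f)^2 = t^2 (v00 + 2 v01 f + v11 f^2)
    qa = b1**2 - t2 * v11
    qb = 2.0 * (b0 * b1 - t2 * v01)
    qc = b0**2 - t2 * v00
    roots: list[float] = []
    if abs(qa) < 1e-300:
        if qb != 0:
            roots = [-qc / qb]
    else:
        disc = qb**2 - 4 * qa * qc
        if disc >= 0:
            roots = [(-qb - np.sqrt(disc)) / (2 * qa), (-qb + np.sqrt(disc)) / (2 * qa)]
    boundaries = tuple(sorted(r for r in roots if lo <= r <= hi))

    def significant_at(f: float) -> bool:
        est = b0 + b1 * f
        se = np.sqrt(v00 + 2 * v01 * f + v11 * f**2)
        return bool(abs(est / se) > t_crit) if se > 0 else False

    if not boundaries:
        label = "everywhere" if significant_at((lo + hi) / 2.0) else "nowhere"
    elif len(boundaries) == 1:
        b = boundaries[0]
        label = f"below {b:.4g}" if significant_at((lo + b) / 2.0) else f"above {b:.4g}"
    else:
        inside = significant_at(float(np.mean(boundaries)))
        label = "between boundaries" if inside else "outside boundaries"
    return RegionOfSignificance(
        moderator=moderator,
        stage_a=stage_a,
        stage_b=stage_b,
        boundaries=boundaries,
        significant=label,
        alpha=alpha,
    )


# --------------------------------------------------------------------------
# multiple comparisons
# --------------------------------------------------------------------------

def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
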
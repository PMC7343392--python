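"""Recognition/recollection scoring, SDT indices, bias correction.

Under the equal-variance Gaussian signal-detection model,

    d' = z(H) - z(F),    c = -(z(H) + z(F)) / 2,    beta = exp(d' * c),

with H and F first pulled off the 0/1 boundaries by the 1/(2N) rule (or a
log-linear correction).  The likelihood-ratio bias beta is then regressed out
of the per-subject recollection rates (ordinary least squares across
subjects, separately per valence); residuals are re-centered at the sample
mean so corrected rates stay on the percentage scale.  The adjusted emotional
memory score is E / (E + N) of the two corrected rates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from lcmem.config import VALENCES


class BehaviorError(ValueError):
    pass


def tabulate_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Exact integer recognition/recollection counts per subject × valence.

    Raises on trials carrying a recollection response without an endorsement
    (or on a new face), and on subjects lacking old or new trials of a
    valence.
    """
    bad = trials[(trials["recollected"].notna()) & (~trials["recognized"].astype(bool))]
    if len(bad):
        raise BehaviorError("trial with recollection response but no endorsement")
    bad = trials[(trials["recollected"].notna()) & (~trials["is_old"].astype(bool))]
    if len(bad):
        raise BehaviorError("recollection scored on a new face")
    rows = []
    for (subject, valence), g in trials.groupby(["subject", "valence"]):
        old = g[g["is_old"].astype(bool)]
        new = g[~g["is_old"].astype(bool)]
        if len(old) == 0 or len(new) == 0:
            raise BehaviorError(f"subject {subject}: no {'old' if len(old) == 0 else 'new'} "
                                f"{valence} trials")
        hits = int(old["recognized"].sum())
        fa = int(new["recognized"].sum())
        rows.append(
            {
                "subject": subject,
                "valence": valence,
                "hits": hits,
                "misses": len(old) - hits,
                "false_alarms": fa,
                "correct_rejections": len(new) - fa,
                "n_old": len(old),
                "n_new": len(new),
                "recollected_correct": int((old["recollected"] == 1.0).sum()),
            }
        )
    return pd.DataFrame(rows)


def _corrected_rate(k: int, n: int, method: str) -> float:
    if method == "ratio":
        # 1/(2N) boundary rule; interior proportions pass through unchanged
        rate = k / n
        return min(max(rate, 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))
    if method == "loglinear":
        return (k + 0.5) / (n + 1.0)
    raise BehaviorError(f"unknown ceiling correction {method!r}")


def sdt_indices(counts: pd.DataFrame, correction: str = "ratio") -> pd.DataFrame:
    """d', criterion c and likelihood-ratio beta per subject × valence.

    ``correction`` selects the extreme-rate fix: ``"ratio"`` (1/(2N), default)
    or ``"loglinear"`` (+0.5/+1).
    """
    out = counts.copy()
    hr = np.array(
        [_corrected_rate(h, n, correction) for h, n in zip(counts["hits"], counts["n_old"])]
    )
    fr = np.array(
        [
            _corrected_rate(f, n, correction)
            for f, n in zip(counts["false_alarms"], counts["n_new"])
        ]
    )
    zh, zf = stats.norm.ppf(hr), stats.norm.ppf(fr)
    out["hit_rate"] = hr
    out["fa_rate"] = fr
    out["d_prime"] = zh - zf
    out["criterion_c"] = -(zh + zf) / 2.0
    out["beta"] = np.exp(out["d_prime"] * out["criterion_c"])
    return out


def bias_residualize(scores: pd.Series, bias: pd.Series) -> pd.Series:
    """Regress response bias out of recollection rates across subjects.

    Returns OLS residuals plus the sample mean of ``scores`` (index-aligned),
    keeping corrected rates on the original scale.  With fewer than three
    paired subjects, or zero bias variance, the input is returned unchanged
    with a warning (no slope is identifiable).
    """
    joined = pd.concat({"score": scores, "bias": bias}, axis=1).dropna()
    if len(joined) < 3:
        raise BehaviorError("bias residualization needs at least 3 subjects")
    x = joined["bias"].to_numpy(float)
    y = joined["score"].to_numpy(float)
    if np.ptp(x) == 0:
        warnings.warn("bias has zero variance; returning scores unchanged", stacklevel=2)
        return scores.copy()
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    return pd.Series(residuals + y.mean(), index=joined.index)


def adjusted_emotional_score(corrected_emotional: float, corrected_neutral: float) -> float:
    """Adjusted emotional memory performance score E / (E + N); NaN if E + N <= 0."""
    total = corrected_emotional + corrected_neutral
    if not np.isfinite(total) or total <= 0:
        return float("nan")
    return float(corrected_emotional / total)


def paired_compare(
    values_a: np.ndarray,
    values_b: np.ndarray,
    method: str = "wilcoxon",
    continuity: bool = True,
) -> tuple[float, float]:
    """Two-sided paired comparison: Wilcoxon signed-rank Z or paired t.

    The Wilcoxon statistic is the normal approximation
    Z = (W+ - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 - sum(t^3 - t)/48), with zero
    differences dropped and an optional 0.5 continuity correction.  Positive Z
    means A tends to exceed B.  All-zero differences return (0, 1).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise BehaviorError("paired samples must have equal length")
    d = a - b
    d = d[~np.isnan(d)]
    if method == "t":
        if np.allclose(d, 0):
            return 0.0, 1.0
        res = stats.ttest_rel(a[~np.isnan(a - b)], b[~np.isnan(a - b)])
        return float(res.statistic), float(res.pvalue)
    if method != "wilcoxon":
        raise BehaviorError(f"unknown method {method!r}")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    if n < 5:
        warnings.warn("fewer than 5 non-zero pairs; normal approximation is crude", stacklevel=2)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return 0.0, 1.0
    num = w_plus - mu
    if continuity and num != 0:
        num -= 0.5 * np.sign(num)
    z = num / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


# --------------------------------------------------------------------------
# per-subject score table and Table-1-style summary
# --------------------------------------------------------------------------

def memory_scores(trials: pd.DataFrame, correction: str = "ratio") -> pd.DataFrame:
    """One row per subject: rates, SDT indices, corrected rates, adjusted score.

    Rates are expressed in percent.  ``recollection_raw`` is correct names /
    all old faces; ``recollection_of_recognized`` is correct names / correctly
    recognized old faces.  Bias-corrected rates are the OLS residuals of the
    raw recollection rate on beta (per valence), re-centered at the mean.
    """
    counts = sdt_indices(tabulate_counts(trials), correction=correction)
    counts = counts.set_index(["subject", "valence"])
    subjects = sorted({s for s, _ in counts.index})
    wide: dict[str, pd.Series] = {}
    for valence in VALENCES:
        sub = counts.xs(valence, level="valence")
        prefix = valence[0]
        wide[f"hit_rate_{prefix}"] = sub["hits"] / sub["n_old"] * 100.0
        wide[f"fa_rate_{prefix}"] = sub["false_alarms"] / sub["n_new"] * 100.0
        wide[f"recollection_raw_{prefix}"] = sub["recollected_correct"] / sub["n_old"] * 100.0
        with np.errstate(invalid="ignore", divide="ignore"):
            wide[f"recollection_of_recognized_{prefix}"] = (
                sub["recollected_correct"] / sub["hits"] * 100.0
            )
        for col in ("d_prime", "criterion_c", "beta"):
            wide[f"{col}_{prefix}"] = sub[col]
    table = pd.DataFrame(wide, index=pd.Index(subjects, name="subject"))
    for valence in VALENCES:
        prefix = valence[0]
        table[f"recollection_corrected_{prefix}"] = bias_residualize(
            table[f"recollection_raw_{prefix}"], table[f"beta_{prefix}"]
        )
    table["adjusted_emotional_score"] = [
        adjusted_emotional_score(e, n)
        for e, n in zip(table["recollection_corrected_e"], table["recollection_corrected_n"])
    ]
    return table.reset_index()


_SUMMARY_ROWS = [
    ("Recognition Hit Rate (Old faces)", "hit_rate", "wilcoxon"),
    ("Recognition False Alarm Rate (New faces)", "fa_rate", "wilcoxon"),
    ("Recognition Response Bias", "beta", "t"),
    ("Recollection Hit Rate Raw", "recollection_raw", "wilcoxon"),
    ("Recollection Hit Rate (correct recognition)", "recollection_of_recognized", "wilcoxon"),
    ("Bias-corrected Recollection Hit Rate", "recollection_corrected", "wilcoxon"),
]


def summarize_behavior(scores: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR) per valence plus the paired emotional-vs-neutral test per row."""
    rows = []
    for label, stem, method in _SUMMARY_ROWS:
        e = scores[f"{stem}_e"].to_numpy(float)
        n = scores[f"{stem}_n"].to_numpy(float)
        statistic, p = paired_compare(e, n, method=method)
        rows.append(
            {
                "measure": label,
                "emotional_median": float(np.nanmedian(e)),
                "emotional_iqr_low": float(np.nanpercentile(e, 25)),
                "emotional_iqr_high": float(np.nanpercentile(e, 75)),
                "neutral_median": float(np.nanmedian(n)),
                "neutral_iqr_low": float(np.nanpercentile(n, 25)),
                "neutral_iqr_high": float(np.nanpercentile(n, 75)),
                "statistic": statistic,
                "p_value": p,
                "test": "paired t" if method == "t" else "Wilcoxon signed-rank Z",
            }
        )
    return pd.DataFrame(rows)
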
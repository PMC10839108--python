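"""Sequential two-way variance partitioning and companion statistics.

The model is fixed-effects with terms entered in the order
batch -> farm -> batch:farm; sums of squares are sequential (Type I), so
each term is adjusted only for the terms before it. With mildly unbalanced
cells the order matters and is therefore part of the contract. Effect sizes
are eta-squared = SS_term / SS_total, reported for every term including the
residuals so they sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from cortivar.cohort import BatchSummary, Cohort

__all__ = [
    "AnovaDecomposition",
    "AnovaTerm",
    "PairwiseComparison",
    "DegenerateDataError",
    "fit_two_way_anova",
    "residual_diagnostics",
    "tukey_batch_comparisons",
    "cohens_d_combined",
    "mean_sd_regression",
]

TERM_ORDER = ("batch", "farm", "batch:farm", "residuals")


class DegenerateDataError(ValueError):
    """The data admit no meaningful decomposition (zero variance, missing cells)."""


@dataclass(frozen=True)
class AnovaTerm:
    name: str
    sum_of_squares: float
    df: int
    mean_square: float
    F: float | None
    p: float | None
    eta_squared: float


@dataclass
class AnovaDecomposition:
    """Sequential decomposition of the total sum of squares.

    ``terms`` is ordered batch, farm, batch:farm, residuals; ``residuals``
    holds the observation-level residuals from the full cell-means model, in
    cohort row order.
    """

    terms: list[AnovaTerm]
    ss_total: float
    n_obs: int
    residuals: np.ndarray
    cell_index: np.ndarray  # integer cell id per observation, for Levene

    def term(self, name: str) -> AnovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def eta_squared(self) -> dict[str, float]:
        return {t.name: t.eta_squared for t in self.terms}


def _design_dummies(labels: np.ndarray) -> np.ndarray:
    """Full-rank treatment-coded dummies (first level dropped)."""
    levels = np.unique(labels)
    return (labels[:, None] == levels[None, 1:]).astype(float)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def fit_two_way_anova(cohort: Cohort) -> AnovaDecomposition:
    """Fit hcc ~ batch + farm + batch:farm with sequential (Type I) SS.

    Raises
    ------
    DegenerateDataError
        If the total SS is zero (all observations equal) or a farm is
        observed in only one batch (rank-deficient interaction).
    """
    farms = np.asarray([r.farm_id for r in cohort.records])
    batches = np.asarray([r.batch_id for r in cohort.records])
    y = cohort.hcc

    if len(cohort.farm_ids) < 2 or len(cohort.batch_ids) < 2:
        raise DegenerateDataError("need at least 2 farms and 2 batches")
    for farm in cohort.farm_ids:
        present = set(batches[farms == farm])
        absent = set(cohort.batch_ids) - present
        if absent:
            raise DegenerateDataError(
                f"farm {farm!r} has no observations in batch(es) {sorted(absent)}"
            )

    n = len(y)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total <= 0:
        raise DegenerateDataError("zero total variance: all observations are equal")

    ones = np.ones((n, 1))
    Xb = np.hstack([ones, _design_dummies(batches)])
    Xbf = np.hstack([Xb, _design_dummies(farms)])

    # full model == cell means; its RSS is the pooled within-cell SS
    cells = np.asarray([f"{f}\x00{b}" for f, b in zip(farms, batches)])
    cell_levels, cell_idx = np.unique(cells, return_inverse=True)
    cell_means = np.bincount(cell_idx, weights=y) / np.bincount(cell_idx)
    fitted = cell_means[cell_idx]
    residuals = y - fitted

    rss0 = ss_total
    rss_b = _rss(y, Xb)
    rss_bf = _rss(y, Xbf)
    rss_full = float(residuals @ residuals)

    n_b, n_f, n_cells = len(cohort.batch_ids), len(cohort.farm_ids), len(cell_levels)
    ss = {
        "batch": rss0 - rss_b,
        "farm": rss_b - rss_bf,
        "batch:farm": rss_bf - rss_full,
        "residuals": rss_full,
    }
    df = {
        "batch": n_b - 1,
        "farm": n_f - 1,
        "batch:farm": n_cells - n_b - n_f + 1,
        "residuals": n - n_cells,
    }
    if df["residuals"] <= 0:
        raise DegenerateDataError("no residual degrees of freedom")

    mse = ss["residuals"] / df["residuals"]
    terms = []
    for name in TERM_ORDER:
        ms = ss[name] / df[name] if df[name] > 0 else float("nan")
        if name == "residuals" or mse <= 0:
            F = p = None
        else:
            F = ms / mse
            p = float(stats.f.sf(F, df[name], df["residuals"]))
        terms.append(
            AnovaTerm(
                name=name,
                sum_of_squares=ss[name],
                df=df[name],
                mean_square=ms,
                F=F,
                p=p,
                eta_squared=ss[name] / ss_total,
            )
        )
    return AnovaDecomposition(
        terms=terms, ss_total=ss_total, n_obs=n, residuals=residuals, cell_index=cell_idx
    )


def residual_diagnostics(
    decomposition: AnovaDecomposition, *, levene_center: str = "median"
) -> dict:
    """Shapiro-Wilk normality and Levene homoscedasticity checks on residuals.

    Diagnostics inform only; no refusal is triggered. Returns a dict with
    ``shapiro`` (statistic, p), ``levene`` (statistic, p, center), ``qq``
    (theoretical and ordered sample quantiles for plotting) and ``flags``.
    """
    resid = decomposition.residuals
    report: dict = {"flags": []}

    if len(resid) >= 3:
        if len(resid) > 5000:
            report["flags"].append("shapiro computed on n > 5000; p approximate")
        stat, p = stats.shapiro(resid)
        report["shapiro"] = {"statistic": float(stat), "p": float(p)}
        if p < 0.05:
            report["flags"].append("residual normality rejected at 0.05")
    else:
        report["shapiro"] = None
        report["flags"].append("normality test unavailable: n < 3")

    groups = [resid[decomposition.cell_index == k] for k in np.unique(decomposition.cell_index)]
    if levene_center not in ("median", "mean"):
        raise ValueError("levene_center must be 'median' or 'mean'")
    if all(np.ptp(g) == 0 for g in groups):
        stat, p = 0.0, 1.0  # no dispersion anywhere: nothing to test
    else:
        stat, p = stats.levene(*groups, center=levene_center)
    report["levene"] = {"statistic": float(stat), "p": float(p), "center": levene_center}
    if p < 0.05:
        report["flags"].append("homoscedasticity rejected at 0.05")

    (osm, osr), _ = stats.probplot(resid, dist="norm")
    report["qq"] = {"theoretical": osm.tolist(), "sample": osr.tolist()}
    return report


@dataclass(frozen=True)
class PairwiseComparison:
    """One within-farm batch contrast under the Tukey-Kramer adjustment."""

    farm_id: str
    batch_pair: tuple[str, str]
    mean_diff: float
    adjusted_p: float
    cohens_d_abs: float
    significant: bool


def tukey_batch_comparisons(
    cohort: Cohort, *, family: str = "all_cells", alpha: float = 0.05
) -> list[PairwiseComparison]:
    """Tukey-Kramer comparisons of the two batch means within each farm.

    The studentized-range adjustment uses the residual mean square of the
    two-way fit and unequal cell sizes. ``family`` controls the comparison
    family: ``"all_cells"`` treats all (farm, batch) cell means as the
    family (k = number of cells); ``"within_farm"`` adjusts each farm's
    contrast in isolation (k = number of batches, equivalent for 2 batches
    to an unadjusted t test via q = t * sqrt(2)).
    """
    if family not in ("all_cells", "within_farm"):
        raise ValueError("family must be 'all_cells' or 'within_farm'")
    if len(cohort.batch_ids) != 2:
        raise ValueError("batch comparisons require exactly 2 batches per farm")
    decomp = fit_two_way_anova(cohort)
    mse = decomp.term("residuals").mean_square
    df_resid = decomp.term("residuals").df
    cells = {k: v for k, v in cohort.cell_values().items()}
    k = len(cells) if family == "all_cells" else len(cohort.batch_ids)

    out: list[PairwiseComparison] = []
    for farm in cohort.farm_ids:
        per_batch = {b: cells[(farm, b)] for b in cohort.batch_ids}
        b1, b2 = cohort.batch_ids[0], cohort.batch_ids[1]
        x1, x2 = per_batch[b1], per_batch[b2]
        diff = float(np.mean(x1) - np.mean(x2))
        se = np.sqrt(mse / 2.0 * (1.0 / len(x1) + 1.0 / len(x2)))
        if se == 0:
            p = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_resid))
        d = cohens_d_combined(
            float(np.mean(x1)), float(np.std(x1, ddof=1)), len(x1),
            float(np.mean(x2)), float(np.std(x2, ddof=1)), len(x2),
        )
        out.append(
            PairwiseComparison(
                farm_id=farm,
                batch_pair=(b1, b2),
                mean_diff=diff,
                adjusted_p=min(1.0, p),
                cohens_d_abs=d,
                significant=p < alpha,
            )
        )
    return out


def cohens_d_combined(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    """Absolute standardized mean difference with a combined-sample denominator.

    The denominator is the SD of the pooled two-group sample reconstructed
    from summary statistics (it includes the between-group spread):

        m  = (n1*m1 + n2*m2) / (n1 + n2)
        s2c = [n1*(s1^2 + (m1-m)^2) + n2*(s2^2 + (m2-m)^2)] / (n1 + n2)
        d  = |m1 - m2| / sqrt(s2c)

    Returns ``inf`` when the means differ but the combined variance is zero.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    m = (n1 * m1 + n2 * m2) / (n1 + n2)
    var_c = (n1 * (s1**2 + (m1 - m) ** 2) + n2 * (s2**2 + (m2 - m) ** 2)) / (n1 + n2)
    diff = abs(m1 - m2)
    if var_c == 0:
        return 0.0 if diff == 0 else float("inf")
    return diff / float(np.sqrt(var_c))


def mean_sd_regression(summaries: list[BatchSummary]) -> dict:
    """Pearson correlation and OLS line of batch SD against batch mean."""
    if len(summaries) < 3:
        raise ValueError("need at least 3 batch summaries")
    means = np.asarray([s.mean for s in summaries])
    sds = np.asarray([s.sd for s in summaries])
    if np.ptp(means) == 0:
        raise DegenerateDataError("zero variance in batch means: correlation undefined")
    res = stats.linregress(means, sds)
    return {
        "pearson_r": float(res.rvalue),
        "p": float(res.pvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "n": len(summaries),
    }
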
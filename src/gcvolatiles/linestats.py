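"""Per-peak screen for heritable variation among isofemale lines.

For each peak of a dataset, peak areas are rank-normalised to a standard
normal (ordered-quantile / OrderNorm transform), a one-way fixed-effects
linear model with line as the factor is fitted, and the F ratio of
between-line to between-replicate variation is tested. Replicates span
cages and generations, so a significant line effect in a common-garden
design indicates inherited variation. P values are Benjamini-Hochberg
FDR-adjusted across the peaks of the dataset; significant peaks get
per-line estimated marginal means with confidence limits (back-
transformed to the area scale for display) and compact-letter-display
groupings from pairwise contrasts. A Spearman screen over per-line mean
areas summarises the correlation structure among significant peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .peak_io import PeakTable
from .classify import inclusion_filter

logger = logging.getLogger(__name__)


class OrderNorm(TransformerMixin, BaseEstimator):
    """Ordered-quantile normalisation to a standard normal.

    Training values are mapped to normal quantiles of the plotting
    positions p = (rank - 0.5)/n, with average ranks for ties, giving
    scores with zero mean and (up to the n/(n-1) sample correction) unit
    variance. New values are transformed by monotone linear
    interpolation of the fitted value->score map and the inverse by
    interpolation of the reverse map, both clamped at the extremes.
    Operates on a single variable (1-d array).
    """

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float).reshape(-1)
        if values.size < 3 or not np.isfinite(values).all():
            raise ValueError("need at least 3 finite values")
        if np.ptp(values) == 0:
            raise ValueError("constant input: OrderNorm undefined (no variance)")
        ranks = stats.rankdata(values, method="average")
        scores = stats.norm.ppf((ranks - 0.5) / values.size)
        order = np.argsort(values, kind="stable")
        v_sorted, s_sorted = values[order], scores[order]
        uniq_v, idx = np.unique(v_sorted, return_index=True)
        self.values_ = uniq_v
        self.scores_ = s_sorted[idx]  # ties share one score, map stays strictly monotone
        self.n_ = values.size
        return self

    def transform(self, X):
        check_is_fitted(self, "values_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return np.interp(x, self.values_, self.scores_)

    def inverse_transform(self, X):
        check_is_fitted(self, "values_")
        s = np.asarray(X, dtype=float).reshape(-1)
        return np.interp(s, self.scores_, self.values_)


def ordernorm_fit(values) -> OrderNorm:
    return OrderNorm().fit(values)


def ordernorm_transform(mapping: OrderNorm, values):
    return mapping.transform(values)


def ordernorm_inverse(mapping: OrderNorm, scores):
    return mapping.inverse_transform(scores)


@dataclass
class LineModelFit:
    """One-way fixed-effects fit of transformed areas on line."""

    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float
    group_means: pd.Series = dc_field(repr=False, default=None)
    group_sizes: pd.Series = dc_field(repr=False, default=None)
    degenerate: bool = False


def fit_line_model(values, lines) -> LineModelFit:
    """One-way ANOVA of *values* on the *lines* factor.

    F = MS_between / MS_within with df (n_lines - 1, n - n_lines).
    Requires at least two lines and at least one replicated line; a zero
    within-line sum of squares yields an infinite F flagged degenerate.
    """
    values = np.asarray(values, dtype=float).reshape(-1)
    lines = pd.Series(np.asarray(lines), name="line")
    if values.size != lines.size:
        raise ValueError("values and lines differ in length")
    groups = pd.Series(values).groupby(lines.values)
    means = groups.mean()
    sizes = groups.size()
    k, n = len(means), values.size
    if k < 2:
        raise ValueError("need at least 2 lines")
    df_between, df_within = k - 1, n - k
    if df_within <= 0:
        raise ValueError("no replication: within-line degrees of freedom is zero")
    grand = values.mean()
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(((values - means.loc[lines.values].to_numpy()) ** 2).sum())
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        return LineModelFit(float("inf"), df_between, df_within, 0.0, 0.0, means, sizes, True)
    F = ms_between / ms_within
    p = float(stats.f.sf(F, df_between, df_within))
    return LineModelFit(float(F), df_between, df_within, p, ms_within, means, sizes)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def marginal_means(fit: LineModelFit, mapping: OrderNorm | None = None, conf: float = 0.95) -> pd.DataFrame:
    """Per-line estimated marginal means with confidence limits.

    For a one-way model the marginal mean is the line's arithmetic mean
    of transformed values; CI = mean +/- t(1-(1-conf)/2, df_within) *
    sqrt(MS_within / n_line). With an OrderNorm *mapping*, means and
    limits are also back-transformed to the area scale.
    """
    tcrit = stats.t.ppf(1 - (1 - conf) / 2, fit.df_within)
    se = np.sqrt(fit.ms_within / fit.group_sizes.to_numpy(float))
    out = pd.DataFrame(
        {
            "n": fit.group_sizes,
            "emmean": fit.group_means,
            "se": se,
            "lower": fit.group_means - tcrit * se,
            "upper": fit.group_means + tcrit * se,
        }
    )
    if mapping is not None:
        for col in ("emmean", "lower", "upper"):
            out[f"{col}_backtransformed"] = mapping.inverse_transform(out[col].to_numpy())
    return out


from functools import lru_cache


@lru_cache(maxsize=1024)
def _tukey_qcrit(alpha: float, k: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1 - alpha, k, df))


def pairwise_significance(
    fit: LineModelFit, alpha: float = 0.05, adjust: str = "tukey", exact_p: bool = False
) -> pd.DataFrame:
    """Pairwise line contrasts on the fitted model.

    Returns one row per unordered line pair with the t statistic, a p
    value and the significance decision. ``adjust`` is "tukey"
    (studentized-range), "bh" or "none". For Tukey the decision compares
    the q statistic against the exact studentized-range critical value;
    the reported p uses the fast psturng approximation unless *exact_p*
    asks for the exact (slow) survival function.
    """
    lines = list(fit.group_means.index)
    k = len(lines)
    rows = []
    for a, b in combinations(lines, 2):
        diff = fit.group_means[a] - fit.group_means[b]
        se = np.sqrt(fit.ms_within * (1 / fit.group_sizes[a] + 1 / fit.group_sizes[b]))
        t = diff / se if se > 0 else np.inf * np.sign(diff)
        rows.append({"line_a": a, "line_b": b, "t": float(t)})
    table = pd.DataFrame(rows)
    t_abs = table["t"].abs().to_numpy()
    if adjust == "tukey":
        q = t_abs * np.sqrt(2)
        if exact_p:
            p = stats.studentized_range.sf(np.where(np.isinf(q), 1e6, q), k, fit.df_within)
        else:
            from statsmodels.stats.libqsturng import psturng

            p = np.atleast_1d(psturng(np.where(np.isinf(q), 1e6, q), k, fit.df_within))
        p = np.where(np.isinf(t_abs), 0.0, p)
        significant = q > _tukey_qcrit(alpha, k, fit.df_within)
    else:
        p = 2 * stats.t.sf(t_abs, fit.df_within)
        if adjust == "bh" and len(table):
            p = fdr_adjust(p)
        significant = p < alpha
    table["p"] = p
    table["significant"] = significant
    return table


def compact_letters(levels, significant_pairs) -> dict:
    """Compact letter display by insert-and-absorb.

    *significant_pairs* is an iterable of (a, b) level pairs judged
    significantly different. Two levels share a letter iff their pair is
    not significant.
    """
    levels = list(levels)
    groups = [set(levels)]
    for a, b in significant_pairs:
        new_groups = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend([g - {a}, g - {b}])
            else:
                new_groups.append(g)
        # absorb: drop groups contained in another
        groups = [
            g
            for i, g in enumerate(new_groups)
            if g and not any(g < h or (g == h and i > j) for j, h in enumerate(new_groups))
        ]
    # letters in order of each level's first appearance
    groups.sort(key=lambda g: min(levels.index(x) for x in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lv: "" for lv in levels}
    for i, g in enumerate(groups):
        symbol = alphabet[i % 26] * (i // 26 + 1)
        for lv in g:
            letters[lv] += symbol
    return {lv: "".join(sorted(s)) for lv, s in letters.items()}


def pairwise_letters(fit: LineModelFit, alpha: float = 0.05, adjust: str = "tukey") -> dict:
    """Letter codes per line: lines sharing a letter are not significantly different."""
    contrasts = pairwise_significance(fit, alpha=alpha, adjust=adjust)
    sig = [(r.line_a, r.line_b) for r in contrasts.itertuples() if r.significant]
    order = fit.group_means.sort_values(ascending=False).index
    return compact_letters(order, sig)


def spearman_screen(line_means: pd.DataFrame, exclude_line: str | None = None) -> pd.DataFrame:
    """Pairwise Spearman correlations between per-line mean peak areas.

    *line_means* is peaks x lines. Optionally excludes one line (e.g.
    the domesticated line) before correlating; p values are BH-adjusted
    over all peak pairs. Pairs with a constant vector get missing rho.
    """
    data = line_means.drop(columns=[exclude_line]) if exclude_line else line_means
    if data.shape[1] < 3:
        raise ValueError("need at least 3 lines for a Spearman screen")
    peaks = list(data.index)
    rows = []
    for a, b in combinations(peaks, 2):
        xa, xb = data.loc[a].to_numpy(float), data.loc[b].to_numpy(float)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            rows.append({"peak_a": a, "peak_b": b, "rho": np.nan, "p_raw": np.nan})
            continue
        rho, p = stats.spearmanr(xa, xb)
        rows.append({"peak_a": a, "peak_b": b, "rho": float(rho), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        mask = out["p_raw"].notna()
        out["p_fdr"] = np.nan
        out.loc[mask, "p_fdr"] = fdr_adjust(out.loc[mask, "p_raw"].to_numpy())
    return out


@dataclass
class ScreenResult:
    """Output bundle of :func:`screen_dataset`."""

    table: pd.DataFrame
    emmeans: dict
    letters: dict
    retained: list
    skipped: list


def screen_dataset(
    table: PeakTable,
    alpha: float = 0.05,
    threshold: float = 0.5,
    by_line: bool = True,
    include_zeros: bool = True,
    adjust: str = "tukey",
    apply_filter: bool = True,
) -> ScreenResult:
    """Full per-peak line-variation screen of one dataset.

    Applies the inclusion filter, then per retained peak: OrderNorm on
    the peak's areas -> one-way line-model F test; BH-FDR across the
    dataset's peaks; marginal means and compact letters for the
    FDR-significant peaks. Peaks whose areas are constant (or otherwise
    fail model preconditions) are logged and skipped.
    """
    labels = (
        inclusion_filter(table, by_line=by_line, threshold=threshold)
        if apply_filter
        else list(table.areas.columns)
    )
    lines = table.samples["line"].to_numpy()
    rows, mappings, skipped = [], {}, []
    for label in labels:
        areas = table.areas[label].to_numpy(float)
        if not include_zeros:
            keep = areas > 0
            areas, peak_lines = areas[keep], lines[keep]
        else:
            peak_lines = lines
        try:
            mapping = OrderNorm().fit(areas)
            fit = fit_line_model(mapping.transform(areas), peak_lines)
        except ValueError as exc:
            logger.info("peak %s skipped: %s", label, exc)
            skipped.append(label)
            continue
        mappings[label] = (mapping, fit)
        rows.append(
            {
                "peak_label": float(label),
                "n": len(areas),
                "F": fit.F,
                "df_between": fit.df_between,
                "df_within": fit.df_within,
                "p_raw": fit.p,
            }
        )
    result = pd.DataFrame(rows)
    emmeans, letters = {}, {}
    if len(result):
        result["p_fdr"] = fdr_adjust(result["p_raw"].to_numpy())
        result["significant"] = result["p_fdr"] < alpha
        for rec in result[result["significant"]].itertuples():
            mapping, fit = mappings[rec.peak_label]
            emmeans[rec.peak_label] = marginal_means(fit, mapping)
            letters[rec.peak_label] = pairwise_letters(fit, alpha=alpha, adjust=adjust)
    return ScreenResult(result, emmeans, letters, [float(x) for x in labels], skipped)
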
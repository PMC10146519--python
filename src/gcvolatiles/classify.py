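"""Peak inclusion filtering and classification.

Implements the screening rules used for rectal-gland volatile tables:

* inclusion filter — keep a peak only if detected in at least half the
  samples of at least one sex/mating-history category (optionally within
  at least one line);
* abundance classes — major / intermediate / minor by the peak's share of
  total area in the category where it is most abundant (>=1%, 0.1-0.99%,
  <0.1%);
* sex bias — sex specific (detected in one sex only), sex selective
  (>1 log10 difference in mean area between sexes), or none;
* retention ranges — short / mid / long windows on the Rt or KI axis;
* a chi-square ratio (enrichment) test of observed category counts
  against reference proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .peak_io import PeakTable

ABUNDANCE_CLASSES = ("major", "intermediate", "minor")
RT_RANGES = ("short", "mid", "long")


@dataclass(frozen=True)
class RangeBounds:
    """Short/mid/long windows on the retention-time and Kovats-index axes."""

    rt_short: tuple = (4.60, 10.39)
    rt_mid: tuple = (10.40, 13.59)
    rt_long: tuple = (13.60, 21.0)
    ki_short: tuple = (840, 1095)
    ki_mid: tuple = (1096, 1240)
    ki_long: tuple = (1241, 2175)


DEFAULT_BOUNDS = RangeBounds()


def rt_range(label: float, bounds: RangeBounds = DEFAULT_BOUNDS) -> str:
    """Classify a peak label (Rt in minutes or KI) as short, mid or long.

    Labels >= 600 are interpreted on the Kovats-index axis, smaller ones
    as retention times; a label outside all windows is an error.
    """
    label = float(label)
    windows = (
        (bounds.ki_short, bounds.ki_mid, bounds.ki_long)
        if label >= 600
        else (bounds.rt_short, bounds.rt_mid, bounds.rt_long)
    )
    for name, (lo, hi) in zip(RT_RANGES, windows):
        if lo <= label <= hi:
            return name
    raise ValueError(f"peak label {label} outside the classified Rt/KI ranges")


def inclusion_filter(
    table: PeakTable,
    by_line: bool = True,
    threshold: float = 0.5,
    category_cols: Iterable[str] = ("sex", "mating"),
) -> list:
    """Labels of peaks detected in >= *threshold* of samples in some cell.

    A cell is a sex/mating-history category, crossed with line when
    *by_line* is set. The comparison is inclusive (>=), so a peak seen
    in 2 of 4 samples of a single cell passes at the default threshold.
    Monotone in *threshold*: raising it never adds peaks.
    """
    group_cols = [c for c in category_cols if c in table.samples.columns]
    if by_line:
        group_cols = ["line"] + group_cols
    detected = table.detected()
    if not group_cols:
        prop = detected.mean(axis=0).to_frame().T
    else:
        prop = detected.groupby([table.samples[c] for c in group_cols], observed=True).mean()
    keep = (prop >= threshold).any(axis=0)
    return [label for label in table.areas.columns if keep[label]]


def category_shares(tables: Mapping[str, PeakTable]) -> pd.DataFrame:
    """Per-category share of total summed area for every peak (fractions)."""
    shares = {}
    for name, tab in tables.items():
        total = tab.areas.to_numpy(float).sum()
        shares[name] = tab.areas.sum(axis=0) / total
    return pd.DataFrame(shares)


def abundance_class(tables: Mapping[str, PeakTable], peak_label: float) -> str:
    """Major / intermediate / minor by maximum category share.

    The share is the peak's summed area divided by the summed area of all
    peaks in that category; the class comes from the maximum share over
    categories: >=1% major, >=0.1% intermediate, <0.1% minor.
    """
    best = 0.0
    present = False
    for tab in tables.values():
        cols = np.asarray(tab.areas.columns, dtype=float)
        hit = np.isclose(cols, float(peak_label))
        if not hit.any():
            continue
        present = True
        col = tab.areas.columns[int(np.argmax(hit))]
        total = tab.areas.to_numpy(float).sum()
        if total > 0:
            best = max(best, float(tab.areas[col].sum()) / total)
    if not present:
        raise KeyError(f"peak {peak_label} absent from all category tables")
    if best >= 0.01:
        return "major"
    if best >= 0.001:
        return "intermediate"
    return "minor"


def sex_bias_class(
    male_table: PeakTable | None,
    female_table: PeakTable | None,
    peak_label: float,
    log10_threshold: float = 1.0,
) -> str:
    """Sex specificity/selectivity of one peak within one sample type.

    Both tables must already be restricted to the same mating-history
    category. Detected in one sex only -> ``*_specific``; detected in
    both with more than *log10_threshold* difference in mean area ->
    ``*_selective`` toward the larger sex; otherwise ``none``. Means
    include non-detected (zero) samples. Exactly 10-fold differences do
    not count as selective (the rule is strictly greater).
    """
    def mean_area(tab):
        if tab is None or tab.n_samples == 0:
            return None
        cols = np.asarray(tab.areas.columns, dtype=float)
        hit = np.isclose(cols, float(peak_label))
        if not hit.any():
            return 0.0
        return float(tab.areas[tab.areas.columns[int(np.argmax(hit))]].mean())

    mean_m = mean_area(male_table)
    mean_f = mean_area(female_table)
    if mean_m is None or mean_f is None:
        return "not_assayed"
    det_m, det_f = mean_m > 0, mean_f > 0
    if not det_m and not det_f:
        return "not_detected"
    if det_m and not det_f:
        return "male_specific"
    if det_f and not det_m:
        return "female_specific"
    diff = math.log10(mean_m) - math.log10(mean_f)
    if diff > log10_threshold:
        return "male_selective"
    if -diff > log10_threshold:
        return "female_selective"
    return "none"


def enrichment_test(observed_counts, reference_counts):
    """Goodness-of-fit chi-square of observed counts against reference ratios.

    Expected counts are the observed total split in the reference
    proportions; the statistic is sum((O-E)^2/E) on (k-1) degrees of
    freedom. Used to ask whether, e.g., significant peaks are enriched
    in particular retention ranges relative to all peaks tested.
    """
    obs = np.asarray(observed_counts, dtype=float)
    ref = np.asarray(reference_counts, dtype=float)
    if obs.shape != ref.shape:
        raise ValueError("observed and reference count vectors differ in length")
    if (ref <= 0).any():
        raise ValueError("all reference counts must be positive")
    if obs.sum() <= 0:
        raise ValueError("observed total must be positive")
    expected = obs.sum() * ref / ref.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def contingency_test(observed_counts, reference_counts):
    """2 x k chi-square treating both count vectors as samples.

    Companion to :func:`enrichment_test` for the alternative reading of a
    ratio comparison where the reference is itself a counted sample.
    """
    table = np.vstack([observed_counts, reference_counts])
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def range_share_summary(cases_per_range: Mapping[str, int], peaks_per_range: Mapping[str, int]):
    """Shares of significance cases and of tested peaks per retention range.

    Returns a DataFrame with, per range, the number of significance
    cases, the share of all cases it represents (percent), the number of
    peaks tested, and the percent of that range's tested peaks involved
    in a case.
    """
    rows = {}
    total_cases = sum(cases_per_range.values())
    for rng in RT_RANGES:
        cases = cases_per_range.get(rng, 0)
        tested = peaks_per_range.get(rng, 0)
        rows[rng] = {
            "cases": cases,
            "case_share_pct": 100.0 * cases / total_cases if total_cases else 0.0,
            "peaks_tested": tested,
            "pct_of_range_significant": 100.0 * cases / tested if tested else 0.0,
        }
    return pd.DataFrame(rows).T


def classification_summary(classifications: pd.DataFrame) -> pd.DataFrame:
    """Count classified peaks per (virgin-bias, mixed-bias, range, abundance).

    *classifications* needs columns ``virgin_bias``, ``mixed_bias``,
    ``rt_range`` and ``abundance``; the result is a counts table over the
    full cross of observed transition patterns, ranges and classes.
    """
    required = ["virgin_bias", "mixed_bias", "rt_range", "abundance"]
    missing = [c for c in required if c not in classifications.columns]
    if missing:
        raise ValueError(f"classification table missing columns: {missing}")
    if classifications.empty:
        return pd.DataFrame(columns=required + ["count"])
    counts = (
        classifications.groupby(required, observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return counts


def classify_peaks(
    category_tables: Mapping[tuple, PeakTable],
    peak_labels: Iterable[float],
    bounds: RangeBounds = DEFAULT_BOUNDS,
) -> pd.DataFrame:
    """Full per-peak classification across the four sex/mating categories.

    *category_tables* maps (sex, mating) tuples to tables; a missing key
    means that category was not assayed. Returns one row per peak with
    the retention range, abundance class and per-sample-type sex bias.
    """
    named = {f"{sex}-{mating}": tab for (sex, mating), tab in category_tables.items()}
    rows = []
    for label in peak_labels:
        row = {"peak_label": float(label), "rt_range": rt_range(label, bounds)}
        try:
            row["abundance"] = abundance_class(named, label)
        except KeyError:
            row["abundance"] = "not_detected"
        for mating, col in (("virgin", "virgin_bias"), ("mixed", "mixed_bias")):
            row[col] = sex_bias_class(
                category_tables.get(("male", mating)),
                category_tables.get(("female", mating)),
                label,
            )
        rows.append(row)
    return pd.DataFrame(rows)
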
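"""Simulation-based validation of the analysis stages.

Each benchmark generates study-shaped data with known truth and measures
an operating characteristic of one stage: type-I error and power of the
per-peak line screen, recovery and false-pair rate of the cross-platform
matching pipeline, and calibration of the PERMANOVA permutation test
under the null. They are used by the test suite and by the reproduction
script; problem sizes are arguments so callers can trade precision for
time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .classify import abundance_class
from .linestats import screen_dataset
from .matching import candidate_matches, assign_spectra, compatibility_rating, presence_code
from .multivariate import distance_matrix, permanova
from .peak_io import PeakTable, normalize_batches
from .simulate import SimConfig, simulate_gcms, simulate_study, pattern_presence_codes


def _null_config(**overrides) -> SimConfig:
    base = dict(
        n_peaks=125,
        fraction_line_affected=0.0,
        categories=(("male", "mixed"),),
    )
    base.update(overrides)
    return SimConfig(**base)


def screen_type1_error(n_datasets: int = 8, alpha: float = 0.05, seed: int = 0):
    """Rejection rate of the per-peak line F test on null simulations.

    Simulates *n_datasets* studies with no line effects, screens each
    male mixed-cohort table and pools the raw per-peak p values. Returns
    ``(rejection_rate, n_tests, max_fdr_significant)`` where the last
    entry is the largest FDR-significant count seen in any null dataset.
    """
    rng = np.random.default_rng(seed)
    p_values = []
    max_fdr_sig = 0
    for _ in range(n_datasets):
        tables, _ = simulate_study(_null_config(), seed=int(rng.integers(2**31)))
        res = screen_dataset(normalize_batches(tables[("male", "mixed")]), alpha=alpha)
        p_values.append(res.table["p_raw"].to_numpy())
        max_fdr_sig = max(max_fdr_sig, int(res.table["significant"].sum()))
    pooled = np.concatenate(p_values)
    return float((pooled < alpha).mean()), len(pooled), max_fdr_sig


def screen_power(
    n_sims: int = 10,
    effect_size: float = 2.0,
    reps_per_line: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Power of the screen for line effects of *effect_size* residual SDs.

    Each simulated dataset has 24 lines with *reps_per_line* replicates
    (one generation) and ~10% of 100 peaks carrying line effects; power
    is the fraction of affected-and-tested peaks that are FDR-significant.
    Returns ``(power, n_affected_tested)``.
    """
    rng = np.random.default_rng(seed)
    config = SimConfig(
        n_peaks=100,
        generations=(6,),
        reps_per_generation=(reps_per_line, reps_per_line),
        line_effect_size=effect_size,
        fraction_line_affected=0.1,
        categories=(("male", "mixed"),),
    )
    hits = total = 0
    for _ in range(n_sims):
        tables, truth = simulate_study(config, seed=int(rng.integers(2**31)))
        res = screen_dataset(normalize_batches(tables[("male", "mixed")]), alpha=alpha)
        affected = set(truth.peaks.loc[truth.peaks["line_affected"], "rt"])
        tested = set(res.table["peak_label"])
        found = set(res.table.loc[res.table["significant"], "peak_label"])
        total += len(affected & tested)
        hits += len(affected & tested & found)
    return (hits / total if total else float("nan")), total


def _rate_candidates(cands, tables, truth, ms):
    """Attach compatibility ratings using truth-consistent presence codes."""
    ki2rt = dict(zip(truth.peaks["true_ki"].astype(float), truth.peaks["rt"]))
    ms_meta = ms.set_index("ki")
    cat = {key: tables[key] for key in tables}
    named = {f"{s}-{m}": t for (s, m), t in cat.items()}

    def codes_at(rt):
        return {
            mt: presence_code(cat.get(("male", mt)), cat.get(("female", mt)), rt)
            for mt in ("virgin", "mixed")
        }

    for cand in cands:
        if not cand.accepted:
            continue
        rt = ki2rt[cand.fid_ki]
        src = ms_meta.loc[cand.ms_ki, "source_rt"]
        if pd.isna(src):  # platform-specific extra: only its sex pattern is known
            ms_codes = pattern_presence_codes(ms_meta.loc[cand.ms_ki, "sex_pattern"])
        else:
            ms_codes = codes_at(src)
        try:
            abundance = abundance_class(named, rt)
        except KeyError:
            abundance = "minor"
        cand.rating = compatibility_rating(codes_at(rt), ms_codes, abundance)
    return cands


def matching_benchmark(n_sims: int = 50, tol: float = 4.0, seed: int = 0):
    """Pair recovery and false-pair rate of the full matching pipeline.

    Uses a 30-peak evenly spaced panel (all shared between platforms,
    plus platform-specific extras) with the default KI noise, runs
    candidate generation, compatibility rating and spectra assignment,
    and scores accepted pairs against the generator's truth. Returns
    ``(recovery, false_pair_rate, n_shared)``.
    """
    grid = tuple(np.round(np.linspace(4.8, 20.8, 30), 2))
    config = SimConfig(rt_grid=grid, fraction_shared_ms=1.0, fraction_platform_specific=0.2)
    rng = np.random.default_rng(seed)
    recovered = false = accepted = shared = 0
    for _ in range(n_sims):
        s1, s2 = (int(x) for x in rng.integers(2**31, size=2))
        tables, truth = simulate_study(config, seed=s1)
        ms = simulate_gcms(config, truth, seed=s2)
        fid = truth.peaks["true_ki"].to_numpy(float)
        cands = candidate_matches(fid, ms["ki"], tol=tol)
        cands = _rate_candidates(cands, tables, truth, ms)
        result = assign_spectra(cands)
        truemap = dict(zip(ms["ki"], ms["source_rt"]))
        ki2rt = dict(zip(fid, truth.peaks["rt"]))
        for cand in result.accepted:
            src = truemap.get(cand.ms_ki)
            if src is not None and not pd.isna(src) and abs(ki2rt[cand.fid_ki] - src) < 1e-9:
                recovered += 1
            else:
                false += 1
        accepted += len(result.accepted)
        shared += int(ms["shared"].sum())
    return recovered / shared, (false / accepted if accepted else 0.0), shared


def permanova_null_pvalues(n_runs: int = 500, n_perm: int = 199, seed: int = 0):
    """Permutation p values of a one-way PERMANOVA under the null.

    Each run draws a small table (4 groups x 3 samples, 5 peaks) with no
    group structure and records the line-term p value; under the null
    these are uniform on the permutation grid. Returns the array of p
    values and the Kolmogorov-Smirnov p value against uniformity.
    """
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_runs)
    lines = np.repeat([f"L{i}" for i in range(4)], 3)
    for i in range(n_runs):
        areas = rng.lognormal(3.0, 1.0, size=(12, 5))
        idx = pd.Index([f"s{j}" for j in range(12)], name="sample_id")
        tab = PeakTable(
            pd.DataFrame({"line": lines}, index=idx),
            pd.DataFrame(areas, index=idx, columns=[5.0, 6.0, 7.0, 8.0, 9.0]),
        )
        dist = distance_matrix(tab)
        out = permanova(dist, tab.samples["line"], n_perm=n_perm, seed=int(rng.integers(2**31)))
        pvals[i] = out.terms.loc[0, "p"]
    ks = stats.kstest(pvals, "uniform")
    return pvals, float(ks.pvalue)
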
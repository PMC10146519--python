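"""Synthetic study generator with known ground truth.

Emulates the design of the isofemale-line volatile study: 23 recently
collected lines from 7 localities plus one long-domesticated line,
screened over up to 4 generations with 1-4 replicate cages per
generation, in up to four sex/mating-history categories. Peak areas are
log-normal: log10(area) is a peak baseline plus sex, line, generation,
and batch effects plus residual noise, left-censored to 0 below a
detection threshold. A known piecewise Rt->KI map and configurable KI
noise let the calibration and cross-platform matching stages be tested
against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .peak_io import PeakTable, SEXES, MATINGS

#: localities and number of isofemale lines per locality, as in the study
DEFAULT_LOCALITIES = {
    "AliceSprings": 3,
    "CapeTribulation": 3,
    "Sydney": 3,
    "Brisbane": 4,
    "Mareeba": 4,
    "Narrabri": 3,
    "UtcheeCreek": 3,
}

_CATEGORIES = tuple((s, m) for s in SEXES for m in MATINGS)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Effects act on the log10(area) scale; ``line_effect_size`` and the
    domesticated multiplier are in residual-SD units.
    """

    localities: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LOCALITIES))
    domesticated_line: str = "S06"
    domesticated_locality: str = "Sydney"
    generations: tuple = (6, 8, 10, 12)
    reps_per_generation: tuple = (1, 2)
    categories: tuple = _CATEGORIES
    n_peaks: int = 150
    rt_span: tuple = (4.6, 21.0)
    rt_grid: tuple | None = None  # explicit peak Rts; overrides n_peaks/rt_span
    fraction_sex_specific: float = 0.45
    male_share_of_specific: float = 0.75
    fraction_sex_selective: float = 0.2
    sex_selective_shift: float = 1.5
    fraction_line_affected: float = 0.1
    line_effect_size: float = 2.0
    domesticated_multiplier: float = 2.0
    fraction_locality_affected: float = 0.0
    locality_effect_size: float = 0.0  # rank-1 effect: one direction across peaks
    residual_sd: float = 0.3
    generation_sd: float = 0.05
    batch_log_sd: float = 0.05
    baseline_range: tuple = (2.5, 6.0)
    detection_threshold: float = 300.0
    ki_noise_sd: float = 1.5
    fraction_shared_ms: float = 0.6
    fraction_platform_specific: float = 0.2

    def validate(self) -> None:
        fracs = (
            self.fraction_sex_specific,
            self.male_share_of_specific,
            self.fraction_sex_selective,
            self.fraction_line_affected,
            self.fraction_locality_affected,
            self.fraction_shared_ms,
            self.fraction_platform_specific,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all fractions must be in [0, 1]")
        if self.line_effect_size < 0 or self.domesticated_multiplier < 0:
            raise ValueError("effect sizes must be >= 0")
        if not (4.6 <= self.rt_span[0] < self.rt_span[1] <= 21.0):
            raise ValueError("Rt span must lie within [4.6, 21]")
        if self.rt_grid is not None:
            grid = np.asarray(self.rt_grid, dtype=float)
            if not ((grid >= 4.6) & (grid <= 21.0)).all() or not (np.diff(grid) > 0).all():
                raise ValueError("rt_grid must be strictly increasing within [4.6, 21]")
        if self.reps_per_generation[0] < 1:
            raise ValueError("need at least one replicate per sampled generation")


# -- true Rt -> KI map -------------------------------------------------
_ANCHORS_RT = np.array([13.59, 15.0, 16.5, 17.37])
_ANCHORS_KI = np.array([1240.0, 1310.0, 1420.0, 1500.0])
_MID_PCHIP = PchipInterpolator(_ANCHORS_RT, _ANCHORS_KI)


def true_ki(rt) -> np.ndarray:
    """Ground-truth piecewise Rt->KI map used by the generator.

    Linear below Rt 13.59 and above Rt 17.37, monotone-cubic in between;
    continuous and increasing over [4.6, 21].
    """
    rt = np.asarray(rt, dtype=float)
    lower = 635.2 + 44.49388 * rt  # through (4.60, 840) and (13.59, 1240)
    upper = 1500.0 + (2175.0 - 1500.0) / (21.0 - 17.37) * (rt - 17.37)
    out = np.where(rt <= 13.59, lower, np.where(rt >= 17.37, upper, _MID_PCHIP(rt)))
    return out


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated study."""

    peaks: pd.DataFrame  # rt, true_ki, sex_pattern, line/locality effects
    line_effects: pd.DataFrame  # lines x peaks, log10-scale shifts
    batch_log_factors: dict
    locality_scalars: dict
    config: SimConfig


def _line_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for loc, n in config.localities.items():
        abbr = "".join(w[0] for w in loc.split()) if " " in loc else loc[:2].upper()
        for i in range(n):
            rows.append({"line": f"{abbr}{i + 1:02d}", "locality": loc, "domesticated": False})
    rows.append(
        {
            "line": config.domesticated_line,
            "locality": config.domesticated_locality,
            "domesticated": True,
        }
    )
    return pd.DataFrame(rows)


def simulate_study(config: SimConfig | None = None, seed: int | None = None):
    """Generate per-category peak tables plus the truth used to make them.

    Returns ``(tables, truth)`` where *tables* maps (sex, mating) tuples
    to :class:`~gcvolatiles.peak_io.PeakTable` objects. Same seed, same
    output, bit for bit.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    lines = _line_table(config)

    # peak panel ---------------------------------------------------------
    if config.rt_grid is not None:
        rts = np.round(np.asarray(config.rt_grid, dtype=float), 2)
        n_peaks = len(rts)
        config = replace(config, n_peaks=n_peaks)
    else:
        lo, hi = config.rt_span
        rts = np.sort(rng.uniform(lo, hi, config.n_peaks))
        rts = np.round(rts, 2)
        while len(np.unique(rts)) < config.n_peaks:  # resolve 2-d.p. collisions
            dup = pd.Series(rts).duplicated().to_numpy()
            rts[dup] = np.round(rng.uniform(lo, hi, int(dup.sum())), 2)
            rts = np.sort(rts)
    baselines = rng.uniform(*config.baseline_range, config.n_peaks)

    u = rng.uniform(size=config.n_peaks)
    sex_pattern = np.full(config.n_peaks, "none", dtype=object)
    spec = u < config.fraction_sex_specific
    male_spec = spec & (rng.uniform(size=config.n_peaks) < config.male_share_of_specific)
    sex_pattern[spec] = "female_specific"
    sex_pattern[male_spec] = "male_specific"
    sel = (~spec) & (u < config.fraction_sex_specific + config.fraction_sex_selective)
    male_sel = sel & (rng.uniform(size=config.n_peaks) < 0.5)
    sex_pattern[sel] = "female_selective"
    sex_pattern[male_sel] = "male_selective"

    affected = rng.uniform(size=config.n_peaks) < config.fraction_line_affected
    effect_scale = config.line_effect_size * config.residual_sd
    line_effects = pd.DataFrame(
        0.0, index=lines["line"], columns=np.round(rts, 2)
    )
    for p in np.flatnonzero(affected):
        col = line_effects.columns[p]
        line_effects[col] = rng.normal(0.0, effect_scale, len(lines))
        line_effects.loc[lines.loc[lines["domesticated"], "line"], col] = (
            config.domesticated_multiplier * effect_scale
        )

    # rank-1 locality effect: one shared direction over the affected peaks
    loc_affected = rng.uniform(size=config.n_peaks) < config.fraction_locality_affected
    loc_weights = np.where(loc_affected, rng.uniform(0.5, 1.0, config.n_peaks), 0.0)
    loc_scale = config.locality_effect_size * config.residual_sd
    locality_scalars = {loc: rng.normal(0.0, loc_scale) for loc in config.localities}

    peaks = pd.DataFrame(
        {
            "rt": rts,
            "true_ki": np.round(true_ki(rts)).astype(int),
            "baseline": baselines,
            "sex_pattern": sex_pattern,
            "line_affected": affected,
            "locality_affected": loc_affected,
            "locality_weight": loc_weights,
        }
    )

    # batches: one per screened generation, as in the assay design -------
    batch_log = {f"B{g}": rng.normal(0.0, config.batch_log_sd) for g in config.generations}

    tables = {}
    gen_shift = {g: rng.normal(0.0, config.generation_sd) for g in config.generations}
    for sex, mating in config.categories:
        meta_rows, area_rows = [], []
        for rec in lines.itertuples():
            for g in config.generations:
                n_rep = int(rng.integers(config.reps_per_generation[0], config.reps_per_generation[1] + 1))
                for r in range(n_rep):
                    sid = f"{rec.line}-{sex[0]}{mating[0]}-g{g}-c{r + 1}"
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "line": rec.line,
                            "locality": rec.locality,
                            "generation": g,
                            "cage": f"c{r + 1}",
                            "sex": sex,
                            "mating": mating,
                            "batch": f"B{g}",
                        }
                    )
                    mu = (
                        baselines
                        + line_effects.loc[rec.line].to_numpy()
                        + locality_scalars[rec.locality] * loc_weights
                        + gen_shift[g]
                        + batch_log[f"B{g}"]
                        + rng.normal(0.0, config.residual_sd, config.n_peaks)
                    )
                    sel_shift = config.sex_selective_shift
                    if sex == "female":
                        mu = np.where(sex_pattern == "male_selective", mu - sel_shift, mu)
                        mu = np.where(sex_pattern == "female_selective", mu + sel_shift, mu)
                    else:
                        mu = np.where(sex_pattern == "male_selective", mu + sel_shift, mu)
                        mu = np.where(sex_pattern == "female_selective", mu - sel_shift, mu)
                    area = 10.0**mu
                    absent = (
                        (sex_pattern == "female_specific")
                        if sex == "male"
                        else (sex_pattern == "male_specific")
                    )
                    area = np.where(absent, 0.0, area)
                    area = np.where(area < config.detection_threshold, 0.0, area)
                    area_rows.append(area)
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        areas = pd.DataFrame(
            np.asarray(area_rows), index=meta.index, columns=np.round(rts, 2)
        )
        tables[(sex, mating)] = PeakTable(meta, areas, dataset_tag=f"sim-{sex}-{mating}")

    truth = SimTruth(peaks, line_effects, batch_log, locality_scalars, config)
    return tables, truth


def simulate_gcms(config: SimConfig, truth: SimTruth, seed: int | None = None) -> pd.DataFrame:
    """MS-side peak list consistent with a simulated study.

    A configurable subset of the FID peaks is observed on the MS platform
    with KI = true KI + Gaussian noise, plus platform-specific extra
    peaks; each row carries the source Rt (NaN for extras) so matching
    can be scored against truth.
    """
    rng = np.random.default_rng(seed)
    shared = rng.uniform(size=len(truth.peaks)) < config.fraction_shared_ms
    rows = []
    for rec, is_shared in zip(truth.peaks.itertuples(), shared):
        if not is_shared:
            continue
        ki = rec.true_ki + rng.normal(0.0, config.ki_noise_sd)
        rows.append(
            {"ki": float(np.round(ki)), "source_rt": rec.rt, "shared": True,
             "sex_pattern": rec.sex_pattern}
        )
    n_extra = int(round(config.fraction_platform_specific * len(rows)))
    lo = float(truth.peaks["true_ki"].min())
    hi = float(truth.peaks["true_ki"].max())
    patterns = ("male_specific", "female_specific", "male_selective", "female_selective", "none")
    for _ in range(n_extra):
        rows.append(
            {"ki": float(np.round(rng.uniform(lo, hi))), "source_rt": np.nan, "shared": False,
             "sex_pattern": patterns[int(rng.integers(len(patterns)))]}
        )
    out = pd.DataFrame(rows).sort_values("ki").reset_index(drop=True)
    # KIs must be duplicate-free after rounding
    out = out.drop_duplicates(subset="ki", keep="first").reset_index(drop=True)
    return out


def pattern_presence_codes(pattern: str) -> dict:
    """Idealised per-sample-type presence codes implied by a sex pattern.

    Used for the MS side of synthetic matching runs, where only the
    qualitative sex pattern (not per-replicate areas) is simulated.
    """
    from .matching import ALL, ND, PresenceCode

    hi, lo_sel = 1e4, 1e4 / 10**1.5  # selective shift on the log10 scale
    per_type = {
        "male_specific": PresenceCode(ALL, ND, hi, 0.0),
        "female_specific": PresenceCode(ND, ALL, 0.0, hi),
        "male_selective": PresenceCode(ALL, ALL, hi, lo_sel),
        "female_selective": PresenceCode(ALL, ALL, lo_sel, hi),
        "none": PresenceCode(ALL, ALL, hi, hi),
    }[pattern]
    return {"virgin": per_type, "mixed": per_type}


def make_calibrators(
    n: int = 15,
    noise_sd: float = 1.0,
    seed: int | None = None,
    rt_span: tuple = (4.6, 21.0),
) -> pd.DataFrame:
    """Synthetic calibrator pairs drawn from the true Rt->KI map.

    Returns ``n`` (rt, ki, name) rows spanning *rt_span*, with the two
    region boundaries (Rt 13.59 and 17.37) always included, KIs perturbed
    by Gaussian noise of SD *noise_sd* and rounded to integers.
    """
    rng = np.random.default_rng(seed)
    # anchors: span ends, both region boundaries, and two mid-region points
    fixed = np.array([rt_span[0], 13.59, 15.0, 16.3, 17.37, rt_span[1]])
    free = rng.uniform(rt_span[0] + 0.2, rt_span[1] - 0.2, max(n - len(fixed), 0))
    rts = np.round(np.sort(np.concatenate([fixed, free])), 2)
    rts = np.unique(rts)
    kis = np.round(true_ki(rts) + rng.normal(0.0, noise_sd, len(rts))).astype(int)
    while not (np.diff(kis) > 0).all():  # noise must not break monotonicity
        kis = np.round(true_ki(rts) + rng.normal(0.0, noise_sd, len(rts))).astype(int)
    return pd.DataFrame({"rt": rts, "ki": kis, "name": [f"cal{i + 1}" for i in range(len(rts))]})


def fixture_table4() -> pd.DataFrame:
    """The 19 published FID/MS peak pairs matched for KI in domesticated males.

    Columns: FID retention time, imputed KI, observed MS KI, identity
    (empty when unknown), whether the identification was validated with
    an authentic standard, and whether the peak varied significantly
    among lines.
    """
    rows = [
        (5.20, 885, 883, "2-Methyl-3-hexanol", False, True),
        (6.21, 933, 933, "Ethyl 2-methylpentanoate", True, True),
        (6.30, 937, 939, "x-Octenal isomer 2", True, True),
        (6.64, 953, 955, "n-Butylcyclopentane", False, False),
        (7.08, 974, 972, "Phenol", False, False),
        (8.06, 1021, 1019, "n-Octen-1-ol", True, True),
        (9.58, 1093, 1094, "N-(2-Methylpropyl) propanamide", True, False),
        (10.05, 1115, 1115, "", False, True),
        (11.16, 1161, 1164, "", False, False),
        (11.46, 1171, 1171, "2-Bornanone", True, False),
        (11.50, 1172, 1173, "", False, False),
        (11.70, 1179, 1179, "Borneol isomer 1", False, False),
        (11.93, 1185, 1187, "Borneol isomer 2", False, False),
        (11.97, 1186, 1188, "", False, False),
        (13.88, 1252, 1253, "", False, False),
        (13.95, 1254, 1256, "", False, False),
        (14.37, 1267, 1267, "", False, False),
        (17.07, 1463, 1464, "", False, True),
        (17.17, 1482, 1484, "", False, False),
    ]
    return pd.DataFrame(
        rows, columns=["rt", "ki_imputed", "ki_observed", "identity", "validated", "significant"]
    )
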
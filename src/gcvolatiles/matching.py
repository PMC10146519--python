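"""Cross-platform peak matching between GC-FID and GC-MS profiles.

FID peaks carry imputed Kovats indices, MS peaks observed ones. A pair
is a match candidate when the two KIs are mutually nearest, no more than
``tol`` units apart, and clearly closer to each other than to the
immediately adjacent alternative peaks on either side (strict
inequality; ties reject). Candidates are then rated for compatibility
of their sex/mating abundance patterns:

* ``YY`` — per sample type and per sex, the detection states agree
  (present-in-all and present-in-some are collapsed) or one platform did
  not assay that category;
* ``Y`` — the only disagreements are presence/absence where the present
  side is partial (some but not all replicates) and the peak is minor in
  abundance, or where the presence retains a greater-than-ten-fold mean
  bias toward the sex in question;
* ``N`` — anything else.

Accepted matches are the rated candidates minus already-identified peaks
and minus ``N``-rated pairs, forming a one-to-one pairing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .peak_io import PeakTable

#: detection codes, mirroring the M/m/nd/na notation used for such tables
ALL, SOME, ND, NA = "ALL", "SOME", "ND", "NA"


@dataclass(frozen=True)
class PresenceCode:
    """Detection pattern of one peak in one sample type, both sexes."""

    male: str
    female: str
    mean_male: float = float("nan")
    mean_female: float = float("nan")

    def fold_bias(self, fold: float = 10.0, strict: bool = False) -> str:
        """'male', 'female' or 'none' by mean-area fold difference."""
        m, f = self.mean_male, self.mean_female
        if not (m > 0 and f > 0) or math.isnan(m) or math.isnan(f):
            return "none"
        ratio = m / f
        if (ratio > fold) or (not strict and ratio == fold):
            return "male"
        inv = f / m
        if (inv > fold) or (not strict and inv == fold):
            return "female"
        return "none"


@dataclass
class MatchCandidate:
    """A mutually-nearest (FID, MS) KI pair with its adjacency context."""

    fid_ki: float
    ms_ki: float
    delta: float
    delta_prev: float
    delta_next: float
    fid_label: float | None = None
    rating: str = "unrated"
    accepted: bool = True
    reject_reason: str | None = None


@dataclass
class MatchResult:
    """Outcome of spectra assignment: accepted pairs and the rest."""

    accepted: list = field(default_factory=list)
    rejected: list = field(default_factory=list)
    already_identified: list = field(default_factory=list)
    unmatched_fid: list = field(default_factory=list)
    unmatched_ms: list = field(default_factory=list)


def _neighbor_deltas(value: float, sorted_arr: np.ndarray, partner_idx: int):
    """Distances from *value* to the neighbors of its matched partner."""
    prev_d = abs(value - sorted_arr[partner_idx - 1]) if partner_idx > 0 else math.inf
    next_d = (
        abs(value - sorted_arr[partner_idx + 1])
        if partner_idx + 1 < len(sorted_arr)
        else math.inf
    )
    return prev_d, next_d


def candidate_matches(fid_kis, ms_kis, tol: float = 4.0) -> list[MatchCandidate]:
    """All mutually-nearest FID/MS pairs, accepted or annotated with a reason.

    A pair is accepted when |KI difference| <= *tol* and the difference is
    strictly smaller than the distance from either member to the other
    side's adjacent alternatives; equality (a tie) rejects. Symmetric in
    the two platforms.
    """
    fid = np.asarray(sorted(fid_kis), dtype=float)
    ms = np.asarray(sorted(ms_kis), dtype=float)
    out: list[MatchCandidate] = []
    if fid.size == 0 or ms.size == 0:
        return out
    for i, f in enumerate(fid):
        j = int(np.argmin(np.abs(ms - f)))
        # mutual nearest: the MS peak's nearest FID peak must be this one
        i_back = int(np.argmin(np.abs(fid - ms[j])))
        if i_back != i:
            continue
        delta = abs(f - ms[j])
        prev_ms, next_ms = _neighbor_deltas(f, ms, j)
        prev_fid, next_fid = _neighbor_deltas(ms[j], fid, i)
        cand = MatchCandidate(
            fid_ki=float(f),
            ms_ki=float(ms[j]),
            delta=float(delta),
            delta_prev=float(min(prev_ms, prev_fid)),
            delta_next=float(min(next_ms, next_fid)),
        )
        if delta > tol:
            cand.accepted, cand.reject_reason = False, "tolerance"
        elif not (delta < prev_ms and delta < next_ms and delta < prev_fid and delta < next_fid):
            cand.accepted, cand.reject_reason = False, "adjacency"
        out.append(cand)
    return out


def presence_code(
    male_table: PeakTable | None,
    female_table: PeakTable | None,
    peak_label: float,
) -> PresenceCode:
    """Detection code of one peak for both sexes within one sample type.

    ALL if detected in every sample of a sex, SOME if in at least one but
    not all, ND if in none, NA if that sex was not assayed; mean areas
    are carried along for the fold-bias rules.
    """
    def one_sex(tab):
        if tab is None or tab.n_samples == 0:
            return NA, float("nan")
        cols = np.asarray(tab.areas.columns, dtype=float)
        hit = np.isclose(cols, float(peak_label))
        if not hit.any():
            return ND, 0.0
        col = tab.areas.columns[int(np.argmax(hit))]
        values = tab.areas[col].to_numpy(float)
        n_det = int((values > 0).sum())
        mean = float(values.mean())
        if n_det == 0:
            return ND, mean
        return (ALL if n_det == len(values) else SOME), mean

    mcode, mmean = one_sex(male_table)
    fcode, fmean = one_sex(female_table)
    return PresenceCode(male=mcode, female=fcode, mean_male=mmean, mean_female=fmean)


def compatibility_rating(
    fid_codes: Mapping[str, PresenceCode],
    ms_codes: Mapping[str, PresenceCode],
    fid_abundance_class: str,
    fold: float = 10.0,
) -> str:
    """YY / Y / N compatibility of sex/mating abundance patterns.

    *fid_codes* and *ms_codes* map sample types ("virgin", "mixed") to
    :class:`PresenceCode` objects computed on the same peak pair.
    """
    any_disagreement = False
    all_excusable = True
    for sample_type in sorted(set(fid_codes) | set(ms_codes)):
        fc = fid_codes.get(sample_type)
        mc = ms_codes.get(sample_type)
        if fc is None or mc is None:
            continue
        for sex in ("male", "female"):
            a, b = getattr(fc, sex), getattr(mc, sex)
            if a == NA or b == NA:
                continue
            det_a, det_b = a in (ALL, SOME), b in (ALL, SOME)
            if det_a == det_b:
                continue  # ALL vs SOME never breaks compatibility
            any_disagreement = True
            present_code = a if det_a else b
            present_side = fc if det_a else mc
            minor_partial = present_code == SOME and fid_abundance_class == "minor"
            biased = present_side.fold_bias(fold=fold, strict=True) == sex
            if not (minor_partial or biased):
                all_excusable = False
    if not any_disagreement:
        return "YY"
    return "Y" if all_excusable else "N"


def assign_spectra(
    candidates: Iterable[MatchCandidate],
    already_identified: Iterable[float] = (),
) -> MatchResult:
    """Final one-to-one assignment of MS spectra to FID peaks.

    Accepted pairs are the tolerance+adjacency candidates minus those
    whose FID peak is already identified (reported separately) and minus
    pairs rated ``N``. Raises on a conflicting (non-injective) pairing.
    """
    known = {round(float(k), 6) for k in already_identified}
    result = MatchResult()
    seen_fid, seen_ms = set(), set()
    for cand in candidates:
        if not cand.accepted:
            result.rejected.append(cand)
            continue
        key = round(cand.fid_label if cand.fid_label is not None else cand.fid_ki, 6)
        if key in known or round(cand.fid_ki, 6) in known:
            result.already_identified.append(cand)
            continue
        if cand.rating == "N":
            cand.reject_reason = "incompatible"
            result.rejected.append(cand)
            continue
        if cand.fid_ki in seen_fid or cand.ms_ki in seen_ms:
            raise ValueError(f"conflicting assignment for pair {cand.fid_ki}/{cand.ms_ki}")
        seen_fid.add(cand.fid_ki)
        seen_ms.add(cand.ms_ki)
        result.accepted.append(cand)
    return result
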
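"""Retention-time -> Kovats-index calibration for GC-FID peaks.

GC-FID yields retention times (Rt) but no spectra; GC-MS yields Kovats
indices (KI) on an alkane-normalised scale that is comparable across
instruments. Compounds identified against authentic standards on both
platforms ("calibrator" peaks) anchor a piecewise Rt->KI map: the Rt-KI
relationship is close to linear at both ends of the chromatogram with a
curved transition in between, so the map is piecewise linear
interpolation in the two outer regions and a low-degree polynomial fit
in the intervening region. The fitted map imputes a KI for every FID
peak, which is what the cross-platform peak matching consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


def _interp_extrap(x, xp, fp):
    """np.interp with linear extrapolation from the end segments."""
    x = np.asarray(x, dtype=float)
    y = np.interp(x, xp, fp)
    if len(xp) >= 2:
        lo = x < xp[0]
        hi = x > xp[-1]
        if lo.any():
            slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
            y = np.where(lo, fp[0] + slope * (x - xp[0]), y)
        if hi.any():
            slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
            y = np.where(hi, fp[-1] + slope * (x - xp[-1]), y)
    return y


class KovatsCalibrator(RegressorMixin, BaseEstimator):
    """Piecewise Rt->KI calibration fitted from calibrator peaks.

    Parameters
    ----------
    lower_max_rt : float
        Last retention time (minutes) of the lower linear region.
    upper_min_rt : float
        First retention time of the upper linear region.
    poly_degree : int
        Degree of the least-squares polynomial for the mid region.
    boundary_tol : float
        Maximum allowed |KI| gap between the mid polynomial and the
        calibrators at the region boundaries (soft continuity).
    extrapolation : bool
        Allow prediction outside [first calibrator Rt - margin, last
        calibrator Rt + margin]; off by default.
    margin : float
        Minutes beyond the calibrator span always allowed.

    Attributes
    ----------
    calibrators_ : pandas.DataFrame
        Sorted (rt, ki) calibrator pairs used in the fit.
    mid_coeffs_ : numpy.ndarray
        Polynomial coefficients (numpy.polyval order) for the mid region.
    """

    def __init__(
        self,
        lower_max_rt: float = 13.59,
        upper_min_rt: float = 17.37,
        poly_degree: int = 3,
        boundary_tol: float = 1.0,
        extrapolation: bool = False,
        margin: float = 1.0,
    ):
        self.lower_max_rt = lower_max_rt
        self.upper_min_rt = upper_min_rt
        self.poly_degree = poly_degree
        self.boundary_tol = boundary_tol
        self.extrapolation = extrapolation
        self.margin = margin

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """Fit from calibrator retention times *X* and Kovats indices *y*."""
        rt = np.asarray(X, dtype=float).reshape(-1)
        ki = np.asarray(y, dtype=float).reshape(-1)
        if rt.shape != ki.shape or rt.size < 4:
            raise ValueError("need matching rt/ki arrays with at least 4 calibrators")
        order = np.argsort(rt)
        rt, ki = rt[order], ki[order]
        if not (np.diff(rt) > 0).all() or not (np.diff(ki) > 0).all():
            raise ValueError("calibrators must be strictly increasing in both Rt and KI")

        lower = rt <= self.lower_max_rt
        upper = rt >= self.upper_min_rt
        if lower.sum() < 2 or upper.sum() < 2:
            raise ValueError("need at least 2 calibrators in each linear region")

        # mid region spans from the last lower calibrator to the first
        # upper calibrator, boundary points included
        i_lo = int(np.max(np.flatnonzero(lower)))
        i_hi = int(np.min(np.flatnonzero(upper)))
        mid_rt = rt[i_lo : i_hi + 1]
        mid_ki = ki[i_lo : i_hi + 1]
        if mid_rt.size < self.poly_degree + 1:
            raise ValueError(
                f"need >= {self.poly_degree + 1} calibrators spanning the mid region, "
                f"got {mid_rt.size}"
            )
        # heavy weights pull the polynomial through the boundary calibrators
        w = np.ones_like(mid_rt)
        w[0] = w[-1] = 100.0
        coeffs = np.polyfit(mid_rt, mid_ki, deg=self.poly_degree, w=w)
        for brt, bki in ((mid_rt[0], mid_ki[0]), (mid_rt[-1], mid_ki[-1])):
            gap = abs(np.polyval(coeffs, brt) - bki)
            if gap > self.boundary_tol:
                raise ValueError(
                    f"mid polynomial misses boundary calibrator at Rt {brt} by {gap:.2f} KI"
                )

        self.calibrators_ = pd.DataFrame({"rt": rt, "ki": ki})
        self.mid_coeffs_ = coeffs
        self.mid_span_ = (float(mid_rt[0]), float(mid_rt[-1]))
        self.rt_span_ = (float(rt[0]), float(rt[-1]))
        self._check_monotone()
        return self

    def _check_monotone(self):
        grid = np.linspace(self.rt_span_[0], self.rt_span_[1], 2001)
        vals = self._predict_raw(grid)
        if (np.diff(vals) < -1e-9).any():
            raise ValueError("fitted Rt->KI mapping is not monotone over the span")

    def _predict_raw(self, rt):
        rt = np.asarray(rt, dtype=float)
        cal = self.calibrators_
        low_mask = cal["rt"].to_numpy() <= self.lower_max_rt
        up_mask = cal["rt"].to_numpy() >= self.upper_min_rt
        out = np.empty_like(rt, dtype=float)
        lo = rt <= self.lower_max_rt
        hi = rt >= self.upper_min_rt
        mid = ~lo & ~hi
        if lo.any():
            out[lo] = _interp_extrap(rt[lo], cal["rt"].to_numpy()[low_mask], cal["ki"].to_numpy()[low_mask])
        if hi.any():
            out[hi] = _interp_extrap(rt[hi], cal["rt"].to_numpy()[up_mask], cal["ki"].to_numpy()[up_mask])
        if mid.any():
            out[mid] = np.polyval(self.mid_coeffs_, rt[mid])
        return out

    def predict(self, X):
        """Predicted (unrounded) KI for retention times *X*."""
        check_is_fitted(self, "calibrators_")
        rt = np.asarray(X, dtype=float).reshape(-1)
        lo_lim = self.rt_span_[0] - self.margin
        hi_lim = self.rt_span_[1] + self.margin
        if not self.extrapolation and ((rt < lo_lim) | (rt > hi_lim)).any():
            bad = rt[(rt < lo_lim) | (rt > hi_lim)]
            raise ValueError(
                f"Rt values {bad.tolist()} outside the calibrated span "
                f"[{lo_lim:.2f}, {hi_lim:.2f}]; pass extrapolation=True to override"
            )
        return self._predict_raw(rt)


def fit_calibration(calibrators, lower_max_rt=13.59, upper_min_rt=17.37, poly_degree=3) -> KovatsCalibrator:
    """Fit a :class:`KovatsCalibrator` from (rt, ki[, name]) calibrator rows."""
    arr = pd.DataFrame(calibrators)
    rt = arr.iloc[:, 0].to_numpy(float)
    ki = arr.iloc[:, 1].to_numpy(float)
    model = KovatsCalibrator(
        lower_max_rt=lower_max_rt, upper_min_rt=upper_min_rt, poly_degree=poly_degree
    )
    return model.fit(rt, ki)


def impute_ki(model: KovatsCalibrator, rt) -> np.ndarray | int:
    """Imputed integer KI(s) for retention time(s) *rt*."""
    scalar = np.isscalar(rt)
    out = np.rint(model.predict(np.atleast_1d(rt))).astype(int)
    return int(out[0]) if scalar else out


def calibration_report(model: KovatsCalibrator, holdout) -> pd.DataFrame:
    """Residual table for holdout (rt, ki) pairs.

    Returns per pair the observed and imputed KI and their difference;
    ``report.attrs["max_abs_residual"]`` carries the summary.
    """
    arr = pd.DataFrame(holdout)
    rt = arr.iloc[:, 0].to_numpy(float)
    ki_obs = arr.iloc[:, 1].to_numpy(float)
    ki_imp = impute_ki(model, rt)
    report = pd.DataFrame(
        {"rt": rt, "ki_observed": ki_obs, "ki_imputed": ki_imp, "residual": ki_imp - ki_obs}
    )
    report.attrs["max_abs_residual"] = float(np.abs(report["residual"]).max()) if len(report) else 0.0
    return report
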
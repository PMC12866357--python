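"""Time-activity curve modeling and time-integrated activity.

The bridge from a biodistribution table to absorbed dose is the
time-integrated activity coefficient (TIAC): the integral of a tissue's
activity concentration over all time, per unit injected activity, here in
units of h·(%ID/g).  Two descriptive curve shapes are supported:

* ``mono_exp``       C(t) = A · exp(-λ_eff · t)
* ``uptake_washout`` C(t) = A · (exp(-λ_eff · t) - exp(-λ_up · t))

with λ_eff the effective clearance rate (biologic + physical) and λ_up the
uptake rate.  ``uptake_washout`` is the natural shape for an antibody in
tumor (slow arrival from blood, slow washout); normal organs that peak at
the first sampling point are adequately described by ``mono_exp``.

Fitting follows the Model/Results idiom: construct a
:class:`TimeActivityModel` from times and concentrations (or a
:class:`~rptdose.biodist.TissueTimeCourse`), call :meth:`fit`, and work
with the returned :class:`TACFitResults`.

TIAC is computed either from the closed-form integral of the fitted model
(``analytic_fit``) or by trapezoid quadrature over the observation window
plus an analytic single-exponential tail (``trapezoid_tail``).  The
quadrature's leading edge assumes C(0)=0 (the antibody arrives via blood);
its tail rate is never allowed to be slower than physical decay when the
nuclide's decay constant is supplied — unbounded biologic retention is
unphysical.

The tumor-growth dilution correction multiplies a measured concentration
curve by the relative tumor volume V(t)/V(0): a tumor that doubles its mass
halves its concentration at constant total activity, so the correction
restores the curve a non-growing reference-mass tumor would have shown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .biodist import Nuclide, TissueTimeCourse

__all__ = [
    "FitError",
    "TimeActivityModel",
    "TACFitResults",
    "TIACResult",
    "tiac",
    "GrowthModel",
    "growth_dilution_correction",
    "ExponentialGrowthModel",
    "GrowthFitResults",
]

_MODELS = ("mono_exp", "uptake_washout")


class FitError(RuntimeError):
    """Raised when a curve fit fails to converge or yields invalid rates."""


def _mono(t, A, lam):
    return A * np.exp(-lam * t)


def _washout(t, A, lam_eff, dlam):
    # parameterized with lam_up = lam_eff + dlam so the bound dlam > 0
    # enforces the identifiability convention lam_up > lam_eff
    return A * (np.exp(-lam_eff * t) - np.exp(-(lam_eff + dlam) * t))


class TimeActivityModel:
    """Descriptive exponential model of a tissue time-activity curve.

    Parameters
    ----------
    times_h : array-like
        Sampling times in hours, strictly increasing.
    conc : array-like
        Concentrations (%ID/g) at those times; typically per-time-point
        group means.
    model : {"mono_exp", "uptake_washout"}
    weights : array-like, optional
        Per-point weights for the least-squares objective.  Default is
        unweighted; pass the per-point animal counts to weight by n.
    """

    def __init__(self, times_h, conc, model: str = "mono_exp", weights=None):
        if model not in _MODELS:
            raise ValueError(f"unknown model {model!r}; choose from {_MODELS}")
        t = np.asarray(times_h, dtype=float)
        y = np.asarray(conc, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("times_h and conc must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        minpts = 2 if model == "mono_exp" else 3
        if t.size < minpts:
            raise ValueError(f"{model} requires at least {minpts} time points, got {t.size}")
        if np.any(y < 0):
            raise ValueError("concentrations must be >= 0")
        self.times_h = t
        self.conc = y
        self.model = model
        self.weights = None if weights is None else np.asarray(weights, dtype=float)

    @classmethod
    def from_timecourse(
        cls, tc: TissueTimeCourse, model: str = "mono_exp", weight_by_n: bool = False
    ) -> "TimeActivityModel":
        """Build from per-time-point group means of a tissue time course."""
        w = tc.n_animals.astype(float) if weight_by_n else None
        return cls(tc.times, tc.means, model=model, weights=w)

    # -- starting values ---------------------------------------------------
    def _start(self):
        t, y = self.times_h, self.conc
        pos = y > 0
        if pos.sum() >= 2:
            # log-linear tail slope as a rate guess
            tt, yy = t[pos][-3:], y[pos][-3:]
            slope = np.polyfit(tt, np.log(yy), 1)[0]
            lam0 = max(-slope, 1e-4)
        else:
            lam0 = 1e-2
        if self.model == "mono_exp":
            A0 = y[pos][0] * np.exp(lam0 * t[pos][0]) if pos.any() else 1.0
            return [(max(A0, 1e-6), lam0)]
        peak = max(y.max(), 1e-6)
        # several uptake-rate guesses: the two-exponential surface is
        # multimodal enough that a single start occasionally stalls
        return [(1.5 * peak, lam0, d) for d in (10 * lam0, 0.02, 0.1, 0.5)]

    def fit(self, maxfev: int = 20000) -> "TACFitResults":
        """Unweighted (or n-weighted) least squares on the concentration scale.

        Raises :class:`FitError` on non-convergence or a non-positive rate;
        rates are never silently clamped.
        """
        t, y = self.times_h, self.conc
        if np.all(y == 0):
            # degenerate but well-defined: the zero curve
            return TACFitResults(
                model_name=self.model, amplitude=0.0,
                lambda_eff=np.inf, lambda_up=np.inf if self.model == "uptake_washout" else None,
                rss=0.0, t_domain=(float(t[0]), float(t[-1])), nobs=t.size, bse=None,
            )
        sigma = None if self.weights is None else 1.0 / np.sqrt(self.weights)
        func = _mono if self.model == "mono_exp" else _washout
        nump = 2 if self.model == "mono_exp" else 3
        lower = [1e-12] * nump
        upper = [np.inf] * nump
        best = None
        errors = []
        for p0 in self._start():
            try:
                popt, pcov = curve_fit(
                    func, t, y, p0=np.asarray(p0, dtype=float), sigma=sigma,
                    bounds=(lower, upper), maxfev=maxfev, xtol=1e-14, ftol=1e-14,
                )
            except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
                errors.append(str(exc))
                continue
            rss = float(np.sum((func(t, *popt) - y) ** 2))
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)
        if best is None:
            raise FitError(
                f"{self.model} fit failed on {t.size} points "
                f"(t in [{t[0]}, {t[-1]}] h): {'; '.join(errors)}"
            )
        popt, pcov, rss = best
        bse = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else None
        if self.model == "mono_exp":
            A, lam = popt
            if lam <= 0:
                raise FitError(f"non-positive clearance rate {lam}")
            return TACFitResults(
                model_name=self.model, amplitude=float(A), lambda_eff=float(lam),
                lambda_up=None, rss=rss, t_domain=(float(t[0]), float(t[-1])),
                nobs=t.size, bse=bse,
            )
        A, lam_eff, dlam = popt
        if lam_eff <= 0 or dlam <= 0:
            raise FitError(f"invalid rates lambda_eff={lam_eff}, delta={dlam}")
        if bse is not None:
            # se of lam_up = lam_eff + dlam via the delta method
            var_up = pcov[1, 1] + pcov[2, 2] + 2 * pcov[1, 2]
            bse = np.array([bse[0], bse[1], np.sqrt(max(var_up, 0.0))])
        return TACFitResults(
            model_name=self.model, amplitude=float(A), lambda_eff=float(lam_eff),
            lambda_up=float(lam_eff + dlam), rss=rss,
            t_domain=(float(t[0]), float(t[-1])), nobs=t.size, bse=bse,
        )


@dataclass(frozen=True)
class TACFitResults:
    """Fitted time-activity curve parameters.

    ``bse`` holds approximate standard errors (amplitude, λ_eff[, λ_up])
    from the Gauss–Newton covariance; ``None`` when not estimable.
    """

    model_name: str
    amplitude: float
    lambda_eff: float
    lambda_up: Optional[float]
    rss: float
    t_domain: tuple[float, float]
    nobs: int
    bse: Optional[np.ndarray] = None

    def predict(self, times_h) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        if self.amplitude == 0.0:
            return np.zeros_like(t)
        if self.model_name == "mono_exp":
            return _mono(t, self.amplitude, self.lambda_eff)
        return _washout(t, self.amplitude, self.lambda_eff, self.lambda_up - self.lambda_eff)

    def analytic_integral(self) -> float:
        """Closed-form integral of the fitted curve over [0, inf), h·%ID/g."""
        if self.amplitude == 0.0:
            return 0.0
        if self.model_name == "mono_exp":
            return self.amplitude / self.lambda_eff
        return self.amplitude * (1.0 / self.lambda_eff - 1.0 / self.lambda_up)

    def summary(self) -> str:
        lines = [
            "Time-activity curve fit",
            "=" * 47,
            f"{'model':<22}{self.model_name:>25}",
            f"{'n time points':<22}{self.nobs:>25d}",
            f"{'fit window (h)':<22}{str(self.t_domain):>25}",
            "-" * 47,
        ]
        names = ["amplitude (%ID/g)", "lambda_eff (1/h)"]
        vals = [self.amplitude, self.lambda_eff]
        if self.lambda_up is not None:
            names.append("lambda_up (1/h)")
            vals.append(self.lambda_up)
        for i, (nm, v) in enumerate(zip(names, vals)):
            se = "" if self.bse is None else f"  (se {self.bse[i]:.3g})"
            lines.append(f"{nm:<22}{v:>15.6g}{se}")
        lines.append("-" * 47)
        lines.append(f"{'RSS':<22}{self.rss:>15.6g}")
        return "\n".join(lines)


@dataclass(frozen=True)
class TIACResult:
    """Time-integrated activity concentration per unit injected activity.

    ``tail_fraction`` is the share of the integral contributed by times
    beyond the last observation (the extrapolated tail).
    """

    tissue: str
    tiac_h_pctid_g: float
    method: str
    tail_fraction: float

    def __post_init__(self) -> None:
        if self.tiac_h_pctid_g < 0:
            raise ValueError("TIAC must be >= 0")
        if not 0.0 <= self.tail_fraction <= 1.0:
            raise ValueError("tail_fraction must be in [0, 1]")


def tiac(
    tc: TissueTimeCourse,
    fit: TACFitResults,
    method: str = "trapezoid_tail",
    nuclide: Optional[Nuclide] = None,
    tail_rate: Optional[float] = None,
) -> TIACResult:
    """Time-integrated activity coefficient for one tissue, h·(%ID/g).

    ``trapezoid_tail`` integrates the observed group means by the trapezoid
    rule over [0, t_last] with a C(0)=0 leading edge, then adds the analytic
    tail C(t_last)/λ_tail.  λ_tail is ``tail_rate`` if given, otherwise the
    fitted λ_eff, floored at the physical decay constant when ``nuclide``
    is supplied (retention cannot outlive the radionuclide).

    ``analytic_fit`` returns the closed-form integral of the fitted model
    over [0, inf); the reported tail_fraction refers to times beyond the
    last observation.
    """
    if method not in ("trapezoid_tail", "analytic_fit"):
        raise ValueError(f"unknown TIAC method {method!r}")
    means = tc.means
    if np.all(means == 0):
        return TIACResult(tc.tissue, 0.0, method, 0.0)
    if method == "analytic_fit":
        total = fit.analytic_integral()
        T = tc.times[-1]
        if fit.model_name == "mono_exp":
            tail = fit.amplitude / fit.lambda_eff * np.exp(-fit.lambda_eff * T)
        else:
            tail = fit.amplitude * (
                np.exp(-fit.lambda_eff * T) / fit.lambda_eff
                - np.exp(-fit.lambda_up * T) / fit.lambda_up
            )
        return TIACResult(tc.tissue, float(total), method, float(np.clip(tail / total, 0, 1)))
    t, y = tc.times, means
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        y = np.concatenate([[0.0], y])
    trap = float(np.trapezoid(y, t))
    lam = tail_rate if tail_rate is not None else fit.lambda_eff
    if nuclide is not None:
        lam = max(lam, nuclide.lambda_phys)
    if not lam > 0 or not np.isfinite(lam):
        raise ValueError(f"tail rate must be positive and finite, got {lam}")
    tail = float(y[-1] / lam)
    total = trap + tail
    return TIACResult(tc.tissue, total, method, tail / total if total > 0 else 0.0)


# ---------------------------------------------------------------------------
# tumor growth dilution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthModel:
    """Single-exponential tumor volume model V(t) = v0 · exp(k · t)."""

    v0_mm3: float
    k_growth_per_day: float

    def __post_init__(self) -> None:
        if not self.v0_mm3 > 0:
            raise ValueError("v0_mm3 must be > 0")

    def volume(self, t_days) -> np.ndarray:
        return self.v0_mm3 * np.exp(self.k_growth_per_day * np.asarray(t_days, dtype=float))

    def relative_volume_h(self, t_hours) -> np.ndarray:
        """V(t)/V(0) with t in hours."""
        return np.exp(self.k_growth_per_day * np.asarray(t_hours, dtype=float) / 24.0)


def growth_dilution_correction(tc: TissueTimeCourse, gm: GrowthModel) -> TissueTimeCourse:
    """Correct a tumor concentration curve for growth dilution.

    C'(t) = C(t) · V(t)/V(0).  At constant total tumor activity the measured
    %ID/g falls simply because the mass grows; the corrected curve is the
    concentration a non-growing tumor of the injection-day mass would show,
    which is what belongs in the dose integral for a reference-mass lesion.
    A negative growth rate (shrinking control) is allowed with a warning.
    """
    if gm.k_growth_per_day < 0:
        warnings.warn(
            f"negative growth rate {gm.k_growth_per_day}/d: correction shrinks the curve",
            stacklevel=2,
        )
    factors = gm.relative_volume_h(tc.times)
    return TissueTimeCourse(
        tissue=tc.tissue,
        times_h=tc.times_h,
        values=tuple(
            tuple(f * x for x in vals) for f, vals in zip(factors, tc.values)
        ),
        blocked=tc.blocked,
    )


class ExponentialGrowthModel:
    """Exponential growth fitted to caliper volumes by log-linear regression.

    Zero volumes are excluded from the fit (log-undefined); at least two
    positive measurements are required.
    """

    def __init__(self, times_d, volumes_mm3):
        t = np.asarray(times_d, dtype=float)
        v = np.asarray(volumes_mm3, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and volumes must be 1-D arrays of equal length")
        pos = v > 0
        if pos.sum() < 2:
            raise ValueError("need at least two positive volumes to fit growth")
        self.times_d = t[pos]
        self.volumes_mm3 = v[pos]

    def fit(self) -> "GrowthFitResults":
        k, logv0 = np.polyfit(self.times_d, np.log(self.volumes_mm3), 1)
        resid = np.log(self.volumes_mm3) - (k * self.times_d + logv0)
        return GrowthFitResults(
            v0_mm3=float(np.exp(logv0)),
            k_growth_per_day=float(k),
            rss_log=float(np.sum(resid**2)),
            nobs=self.times_d.size,
        )


@dataclass(frozen=True)
class GrowthFitResults:
    v0_mm3: float
    k_growth_per_day: float
    rss_log: float
    nobs: int

    @property
    def doubling_time_d(self) -> float:
        return np.log(2.0) / self.k_growth_per_day if self.k_growth_per_day > 0 else np.inf

    def as_growth_model(self) -> GrowthModel:
        return GrowthModel(v0_mm3=self.v0_mm3, k_growth_per_day=self.k_growth_per_day)

    def summary(self) -> str:
        return (
            "Exponential tumor growth fit\n"
            "============================\n"
            f"v0 (mm^3)          {self.v0_mm3:12.4g}\n"
            f"k_growth (1/d)     {self.k_growth_per_day:12.4g}\n"
            f"doubling time (d)  {self.doubling_time_d:12.4g}\n"
            f"n obs              {self.nobs:12d}\n"
            f"RSS (log scale)    {self.rss_log:12.4g}"
        )
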
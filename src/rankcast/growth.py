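"""Gompertz growth-curve fitting and growth-parameter extraction.

Plate-reader OD600 trajectories are fitted with the modified (Zwietering)
Gompertz model

    y(t) = A * exp(-exp(mu_max * e / A * (lam - t) + 1))

whose three parameters are the asymptotic yield ``A`` (OD units), the maximum
growth rate ``mu_max`` (OD h^-1) and the lag phase ``lam`` (h).  From a fit,
three integrative growth parameters are derived:

* ``mu_max`` itself,
* the area under the fitted curve over the observation window (AUC, OD h),
* the inverse of the time to mid-exponential phase,
  ``1/T_mid = 1 / (A / (2 mu_max) + lam)`` (h^-1), which combines lag, rate
  and yield so that larger values always mean better growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import curve_fit

__all__ = [
    "GrowthCurve",
    "GompertzFit",
    "GrowthParams",
    "GrowthModelError",
    "gompertz",
    "fit_gompertz",
    "inv_tmid",
    "auc",
    "extract_growth_params",
    "read_plate_csv",
    "fit_plate",
    "write_params_csv",
]

#: default observation window (hours)
DEFAULT_WINDOW = (0.0, 36.0)

#: fits with asymptotic yield below this OD are flagged non-growing
MIN_YIELD = 0.05

#: minimum number of time points for a fittable curve
MIN_POINTS = 8

PLATE_COLUMNS = ["time_h", "od", "species", "replicate", "medium", "treatment", "block"]


class GrowthModelError(ValueError):
    """Structured error for invalid growth-curve inputs."""


@dataclass
class GrowthCurve:
    """One well's OD600 time series.

    ``treatment`` is ``"plain"`` for ordinary monocultures, ``"control"`` for
    the NaCl control of a supernatant assay, or ``"supernatant:<producer>"``
    for conditioned-medium treatments.
    """

    species: str
    replicate: str
    medium: str = "GIM"
    treatment: str = "plain"
    times: np.ndarray = field(default_factory=lambda: np.array([]))
    od: np.ndarray = field(default_factory=lambda: np.array([]))
    block: str = "1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)

    def validate(self) -> None:
        if self.times.size != self.od.size:
            raise GrowthModelError(
                f"times and od differ in length ({self.times.size} vs {self.od.size})"
            )
        if self.times.size < MIN_POINTS:
            raise GrowthModelError(
                f"curve has {self.times.size} points; at least {MIN_POINTS} required"
            )
        if not np.all(np.isfinite(self.od)):
            raise GrowthModelError("non-finite OD values in curve")
        if not np.all(np.diff(self.times) > 0):
            raise GrowthModelError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise GrowthModelError("negative times in curve")


@dataclass
class GompertzFit:
    A: float
    mu_max: float
    lam: float
    converged: bool
    residual_rms: float = float("nan")
    reason: str = ""


@dataclass
class GrowthParams:
    mu_max: float
    auc: float
    inv_tmid: float


def gompertz(t, A: float, mu_max: float, lam: float):
    """Modified Gompertz model evaluated at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    return A * np.exp(-np.exp(mu_max * math.e / A * (lam - t) + 1.0))


def _initial_guess(times: np.ndarray, od: np.ndarray) -> tuple[float, float, float]:
    A0 = float(np.max(od))
    slopes = np.diff(od) / np.diff(times)
    mu0 = float(np.max(slopes)) if np.any(np.isfinite(slopes)) else 0.1
    mu0 = min(max(mu0, 1e-3), 10.0)
    above = np.nonzero(od >= 0.1 * A0)[0]
    lam0 = float(times[above[0]]) if above.size else 0.0
    return max(A0, 1e-3), mu0, min(lam0, 36.0)


def fit_gompertz(curve: GrowthCurve, blank_correct: bool = True) -> GompertzFit:
    """Least-squares Gompertz fit of one growth curve.

    Blank handling: the minimum of the first three OD readings is subtracted
    and the signal floored at 1e-4 before fitting.  A fit that fails to
    converge, or whose yield lands below ``MIN_YIELD``, is returned with
    ``converged=False`` (non-growing well).
    """
    curve.validate()
    od = curve.od.astype(float)
    if blank_correct:
        od = np.maximum(od - float(np.min(od[:3])), 1e-4)
    times = curve.times

    p0 = _initial_guess(times, od)
    bounds = ([1e-6, 1e-6, 0.0], [10.0, 10.0, 36.0])
    try:
        popt, _ = curve_fit(gompertz, times, od, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return GompertzFit(
            float("nan"), float("nan"), float("nan"), False, reason=f"fit failed: {exc}"
        )
    A, mu, lam = (float(v) for v in popt)
    rms = float(np.sqrt(np.mean((gompertz(times, A, mu, lam) - od) ** 2)))
    if A < MIN_YIELD:
        return GompertzFit(A, mu, lam, False, rms, reason="no growth (A below floor)")
    return GompertzFit(A, mu, lam, True, rms)


def inv_tmid(fit: GompertzFit) -> float:
    """Inverse time to mid-exponential phase, 1 / (A/(2 mu_max) + lam)."""
    if not fit.converged:
        raise GrowthModelError(f"inv_tmid requires a converged fit ({fit.reason})")
    return 1.0 / (fit.A / (2.0 * fit.mu_max) + fit.lam)


def auc(
    curve: GrowthCurve | None,
    fit: GompertzFit,
    window: tuple[float, float] | None = None,
    on_raw: bool = False,
) -> float:
    """Area under the growth curve over the observation window (OD h).

    By default the integral of the *fitted* Gompertz curve is evaluated by
    adaptive quadrature.  ``on_raw=True`` instead integrates the raw OD data
    with the trapezoid rule (offered for comparison; the fitted integral is
    the canonical readout).
    """
    if on_raw:
        if curve is None or curve.times.size < 2:
            raise GrowthModelError("raw AUC requires a curve with >= 2 points")
        return float(np.trapezoid(curve.od, curve.times))
    if not fit.converged:
        raise GrowthModelError(f"auc requires a converged fit ({fit.reason})")
    if window is None:
        if curve is not None and curve.times.size:
            window = (float(curve.times[0]), float(curve.times[-1]))
        else:
            window = DEFAULT_WINDOW
    t0, t1 = window
    if not t1 > t0:
        raise GrowthModelError(f"empty integration window ({t0}, {t1})")
    value, _ = quad(lambda t: gompertz(t, fit.A, fit.mu_max, fit.lam), t0, t1, limit=200)
    return float(value)


def extract_growth_params(
    curve: GrowthCurve, window: tuple[float, float] | None = None
) -> GrowthParams:
    """Fit one curve and bundle mu_max, AUC and 1/T_mid.

    Raises :class:`GrowthModelError` for non-growing or unfittable wells so
    that callers can exclude them from parameter tables.
    """
    fit = fit_gompertz(curve)
    if not fit.converged:
        raise GrowthModelError(f"well {curve.species}/{curve.replicate}: {fit.reason}")
    return GrowthParams(
        mu_max=fit.mu_max, auc=auc(curve, fit, window=window), inv_tmid=inv_tmid(fit)
    )


# ---------------------------------------------------------------------------
# plate I/O


def read_plate_csv(path) -> list[GrowthCurve]:
    """Read a long-format plate CSV into per-well :class:`GrowthCurve` objects.

    Required columns: time_h, od, species, replicate, medium, treatment, block.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise GrowthModelError(f"plate CSV {path}: missing columns {missing}")
    curves = []
    keys = ["species", "replicate", "medium", "treatment", "block"]
    for (sp, rep, med, trt, blk), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                species=str(sp),
                replicate=str(rep),
                medium=str(med),
                treatment=str(trt),
                times=grp["time_h"].to_numpy(),
                od=grp["od"].to_numpy(),
                block=str(blk),
            )
        )
    return curves


def fit_plate(
    curves: list[GrowthCurve], window: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Fit every well and tabulate per-replicate growth parameters.

    Non-growing / non-converged wells are kept with ``converged=False`` and
    NaN parameters so they can be inspected, but downstream scoring excludes
    them.
    """
    rows = []
    for c in curves:
        fit = fit_gompertz(c)
        row = {
            "species": c.species,
            "replicate": c.replicate,
            "medium": c.medium,
            "treatment": c.treatment,
            "block": c.block,
            "converged": fit.converged,
            "A": fit.A,
            "mu_max": fit.mu_max,
            "lam": fit.lam,
            "residual_rms": fit.residual_rms,
        }
        if fit.converged:
            row["inv_tmid"] = inv_tmid(fit)
            row["auc"] = auc(c, fit, window=window)
        else:
            row["inv_tmid"] = float("nan")
            row["auc"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def write_params_csv(params: pd.DataFrame, path) -> None:
    params.to_csv(path, index=False, float_format="%.10g")
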
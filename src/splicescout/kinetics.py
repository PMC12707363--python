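"""Pseudo-first-order trans-splicing kinetics and SEC molecular-weight
calibration.

Under pseudo-first-order conditions (Int^C precursor in excess over the
limiting Int^N precursor), splice-product formation follows the one-phase
exponential

    SP(t) = SP_max * (1 - exp(-k t)),

with rate constant k (s^-1), plateau SP_max, half-life t_1/2 = ln(2)/k and
splicing efficiency E = SP_max / P_N0 relative to the limiting precursor.
No delay/offset term is fitted by default (SP(0) = 0 is forced); an offset
can be enabled with ``with_offset=True`` for traces with a baseline.

Size-exclusion chromatography (SEC) calibration fits retention time against
molecular weight, either on a log10(MW) scale (the standard column law) or
linearly; species eluting at or before the void time are reported as lower
bounds on MW.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

MAX_ITER = 10_000
PARAM_TOL = 1e-10


@dataclass(frozen=True)
class SpliceTimeCourse:
    """A splice-product time course.

    ``times`` in seconds, strictly increasing, at least 4 points for
    fitting; ``sp`` is the splice-product signal, either a fraction of the
    initial limiting precursor (densitometry) or a concentration when
    ``pn0`` (uM) is given. ``cleavage`` optionally carries the C-cleavage
    side-product signal; it is reported, never modelled.
    """

    times: np.ndarray
    sp: np.ndarray
    pn0: Optional[float] = None
    cleavage: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.sp, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "sp", s)
        if len(t) != len(s):
            raise ValueError("times and sp must have equal length")
        if len(t) and t[0] < 0:
            raise ValueError("times must be non-negative")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(s < 0):
            raise ValueError("sp must be non-negative")


@dataclass(frozen=True)
class KineticsFit:
    """Fitted one-phase exponential parameters."""

    k: float  # s^-1
    sp_max: float
    t_half: float  # s; ln(2)/k exactly
    rmse: float
    k_stderr: float
    sp_max_stderr: float
    efficiency: Optional[float] = None
    offset: float = 0.0


class FitError(RuntimeError):
    """The one-phase exponential could not be fitted to the data."""


def _model(t: np.ndarray, sp_max: float, k: float, c: float = 0.0) -> np.ndarray:
    return sp_max * (1.0 - np.exp(-k * t)) + c


def _jacobian(t: np.ndarray, sp_max: float, k: float) -> np.ndarray:
    e = np.exp(-k * t)
    return np.column_stack([1.0 - e, sp_max * t * e])


def _k_init_heuristic(t: np.ndarray, sp: np.ndarray) -> float:
    """ln(2) / (time at half of the maximum signal)."""
    half = sp.max() / 2.0
    above = np.nonzero(sp >= half)[0]
    t_half_obs = t[above[0]] if len(above) and t[above[0]] > 0 else t[t > 0][0]
    return math.log(2.0) / t_half_obs


def fit_one_phase(
    tc: SpliceTimeCourse,
    k_init: Optional[float] = None,
    seed: int = 0,
    with_offset: bool = False,
) -> KineticsFit:
    """Fit SP(t) = SP_max (1 - e^{-kt}) by nonlinear least squares.

    Uses the analytic gradient, a relative parameter-change tolerance of
    1e-10 and at most 10^4 model evaluations; failure to converge within
    those limits raises rather than returning an unconverged fit. ``k_init``
    defaults to the ln(2)/t-at-half-max heuristic. The ``seed`` argument is
    accepted for interface uniformity; the deterministic least-squares path
    consumes no randomness.

    Raises :class:`FitError` for data incompatible with a rising
    exponential (best-fit k <= 0, e.g. constant-zero or decreasing traces),
    and ``ValueError`` for fewer than 4 points.
    """
    t, sp = tc.times, tc.sp
    if len(t) < 4:
        raise ValueError(f"need >= 4 time points, got {len(t)}")
    if sp.max() <= 0:
        raise FitError("signal never rises above 0: best-fit k <= 0")
    if np.corrcoef(t, sp)[0, 1] <= 0:
        raise FitError(
            "signal does not increase with time: incompatible with a rising "
            "exponential (best-fit k <= 0)"
        )
    k0 = k_init if k_init is not None else _k_init_heuristic(t, sp)
    p0 = [sp.max(), k0] + ([0.0] if with_offset else [])
    if with_offset:
        fun = lambda tt, a, k, c: _model(tt, a, k, c)
        jac = None
    else:
        fun = lambda tt, a, k: _model(tt, a, k)
        jac = _jacobian
    try:
        popt, pcov = optimize.curve_fit(
            fun, t, sp, p0=p0, jac=jac, maxfev=MAX_ITER, xtol=PARAM_TOL,
            ftol=PARAM_TOL, gtol=PARAM_TOL,
        )
    except RuntimeError as exc:
        raise FitError(f"one-phase fit did not converge: {exc}") from exc
    sp_max, k = float(popt[0]), float(popt[1])
    offset = float(popt[2]) if with_offset else 0.0
    if k <= 0 or sp_max <= 0:
        raise FitError(
            f"fitted parameters non-physical (SP_max={sp_max:.3g}, k={k:.3g})"
        )
    resid = sp - fun(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    perr = np.sqrt(np.diag(pcov))
    fit = KineticsFit(
        k=k,
        sp_max=sp_max,
        t_half=half_life(k),
        rmse=rmse,
        k_stderr=float(perr[1]),
        sp_max_stderr=float(perr[0]),
        efficiency=None,
        offset=offset,
    )
    if tc.pn0 is not None:
        from dataclasses import replace

        fit = replace(fit, efficiency=splicing_efficiency(fit, tc.pn0))
    return fit


def half_life(k: float) -> float:
    """First-order half-life ln(2)/k in seconds."""
    if k <= 0:
        raise ValueError(f"rate constant must be positive, got {k}")
    return math.log(2.0) / k


def splicing_efficiency(fit: KineticsFit, pn0: float) -> float:
    """Splicing efficiency SP_max / P_N0 as a fraction of the limiting
    precursor. Warns above 1.0 and clips at 1.2 (values beyond that indicate
    a calibration problem, not chemistry)."""
    if pn0 <= 0:
        raise ValueError(f"pn0 must be positive, got {pn0}")
    eff = fit.sp_max / pn0
    if eff > 1.05:
        warnings.warn(
            f"efficiency {eff:.2f} exceeds 1.05: check signal normalisation",
            stacklevel=2,
        )
    elif eff > 1.0:
        warnings.warn(f"efficiency {eff:.2f} slightly above 1", stacklevel=2)
    return min(eff, 1.2)


# --- SEC calibration --------------------------------------------------------

LOG_MODE = "log_mw_linear"
LINEAR_MODE = "mw_linear"


@dataclass(frozen=True)
class SecCalibration:
    """Linear SEC calibration: transform(MW) = slope * retention + intercept,
    where the transform is log10 (``log_mw_linear``) or identity
    (``mw_linear``)."""

    mode: str
    slope: float
    intercept: float
    r_squared: float
    points: pd.DataFrame = field(repr=False)
    void_time: Optional[float] = None


@dataclass(frozen=True)
class MwEstimate:
    """A predicted molecular weight; ``lower_bound`` flags species at or
    before the void volume, whose true MW is at least ``mw_kda``."""

    mw_kda: float
    lower_bound: bool = False

    def __str__(self) -> str:
        return (">= " if self.lower_bound else "") + f"{self.mw_kda:.1f} kDa"


def sec_calibrate(
    points: Sequence[tuple[float, float]],
    mode: str = LOG_MODE,
    void_time: Optional[float] = None,
) -> SecCalibration:
    """Fit a linear SEC calibration from (MW in kDa, retention in min) pairs.

    Requires >= 3 standards; duplicate retention times with different MW are
    rejected (the column cannot resolve them and the fit would be arbitrary).
    """
    df = pd.DataFrame(points, columns=["mw_kda", "retention_min"])
    if len(df) < 3:
        raise ValueError("need >= 3 calibration standards")
    if (df["retention_min"] <= 0).any():
        raise ValueError("retention times must be positive")
    dup = df.groupby("retention_min")["mw_kda"].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index.tolist()
        raise ValueError(f"duplicate retention times with different MW: {bad}")
    if mode == LOG_MODE:
        yvals = np.log10(df["mw_kda"].to_numpy())
    elif mode == LINEAR_MODE:
        yvals = df["mw_kda"].to_numpy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.linregress(df["retention_min"].to_numpy(), yvals)
    return SecCalibration(
        mode=mode,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        points=df,
        void_time=void_time,
    )


def sec_predict_mw(cal: SecCalibration, retention_time: float) -> MwEstimate:
    """Invert the calibration at a retention time.

    At or before the void time the column no longer separates, so the value
    predicted at the void time is returned flagged as a lower bound.
    """
    if retention_time <= 0:
        raise ValueError("retention time must be positive")
    lower = cal.void_time is not None and retention_time <= cal.void_time
    rt = cal.void_time if lower else retention_time
    yhat = cal.slope * rt + cal.intercept
    mw = 10.0**yhat if cal.mode == LOG_MODE else yhat
    return MwEstimate(mw_kda=float(mw), lower_bound=lower)


# --- CSV I/O ----------------------------------------------------------------


def read_timecourse_csv(path, pn0: Optional[float] = None) -> SpliceTimeCourse:
    """Read a time course CSV with columns time_s, sp[, cleavage]."""
    df = pd.read_csv(path)
    if not {"time_s", "sp"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns time_s, sp")
    return SpliceTimeCourse(
        times=df["time_s"].to_numpy(dtype=float),
        sp=df["sp"].to_numpy(dtype=float),
        pn0=pn0,
        cleavage=df["cleavage"].to_numpy(dtype=float)
        if "cleavage" in df.columns
        else None,
    )


def read_sec_csv(path) -> list[tuple[float, float]]:
    """Read SEC standards CSV with columns mw_kda, retention_min."""
    df = pd.read_csv(path)
    if not {"mw_kda", "retention_min"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns mw_kda, retention_min")
    return list(zip(df["mw_kda"].astype(float), df["retention_min"].astype(float)))
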
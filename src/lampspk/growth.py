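"""Richards growth-curve machinery.

Real-time isothermal amplification curves are sigmoidal and are fitted here
with the Richards/logistic form

    y(t) = k / (1 + exp(-b (t - m)))

where ``k`` is the plateau (signal or copies at infinite time), ``b`` the
maximum slope parameter (1/min) and ``m`` the time of maximum growth rate
(min).  The rise time (time-to-positive) is ``Tp = m - 2/b``.

The simulated copies-vs-time curves can only be computed out to modest
reaction times, so the module also fits the time-dependence of (k, b, m)
across growing fit windows and extrapolates them to predict rise times
beyond the simulated horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RichardsParams",
    "AmplificationCurve",
    "FitError",
    "FitReport",
    "ParamTrend",
    "richards",
    "fit_richards",
    "rise_time",
    "fit_growing_windows",
    "extrapolate_params",
    "predict_rise_time_from_curve",
    "make_synthetic_curve",
    "read_curve_csv",
    "write_curve_csv",
    "fit_replicates",
]


class FitError(RuntimeError):
    """Raised when a curve cannot be fitted (degenerate data, no convergence)."""


@dataclass(frozen=True)
class RichardsParams:
    k: float  # plateau (copies or fluorescence units)
    b: float  # maximum slope parameter (1/min)
    m: float  # time of maximum growth rate (min)

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.b > 0 and self.m > 0):
            raise ValueError(f"Richards parameters must be positive, got {self}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.k, self.b, self.m)


@dataclass
class AmplificationCurve:
    """An ordered (time, signal) series; times in minutes, signal >= 0."""

    time_min: np.ndarray
    signal: np.ndarray
    source: str = "simulated"  # simulated | experimental | synthetic-fixture
    replicate: Optional[str] = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_min.ndim != 1 or self.time_min.shape != self.signal.shape:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")

    def __len__(self) -> int:
        return len(self.time_min)

    def window(self, t_max: float) -> "AmplificationCurve":
        mask = self.time_min <= t_max
        return AmplificationCurve(
            self.time_min[mask], self.signal[mask], self.source, self.replicate
        )


def richards(t, p: RichardsParams):
    """Evaluate the Richards sigmoid at time ``t`` (minutes)."""
    t = np.asarray(t, dtype=float)
    z = np.clip(-p.b * (t - p.m), -700.0, 700.0)
    return p.k / (1.0 + np.exp(z))


@dataclass
class FitReport:
    rss: float
    rmse: float
    r_squared: float
    n_points: int


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    k0 = float(y.max())
    half = k0 / 2.0
    above = np.nonzero(y >= half)[0]
    m0 = float(t[above[0]]) if above.size else float(t[len(t) // 2])
    dy = np.gradient(y, t)
    slope = float(dy.max())
    # max slope of the Richards curve is k·b/4
    b0 = max(4.0 * slope / k0, 1e-6) if k0 > 0 else 1.0
    return k0, b0, max(m0, float(t[0]) + 1e-9)


def fit_richards(
    curve: AmplificationCurve,
    init: Optional[RichardsParams] = None,
) -> tuple[RichardsParams, FitReport]:
    """Least-squares Richards fit of one amplification curve.

    Initialisation (unless ``init`` is given): k from the maximum signal, m
    from the time of half-maximum, b from the steepest observed slope — so
    fits are deterministic and reproducible.  Degenerate input (fewer than
    four points, constant signal) and non-convergence raise :class:`FitError`.
    """
    t, y = curve.time_min, curve.signal
    if len(t) < 4:
        raise FitError(f"need >= 4 points to fit, got {len(t)}")
    if np.allclose(y, y[0]):
        raise FitError("signal is constant; no sigmoid to fit")
    p0 = init.as_tuple() if init is not None else _initial_guess(t, y)

    def model(tt, k, b, m):
        z = np.clip(-b * (tt - m), -700.0, 700.0)
        return k / (1.0 + np.exp(z))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model,
                t,
                y,
                p0=p0,
                bounds=([1e-300, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Richards fit did not converge: {exc} (p0={p0})") from exc

    params = RichardsParams(*map(float, popt))
    resid = y - model(t, *popt)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    report = FitReport(
        rss=rss,
        rmse=float(np.sqrt(rss / len(t))),
        r_squared=1.0 - rss / tss if tss > 0 else float("nan"),
        n_points=len(t),
    )
    return params, report


def rise_time(p: RichardsParams, *, formula: str = "m-2/b") -> float:
    """Time-to-positive Tp in minutes.

    The standard definition is ``Tp = m - 2/b`` (the onset of the
    exponential rise).  ``formula="m-2b"`` computes the literal alternative
    reading for sensitivity analysis.
    """
    if p.b == 0:
        raise ValueError("Tp is undefined for b = 0")
    if formula == "m-2/b":
        return p.m - 2.0 / p.b
    if formula == "m-2b":
        return p.m - 2.0 * p.b
    raise ValueError(f"unknown Tp formula {formula!r}")


# ---------------------------------------------------------------------------------
# parameter trends across reaction-time windows


_FAMILIES: dict[str, tuple[Callable, int]] = {
    # name -> (model(t, *coef), n_coef)
    "constant": (lambda t, a: np.full_like(np.asarray(t, float), a), 1),
    "linear": (lambda t, a, c: a * np.asarray(t, float) + c, 2),
    "quadratic": (lambda t, a, c, d: a * np.asarray(t, float) ** 2
                  + c * np.asarray(t, float) + d, 3),
    "exponential": (lambda t, a, c: a * np.exp(np.clip(c * np.asarray(t, float),
                                                       -700, 700)), 2),
    "power": (lambda t, a, c: a * np.power(np.maximum(np.asarray(t, float), 1e-12), c), 2),
}


@dataclass
class _TrendFit:
    family: str
    coef: tuple[float, ...]
    aic: float

    def __call__(self, t):
        return _FAMILIES[self.family][0](t, *self.coef)


@dataclass
class ParamTrend:
    """Fitted time-dependence of the Richards parameters across t_R.

    Each of k, b, m gets its own functional family, selected by AIC among
    constant/linear/quadratic/exponential/power (restricted to families that
    converge).  Evaluation at any t_R at or beyond the first fitted window
    returns a full parameter set; non-positive extrapolations trigger a
    warning and raise.
    """

    trends: dict[str, _TrendFit]
    t_fitted: np.ndarray
    diagnostics: pd.DataFrame = field(default=None, repr=False)

    def evaluate(self, t_R: float) -> RichardsParams:
        if t_R < self.t_fitted.min():
            raise ValueError(
                f"t_R={t_R} is below the fitted range starting {self.t_fitted.min()}"
            )
        values = {name: float(trend(t_R)) for name, trend in self.trends.items()}
        if any(v <= 0 for v in values.values()):
            warnings.warn(
                f"extrapolated Richards parameters non-positive at t_R={t_R}: {values}",
                RuntimeWarning,
                stacklevel=2,
            )
        return RichardsParams(values["k"], values["b"], values["m"])

    def to_dict(self) -> dict:
        return {
            name: {"family": tr.family, "coef": list(tr.coef), "aic": tr.aic}
            for name, tr in self.trends.items()
        }


def _fit_trend(t: np.ndarray, y: np.ndarray) -> _TrendFit:
    best: Optional[_TrendFit] = None
    n = len(t)
    for name, (func, n_coef) in _FAMILIES.items():
        if n <= n_coef:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if name == "exponential":
                    # log-space seed keeps the optimizer on the growth branch
                    sign = np.sign(y.mean()) or 1.0
                    ly = np.log(np.maximum(np.abs(y), 1e-300))
                    c0, la0 = np.polyfit(t, ly, 1)
                    p0 = [sign * np.exp(la0), c0]
                else:
                    p0 = np.ones(n_coef)
                coef, _ = curve_fit(func, t, y, p0=p0, maxfev=20000)
        except (RuntimeError, ValueError, TypeError):
            continue
        rss = float(np.sum((y - func(t, *coef)) ** 2))
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * n_coef
        fit = _TrendFit(name, tuple(map(float, coef)), aic)
        if best is None or fit.aic < best.aic:
            best = fit
    if best is None:
        raise FitError("no trend family could be fitted")
    return best


def extrapolate_params(
    fits: Sequence[tuple[float, RichardsParams]],
) -> ParamTrend:
    """Fit time-dependent equations for k, b, m over the fitted t_R values."""
    if len(fits) < 3:
        raise FitError(f"need >= 3 fitted windows to extrapolate, got {len(fits)}")
    t = np.array([f[0] for f in fits], dtype=float)
    trends = {}
    rows = []
    for name, getter in (("k", lambda p: p.k), ("b", lambda p: p.b),
                         ("m", lambda p: p.m)):
        y = np.array([getter(p) for _, p in fits], dtype=float)
        trend = _fit_trend(t, y)
        trends[name] = trend
        rows.append({"param": name, "family": trend.family, "aic": trend.aic,
                     "coef": list(trend.coef)})
    return ParamTrend(trends=trends, t_fitted=t,
                      diagnostics=pd.DataFrame(rows))


def fit_growing_windows(
    curve: AmplificationCurve,
    t_windows: Iterable[float],
    *,
    min_points: int = 4,
) -> list[tuple[float, RichardsParams]]:
    """Richards fits of the curve truncated at each window end.

    Mirrors running the simulator to successive reaction times and fitting
    the copies-vs-time trace available at each: the parameters drift with
    the window until the sigmoid is fully contained.
    """
    fits = []
    for t_R in t_windows:
        sub = curve.window(t_R)
        if len(sub) < min_points:
            continue
        try:
            params, _ = fit_richards(sub)
        except FitError:
            continue
        fits.append((float(t_R), params))
    if not fits:
        raise FitError("no window produced a successful fit")
    return fits


def predict_rise_time_from_curve(
    curve: AmplificationCurve,
    t_windows: Sequence[float],
    horizon_min: float,
    *,
    formula: str = "m-2/b",
) -> tuple[float, ParamTrend]:
    """Growing-window fits -> parameter trends -> Tp at the horizon."""
    fits = fit_growing_windows(curve, t_windows)
    trend = extrapolate_params(fits)
    params = trend.evaluate(horizon_min)
    return rise_time(params, formula=formula), trend


# ---------------------------------------------------------------------------------
# fixtures and I/O


def make_synthetic_curve(
    p: RichardsParams,
    noise_sd: float,
    n_points: int,
    seed: int,
    *,
    t_max: Optional[float] = None,
) -> AmplificationCurve:
    """Reproducible noisy Richards curve (Gaussian noise, clipped at zero)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_points < 2:
        raise ValueError("need at least two points")
    rng = np.random.default_rng(seed)
    t_end = t_max if t_max is not None else p.m + 4.0 / p.b
    t = np.linspace(0.0, t_end, n_points)
    y = richards(t, p)
    if noise_sd > 0:
        y = np.clip(y + rng.normal(0.0, noise_sd, size=n_points), 0.0, None)
    return AmplificationCurve(t, y, source="synthetic-fixture")


def read_curve_csv(path_or_text: str | Path) -> list[AmplificationCurve]:
    """Read amplification curves from CSV (columns time_min, signal and an
    optional replicate column; header case-insensitive)."""
    if isinstance(path_or_text, Path) or "\n" not in str(path_or_text):
        df = pd.read_csv(path_or_text)
    else:
        df = pd.read_csv(StringIO(str(path_or_text)))
    df.columns = [c.strip().lower() for c in df.columns]
    if "time_min" not in df.columns or "signal" not in df.columns:
        raise ValueError("curve CSV needs columns time_min and signal")
    if "replicate" in df.columns:
        return [
            AmplificationCurve(
                g["time_min"].to_numpy(), g["signal"].to_numpy(),
                source="experimental", replicate=str(name),
            )
            for name, g in df.groupby("replicate", sort=True)
        ]
    return [AmplificationCurve(df["time_min"].to_numpy(), df["signal"].to_numpy(),
                               source="experimental")]


def write_curve_csv(curves: Sequence[AmplificationCurve], path: str | Path) -> None:
    frames = []
    for i, c in enumerate(curves):
        frame = pd.DataFrame({"time_min": c.time_min, "signal": c.signal})
        frame["replicate"] = c.replicate if c.replicate is not None else str(i)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def fit_replicates(
    curves: Sequence[AmplificationCurve],
    *,
    formula: str = "m-2/b",
) -> pd.DataFrame:
    """Per-replicate Richards fits with Tp; mean and SD rows appended."""
    rows = []
    for c in curves:
        params, report = fit_richards(c)
        rows.append({
            "replicate": c.replicate,
            "k": params.k, "b": params.b, "m": params.m,
            "Tp_min": rise_time(params, formula=formula),
            "rmse": report.rmse,
        })
    df = pd.DataFrame(rows)
    df.attrs["Tp_mean"] = float(df["Tp_min"].mean())
    df.attrs["Tp_sd"] = float(df["Tp_min"].std(ddof=1)) if len(df) > 1 else 0.0
    return df
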
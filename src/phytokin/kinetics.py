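"""First-order thermal degradation kinetics.

The working model is C(t) = C0 * exp(-k t): the response (an anthocyanin
content, an antioxidant activity) decays exponentially at a temperature-
specific rate k. Fitting is done on the linearized form ln(C/C0) = -k t by
ordinary least squares, the convention in thermal-processing studies. Derived
per-temperature parameters are the half-life t1/2 = ln2/k and the decimal
reduction time D = ln10/k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, UndefinedResultError, ValidationError

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)
LN10 = math.log(10.0)

FitMethod = Literal["free_intercept", "through_origin", "nonlinear"]
C0Policy = Literal["per_replicate", "replicate_mean"]


@dataclass(frozen=True)
class Observation:
    """One measured response at one time point in one replicate tube."""

    time_min: float
    response: float
    replicate: int


@dataclass
class DegradationSeries:
    """One analyte's response versus heating time at a single temperature.

    Parameters
    ----------
    analyte
        Label of the tracked quantity, e.g. ``"TAC"`` or
        ``"antioxidant_activity"``.
    temperature_c
        Heating temperature in °C.
    observations
        Measured (time, response, replicate) triples. Times in minutes,
        responses in arbitrary positive concentration units.
    """

    analyte: str
    temperature_c: float
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for obs in self.observations:
            if obs.time_min < 0:
                raise ValidationError(
                    f"negative time {obs.time_min} in series "
                    f"{self.analyte}@{self.temperature_c}°C"
                )

    @property
    def replicate_ids(self) -> list[int]:
        return sorted({obs.replicate for obs in self.observations})

    def replicate(self, rep: int) -> list[Observation]:
        return sorted(
            (o for o in self.observations if o.replicate == rep),
            key=lambda o: o.time_min,
        )

    @classmethod
    def from_arrays(
        cls,
        analyte: str,
        temperature_c: float,
        times: Sequence[float],
        responses: Sequence[float],
        replicates: Sequence[int] | None = None,
    ) -> "DegradationSeries":
        if replicates is None:
            replicates = [1] * len(times)
        if not (len(times) == len(responses) == len(replicates)):
            raise ValidationError("times, responses and replicates must align")
        obs = [
            Observation(float(t), float(r), int(rep))
            for t, r, rep in zip(times, responses, replicates)
        ]
        return cls(analyte=analyte, temperature_c=temperature_c, observations=obs)


@dataclass(frozen=True)
class FirstOrderFit:
    """Per-temperature first-order kinetic parameters.

    ``k`` is the mean rate constant across replicate fits (min^-1), ``k_sd``
    its standard deviation across replicates (nan for a single replicate) and
    ``k_se`` the regression standard error (mean across replicates). ``t_half``
    and ``d_value`` are derived from ``k`` and are nan when k <= 0.
    """

    analyte: str
    temperature_c: float
    k: float
    k_sd: float
    k_se: float
    r2: float
    t_half: float
    d_value: float
    n_points: int
    replicate_ks: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        # identity t_half * ln10 == d_value * ln2 must hold whenever defined
        if math.isfinite(self.t_half) and math.isfinite(self.d_value):
            assert math.isclose(
                self.t_half * LN10, self.d_value * LN2, rel_tol=1e-12
            ), "t_half/d_value identity violated"


def half_life(k: float) -> float:
    """Half-life t1/2 = ln2 / k (min) of a first-order decay.

    Raises
    ------
    UndefinedResultError
        If ``k <= 0`` (no decay: the half-life does not exist).
    """
    if k <= 0:
        raise UndefinedResultError(f"half-life undefined for k = {k}")
    return LN2 / k


def decimal_reduction(k: float) -> float:
    """Decimal reduction time D = ln10 / k (min): time for a tenfold drop."""
    if k <= 0:
        raise UndefinedResultError(f"D-value undefined for k = {k}")
    return LN10 / k


def predict_retention(k: float, t: float) -> float:
    """Fraction retained C/C0 = exp(-k t) after t minutes at rate k."""
    if t < 0:
        raise ValidationError(f"negative time t = {t}")
    if k < 0:
        raise ValidationError(f"negative rate constant k = {k}")
    return math.exp(-k * t)


def _fit_single(
    times: np.ndarray,
    responses: np.ndarray,
    method: FitMethod,
    c0: float,
) -> tuple[float, float, float]:
    """Fit one replicate. Returns (k, k_se, r2)."""
    y = np.log(responses / c0)
    if method == "free_intercept":
        res = stats.linregress(times, y)
        return -res.slope, res.stderr, res.rvalue**2
    if method == "through_origin":
        # OLS slope with zero intercept; R^2 about the mean for comparability
        sxx = float(np.dot(times, times))
        slope = float(np.dot(times, y)) / sxx
        resid = y - slope * times
        dof = max(len(y) - 1, 1)
        se = math.sqrt(float(np.dot(resid, resid)) / dof / sxx)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 1.0
        return -slope, se, max(min(r2, 1.0), 0.0)
    if method == "nonlinear":
        from scipy.optimize import curve_fit

        def model(t, c0_hat, k):
            return c0_hat * np.exp(-k * t)

        start = [c0, 0.01]
        popt, pcov = curve_fit(model, times, responses, p0=start, maxfev=10000)
        k = float(popt[1])
        k_se = float(np.sqrt(pcov[1, 1]))
        pred = model(times, *popt)
        ss_res = float(np.sum((responses - pred) ** 2))
        ss_tot = float(np.sum((responses - responses.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return k, k_se, max(min(r2, 1.0), 0.0)
    raise ValidationError(f"unknown fit method {method!r}")


def fit_first_order(
    series: DegradationSeries,
    method: FitMethod = "free_intercept",
    c0_policy: C0Policy = "per_replicate",
    pooled: bool = False,
) -> FirstOrderFit:
    """Fit the first-order model to one temperature's degradation series.

    Each replicate is fitted separately by OLS of ln(C/C0) on time (free
    intercept by default) and the rate constant is reported as the mean ± SD
    across replicates, matching how triplicate designs are summarized. With
    ``pooled=True`` all points enter a single regression instead.

    Parameters
    ----------
    series
        The degradation series; non-positive responses are excluded from the
        log-linear fit (with a warning) rather than floored.
    method
        ``free_intercept`` (default), ``through_origin`` or ``nonlinear``.
    c0_policy
        Reference for C0: the replicate's own t=0 measurement
        (``per_replicate``, default) or the mean t=0 across replicates.

    Raises
    ------
    InsufficientDataError
        If fewer than 3 positive-response time points remain in a replicate.
    """
    reps = series.replicate_ids
    if not reps:
        raise InsufficientDataError("series contains no observations")

    c0_mean = None
    if c0_policy == "replicate_mean":
        t0 = [o.response for o in series.observations if o.time_min == 0]
        if not t0:
            raise ValidationError("replicate_mean c0 policy requires t=0 points")
        c0_mean = float(np.mean(t0))

    def usable(rep: int) -> tuple[np.ndarray, np.ndarray]:
        pts = series.replicate(rep)
        t, r = [], []
        for o in pts:
            if o.response <= 0:
                logger.warning(
                    "excluding non-positive response %g at t=%g (rep %d, %s@%g°C)",
                    o.response, o.time_min, rep, series.analyte, series.temperature_c,
                )
                continue
            t.append(o.time_min)
            r.append(o.response)
        return np.asarray(t, dtype=float), np.asarray(r, dtype=float)

    if pooled:
        groups = [usable(rep) for rep in reps]
        times = np.concatenate([g[0] for g in groups])
        resp = np.concatenate([g[1] for g in groups])
        if len(np.unique(times)) < 3:
            raise InsufficientDataError(
                f"fewer than 3 usable time points at {series.temperature_c}°C"
            )
        c0 = c0_mean if c0_mean is not None else float(resp[times == times.min()].mean())
        k, k_se, r2 = _fit_single(times, resp, method, c0)
        ks = (k,)
        k_sd = math.nan
        n_points = len(times)
    else:
        ks_list, ses, r2s, n_points = [], [], [], 0
        for rep in reps:
            times, resp = usable(rep)
            if len(np.unique(times)) < 3:
                raise InsufficientDataError(
                    f"replicate {rep} has fewer than 3 usable time points "
                    f"at {series.temperature_c}°C"
                )
            if c0_mean is not None:
                c0 = c0_mean
            elif 0.0 in times:
                c0 = float(resp[times == 0.0][0])
            else:
                c0 = float(resp[np.argmin(times)])
            k_i, se_i, r2_i = _fit_single(times, resp, method, c0)
            ks_list.append(k_i)
            ses.append(se_i)
            r2s.append(r2_i)
            n_points += len(times)
        ks = tuple(ks_list)
        k = float(np.mean(ks))
        k_sd = float(np.std(ks, ddof=1)) if len(ks) > 1 else math.nan
        k_se = float(np.mean(ses))
        r2 = float(np.mean(r2s))

    if pooled:
        k = ks[0]

    t_half = LN2 / k if k > 0 else math.nan
    d_value = LN10 / k if k > 0 else math.nan
    return FirstOrderFit(
        analyte=series.analyte,
        temperature_c=series.temperature_c,
        k=k,
        k_sd=k_sd,
        k_se=k_se,
        r2=r2,
        t_half=t_half,
        d_value=d_value,
        n_points=n_points,
        replicate_ks=ks,
    )
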
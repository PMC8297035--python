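"""Model-assessment statistics for the regression estimators.

Covers goodness of fit (R^2, RMSE, MAE), the corrected Akaike information
criterion driven by the local-regression hat-matrix trace, categorical
exceedance verification (probability of detection / false alarm against the
90th-percentile threshold), and global Moran's I for residual spatial
autocorrelation with the analytic randomization test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "ContingencyCounts",
    "MetricsReport",
    "MoranResult",
    "r_squared",
    "rmse",
    "mae",
    "aicc",
    "aicc_components",
    "pod_pof",
    "morans_i",
    "evaluate_fit",
]

logger = logging.getLogger(__name__)


@dataclass
class ContingencyCounts:
    """Exceedance contingency relative to the 90th-percentile threshold.

    ``a``: joint exceedances (hit), ``b``: observed-only (miss),
    ``c``: estimated-only (false alarm).
    """

    a: int
    b: int
    c: int


@dataclass
class MoranResult:
    I: float
    z: float
    p: float
    pattern: str
    expected: float
    variance: float


@dataclass
class MetricsReport:
    """All assessment statistics of one fitted model on one evaluation set."""

    r2: float
    rmse: float
    mae: float
    aicc: float | None = None
    sigma_hat: float | None = None
    hat_trace: float | None = None
    pod: float | None = None
    pof: float | None = None
    morans_i: float | None = None
    morans_z: float | None = None
    morans_p: float | None = None
    morans_pattern: str | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _pair(observed, estimated, min_len=1):
    observed = np.asarray(observed, dtype=float).ravel()
    estimated = np.asarray(estimated, dtype=float).ravel()
    if observed.shape != estimated.shape:
        raise ValidationError("observed and estimated must have equal length")
    if observed.size < min_len:
        raise ValidationError(f"need at least {min_len} values, got {observed.size}")
    return observed, estimated


def r_squared(observed, estimated) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (SS_tot about the observed mean)."""
    observed, estimated = _pair(observed, estimated, min_len=2)
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedMetricError("R^2 undefined: observed series is constant")
    ss_res = float(np.sum((estimated - observed) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(observed, estimated) -> float:
    """Root mean squared error with divisor n."""
    observed, estimated = _pair(observed, estimated)
    return float(np.sqrt(np.mean((estimated - observed) ** 2)))


def mae(observed, estimated) -> float:
    """Mean absolute error with divisor n."""
    observed, estimated = _pair(observed, estimated)
    return float(np.mean(np.abs(estimated - observed)))


def aicc_components(n: int, sigma_hat: float, hat_trace: float) -> float:
    """AICc from its components: 2n ln(sigma) + n ln(2 pi) + n (n + tr S)/(n - 2 - tr S).

    ``tr S`` is the hat-matrix trace (effective number of parameters); the
    criterion diverges as ``tr S`` approaches ``n - 2`` and is undefined
    beyond it, which is signaled explicitly.
    """
    if n - 2 - hat_trace <= 0:
        raise UndefinedMetricError(
            f"AICc undefined: hat trace {hat_trace:.3f} >= n - 2 = {n - 2}"
        )
    if sigma_hat < 0:
        raise ValidationError("sigma_hat must be >= 0")
    log_sigma = -math.inf if sigma_hat == 0 else math.log(sigma_hat)
    return 2 * n * log_sigma + n * math.log(2 * math.pi) + n * (n + hat_trace) / (n - 2 - hat_trace)


def aicc(observed, fitted, hat_trace: float) -> float:
    """AICc of a fitted model; sigma is the maximum-likelihood residual scale sqrt(RSS/n)."""
    observed, fitted = _pair(observed, fitted, min_len=4)
    n = observed.size
    sigma = float(np.sqrt(np.mean((observed - fitted) ** 2)))
    return aicc_components(n, sigma, hat_trace)


def pod_pof(observed, estimated, percentile: float = 90.0):
    """Probability of detection and of false alarm for threshold exceedances.

    The threshold is the given percentile (default 90th, linear
    interpolation) of the observed series.  POD = a/(a+b) is undefined when
    the observed series never exceeds the threshold; POF = c/(a+c) is 0 by
    convention when no exceedance is ever estimated (no alarms, none false).

    Returns ``(pod, pof, ContingencyCounts)``.
    """
    observed, estimated = _pair(observed, estimated, min_len=2)
    thr = float(np.percentile(observed, percentile))
    obs_hi = observed > thr
    est_hi = estimated > thr
    a = int(np.sum(obs_hi & est_hi))
    b = int(np.sum(obs_hi & ~est_hi))
    c = int(np.sum(~obs_hi & est_hi))
    if a + b == 0:
        raise UndefinedMetricError("POD undefined: no observed exceedances above the threshold")
    pod = a / (a + b)
    if a + c == 0:
        logger.info("no estimated exceedances; POF defined as 0 (no alarms, none false)")
        pof = 0.0
    else:
        pof = c / (a + c)
    return pod, pof, ContingencyCounts(a=a, b=b, c=c)


def _inverse_distance_weights(coords) -> np.ndarray:
    """Row-standardized inverse-Euclidean-distance weights with zero diagonal.

    Coincident points would give infinite weight; their distance is floored
    at half the smallest positive pairwise distance, with a warning.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    off = ~np.eye(n, dtype=bool)
    pos = d[off & (d > 0)]
    if pos.size == 0:
        raise ValidationError("all locations coincide; spatial weights undefined")
    if np.any(d[off] == 0):
        floor = 0.5 * pos.min()
        logger.warning("coincident locations: flooring zero distances at %.6g", floor)
        d[off & (d == 0)] = floor
    with np.errstate(divide="ignore"):
        w = np.where(off, 1.0 / d, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def morans_i(residuals, coords, weights=None) -> MoranResult:
    """Global Moran's I of residuals with a randomization z-test.

    By default the spatial weights are row-standardized inverse Euclidean
    distance with zero diagonal; a precomputed (n, n) weight matrix may be
    supplied instead.  The z-score uses the analytic moments of I under
    random permutation of the values across locations, and the two-sided
    normal p-value.  The pattern label is "Clustered" (z > 1.96),
    "Dispersed" (z < -1.96) or "Random" otherwise.
    """
    z_vals = np.asarray(residuals, dtype=float).ravel()
    n = z_vals.size
    if n < 4:
        raise ValidationError("Moran's I requires at least 4 locations")
    zc = z_vals - z_vals.mean()
    m2 = float(np.sum(zc**2))
    if m2 == 0:
        raise UndefinedMetricError("Moran's I undefined: residuals have zero variance")
    W = _inverse_distance_weights(coords) if weights is None else np.asarray(weights, dtype=float)
    if W.shape != (n, n):
        raise ValidationError(f"weight matrix shape {W.shape} != {(n, n)}")

    s0 = float(W.sum())
    I = (n / s0) * float(zc @ W @ zc) / m2

    # Cliff-Ord randomization moments
    s1 = 0.5 * float(np.sum((W + W.T) ** 2))
    s2 = float(np.sum((W.sum(axis=1) + W.sum(axis=0)) ** 2))
    b2 = n * float(np.sum(zc**4)) / m2**2
    e_i = -1.0 / (n - 1)
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    den = (n - 1) * (n - 2) * (n - 3) * s0**2
    var_i = num / den - e_i**2
    if var_i <= 0:
        raise UndefinedMetricError("Moran's I variance non-positive under randomization")
    z = (I - e_i) / math.sqrt(var_i)
    p = 2 * float(stats.norm.sf(abs(z)))
    if z > 1.96:
        pattern = "Clustered"
    elif z < -1.96:
        pattern = "Dispersed"
    else:
        pattern = "Random"
    return MoranResult(I=I, z=z, p=p, pattern=pattern, expected=e_i, variance=var_i)


def evaluate_fit(
    observed,
    fitted,
    coords=None,
    hat_trace: float | None = None,
    percentile: float = 90.0,
) -> MetricsReport:
    """Assemble the full metrics report for one fitted model.

    AICc is included when ``hat_trace`` is given; Moran's I of the residuals
    when ``coords`` is given; POD/POF whenever the observed series has
    exceedances (otherwise left unset).
    """
    observed = np.asarray(observed, dtype=float).ravel()
    fitted = np.asarray(fitted, dtype=float).ravel()
    report = MetricsReport(
        r2=r_squared(observed, fitted),
        rmse=rmse(observed, fitted),
        mae=mae(observed, fitted),
    )
    if hat_trace is not None:
        report.hat_trace = float(hat_trace)
        report.sigma_hat = float(np.sqrt(np.mean((observed - fitted) ** 2)))
        report.aicc = aicc(observed, fitted, hat_trace)
    try:
        pod, pof, _ = pod_pof(observed, fitted, percentile)
        report.pod, report.pof = pod, pof
    except UndefinedMetricError:
        pass
    if coords is not None:
        mi = morans_i(observed - fitted, coords)
        report.morans_i, report.morans_z = mi.I, mi.z
        report.morans_p, report.morans_pattern = mi.p, mi.pattern
    return report
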
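"""Gaussian distance-decay weighting and AICc-driven bandwidth selection.

Local regression at a target location weights every sample by a fixed
Gaussian kernel of its Euclidean distance ``d`` to the target,

    w(d) = exp(-d^2 / b^2),

where the bandwidth ``b`` (in the same planar units as the coordinates,
typically meters) controls how quickly influence decays.  The bandwidth is
either supplied explicitly or chosen by minimizing the corrected Akaike
information criterion (AICc) of the resulting local fit over a bracketed
search interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GwtlsError, ValidationError

__all__ = [
    "KernelConfig",
    "BandwidthSearch",
    "gaussian_weight",
    "weight_matrix",
    "select_bandwidth",
]

logger = logging.getLogger(__name__)

#: weights below this are clamped before inversion into an observation
#: covariance (exact zeros would make the covariance undefined)
WEIGHT_FLOOR = 1e-12

_INV_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class KernelConfig:
    """Fixed Gaussian kernel specification.

    ``bandwidth`` is explicit when given; otherwise ``select="aicc"``
    requests data-driven selection within ``(search_lo, search_hi)``.
    """

    kind: str = "fixed_gaussian"
    bandwidth: float | None = None
    select: str | None = None
    search_lo: float | None = None
    search_hi: float | None = None

    def __post_init__(self):
        if self.kind != "fixed_gaussian":
            raise ValidationError(f"unsupported kernel kind: {self.kind!r}")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValidationError("kernel bandwidth must be > 0")
        if self.bandwidth is None and self.select != "aicc":
            raise ValidationError("either an explicit bandwidth or select='aicc' is required")
        if self.search_lo is not None and self.search_hi is not None:
            if not (0 < self.search_lo < self.search_hi):
                raise ValidationError("search bounds must satisfy 0 < lo < hi")


def gaussian_weight(d, b: float):
    """Gaussian kernel weight ``exp(-d^2/b^2)`` for distance(s) ``d``.

    Equals 1 at ``d = 0`` and decreases strictly with distance; approaches 1
    for any fixed ``d`` as ``b`` grows.
    """
    if b <= 0:
        raise ValidationError(f"bandwidth must be > 0, got {b}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValidationError("distances must be >= 0")
    out = np.exp(-(d * d) / (b * b))
    return float(out) if out.ndim == 0 else out


def weight_matrix(coords, target, b: float, *, floor: float | None = None) -> np.ndarray:
    """Diagonal of the kernel weight matrix W(u, v) at ``target``.

    Parameters
    ----------
    coords : (m, 2) array of projected planar site coordinates.
    target : (u, v) pair of the regression point.
    b : bandwidth in coordinate units.
    floor : optional lower clamp applied to the weights (used when the
        weights will be inverted into an observation covariance).

    Returns the length-m vector of diagonal entries; distances are Euclidean.
    """
    coords = np.asarray(coords, dtype=float)
    target = np.asarray(target, dtype=float)
    d = np.hypot(coords[:, 0] - target[0], coords[:, 1] - target[1])
    w = gaussian_weight(d, b)
    if floor is not None:
        w = np.maximum(w, floor)
    return w


@dataclass
class BandwidthSearch:
    """Outcome of an AICc bandwidth search."""

    bandwidth: float
    aicc: float
    profile: list[tuple[float, float]] = field(default_factory=list)
    tied: bool = False


def _aicc_of_bandwidth(system, model, b, fit_kwargs):
    # local import: kernels must stay importable without the model layer
    from . import linear_models, metrics

    if model == "gwr":
        res = linear_models.gwr_fit(system, bandwidth=b, **fit_kwargs)
    elif model == "gwtlsr":
        res = linear_models.gwtlsr_fit(system, bandwidth=b, **fit_kwargs)
    else:
        raise ValidationError(f"unknown model for bandwidth selection: {model!r}")
    return metrics.aicc(system.y, res.fitted, res.hat_trace)


def select_bandwidth(
    system,
    model: str = "gwr",
    lo: float | None = None,
    hi: float | None = None,
    rel_tol: float = 1e-3,
    **fit_kwargs,
) -> BandwidthSearch:
    """Choose the bandwidth minimizing AICc by golden-section search.

    The search runs on log-bandwidth between ``lo`` and ``hi`` (defaults:
    0.1x and 10x the maximum pairwise site distance) to ``rel_tol`` relative
    tolerance.  Bandwidths whose local fits are singular, or whose effective
    model complexity makes AICc undefined, are treated as inadmissible.
    Ties are broken toward the smallest admissible bandwidth evaluated.
    """
    coords = np.asarray(system.coords, dtype=float)
    if lo is None or hi is None:
        diff = coords[:, None, :] - coords[None, :, :]
        dmax = float(np.sqrt((diff**2).sum(-1)).max())
        if dmax <= 0:
            raise ValidationError("all sites coincide; cannot bracket a bandwidth search")
        lo = lo if lo is not None else 0.1 * dmax
        hi = hi if hi is not None else 10.0 * dmax
    if not (0 < lo < hi):
        raise ValidationError("bandwidth search bounds must satisfy 0 < lo < hi")

    profile: list[tuple[float, float]] = []

    def f(logb):
        b = math.exp(logb)
        try:
            a = _aicc_of_bandwidth(system, model, b, fit_kwargs)
        except GwtlsError:
            a = math.inf
        profile.append((b, a))
        return a

    a, c = math.log(lo), math.log(hi)
    fa, fc = f(a), f(c)
    x1 = c - _INV_GOLDEN * (c - a)
    x2 = a + _INV_GOLDEN * (c - a)
    f1, f2 = f(x1), f(x2)
    while (c - a) > rel_tol:
        if f1 <= f2:
            c, fc = x2, f2
            x2, f2 = x1, f1
            x1 = c - _INV_GOLDEN * (c - a)
            f1 = f(x1)
        else:
            a, fa = x1, f1
            x1, f1 = x2, f2
            x2 = a + _INV_GOLDEN * (c - a)
            f2 = f(x2)

    # -inf (a perfect fit) is an admissible minimum; +inf/nan mark failures
    finite = [(b, v) for b, v in profile if not (math.isnan(v) or v == math.inf)]
    if not finite:
        raise GwtlsError("no admissible bandwidth in the search interval (all fits singular)")
    best_val = min(v for _, v in finite)
    # tie rule: smallest bandwidth whose AICc matches the minimum
    tol = 0.0 if not math.isfinite(best_val) else 1e-9 * max(1.0, abs(best_val))
    tied_pts = sorted(b for b, v in finite if v <= best_val + tol)
    tied = len(tied_pts) > 1
    if tied:
        logger.info("AICc tie across %d bandwidths; returning smallest %.6g", len(tied_pts), tied_pts[0])
    best_b = tied_pts[0]
    profile.sort(key=lambda t: t[0])
    return BandwidthSearch(bandwidth=best_b, aicc=best_val, profile=profile, tied=tied)
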
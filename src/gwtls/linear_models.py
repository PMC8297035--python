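"""The four regression estimators: OLS, GWR, WTLS, and GWTLSR.

All estimators share one :class:`DesignSystem` representation of the
regression problem

    y = A x + e,

where ``A`` is the m x n design matrix (k covariate columns followed by a
trailing intercept column of ones), ``y`` the m observations, and the error
structure differs per estimator:

* **OLS** — errors only in ``y``, identity weights.
* **GWR** — errors only in ``y``; one weighted fit per regression point with
  Gaussian distance-decay weights, yielding spatially varying coefficients.
* **WTLS** — errors in both ``y`` (variances ``qy``) and the covariate cells
  of ``A`` (per-cell variances ``qa_variances``); solved by a Lagrangian
  fixed-point iteration started at the OLS solution.
* **GWTLSR** — the hybrid: the WTLS iteration run at each regression point
  with the inverse kernel weights as the observation covariance, so the
  errors-in-variables correction and the spatial nonstationarity are
  handled simultaneously.

Because the design covariance is diagonal (independent cell errors), the
mn x mn Kronecker-product algebra of the WTLS normal equations collapses to
cheap column-wise diagonal updates; the implementation exploits this
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceWarning, SchemaError, SingularSystemError, ValidationError
from .kernels import WEIGHT_FLOOR, weight_matrix

__all__ = [
    "DesignSystem",
    "OLSFit",
    "WTLSFit",
    "LocalCoefficients",
    "GWModelResult",
    "ols_fit",
    "gwr_fit",
    "wtls_fit",
    "gwtlsr_fit",
    "predict",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass
class DesignSystem:
    """An assembled regression system.

    Attributes
    ----------
    A : (m, n) ndarray
        Covariate values with a trailing intercept column of ones.
    y : (m,) ndarray
        Observed dependent values (e.g. PM2.5 concentration, ug/m^3).
    qa_variances : (m, n) ndarray
        Per-cell measurement variances of ``A``; the intercept column is
        identically zero (the constant carries no measurement error).
    qy : (m,) ndarray
        Observation variances (diagonal observation covariance); all > 0.
    coords : (m, 2) ndarray
        Projected planar coordinates (u, v) in meters.
    feature_names : tuple of str
        Names of the covariate columns (exclusive of the intercept).
    """

    A: np.ndarray
    y: np.ndarray
    qa_variances: np.ndarray
    qy: np.ndarray
    coords: np.ndarray
    feature_names: tuple = ()

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.qa_variances = np.atleast_2d(np.asarray(self.qa_variances, dtype=float))
        self.qy = np.asarray(self.qy, dtype=float).ravel()
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        m, n = self.A.shape
        if not self.feature_names:
            self.feature_names = tuple(f"x{j + 1}" for j in range(n - 1))
        else:
            self.feature_names = tuple(self.feature_names)
        problems = []
        if m <= n:
            problems.append(f"m={m} observations must outnumber n={n} unknowns")
        if self.y.shape != (m,):
            problems.append(f"y has length {self.y.shape[0]}, expected {m}")
        if self.qa_variances.shape != (m, n):
            problems.append(f"qa_variances shape {self.qa_variances.shape} != {(m, n)}")
        elif np.any(self.qa_variances < 0):
            problems.append("qa_variances entries must be >= 0")
        elif np.any(self.qa_variances[:, -1] != 0):
            problems.append("intercept column of qa_variances must be exactly 0")
        if self.qy.shape != (m,):
            problems.append(f"qy has length {self.qy.shape[0]}, expected {m}")
        elif np.any(self.qy <= 0):
            problems.append("qy entries must be > 0")
        if self.coords.shape != (m, 2):
            problems.append(f"coords shape {self.coords.shape} != {(m, 2)}")
        if len(self.feature_names) != n - 1:
            problems.append(f"{len(self.feature_names)} feature names for {n - 1} covariates")
        if problems:
            raise ValidationError("invalid DesignSystem: " + "; ".join(problems))

    # convenience dimensions
    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def n_params(self) -> int:
        return self.A.shape[1]

    @property
    def n_features(self) -> int:
        return self.A.shape[1] - 1

    @classmethod
    def from_features(cls, X, y, coords, feature_variances=None, qy=None, feature_names=()):
        """Build a system from raw covariates, appending the intercept column.

        ``feature_variances`` defaults to all-zero (error-free covariates) and
        ``qy`` to unit observation variance.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m = X.shape[0]
        A = np.column_stack([X, np.ones(m)])
        if feature_variances is None:
            qa = np.zeros_like(A)
        else:
            fv = np.atleast_2d(np.asarray(feature_variances, dtype=float))
            qa = np.column_stack([fv, np.zeros(m)])
        qy = np.ones(m) if qy is None else np.asarray(qy, dtype=float)
        return cls(A=A, y=y, qa_variances=qa, qy=qy, coords=coords, feature_names=feature_names)


@dataclass
class OLSFit:
    """Global least-squares solution (coefficients ordered features-then-intercept)."""

    x_hat: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    hat_trace: float


@dataclass
class WTLSFit:
    """Converged weighted total least squares solution.

    ``x_hat`` are the coefficients, ``E_A_tilde`` the estimated design errors
    (intercept column exactly zero), ``lambda_hat`` the Lagrange multipliers,
    ``qy_tilde`` the diagonal of the combined covariance
    Q_y + sum_j x_j^2 diag(qa[:, j]), ``ey_tilde`` the observation errors,
    and ``objective`` the weighted sum of squared errors at the solution.
    """

    x_hat: np.ndarray
    E_A_tilde: np.ndarray
    lambda_hat: np.ndarray
    qy_tilde: np.ndarray
    ey_tilde: np.ndarray
    objective: float
    iterations: int
    converged: bool


@dataclass
class LocalCoefficients:
    """Coefficient vector of one regression point: covariates plus intercept."""

    location: tuple
    coeffs: np.ndarray
    intercept: float

    def as_array(self) -> np.ndarray:
        """Full coefficient vector in design order (intercept last)."""
        return np.append(self.coeffs, self.intercept)


@dataclass
class GWModelResult:
    """A locally fitted model (GWR or GWTLSR) over a set of regression points."""

    model: str
    locals: list
    bandwidth: float
    regression_points: np.ndarray
    hat_trace: float | None = None
    fitted: np.ndarray | None = None
    residuals: np.ndarray | None = None
    system: DesignSystem | None = field(default=None, repr=False)
    solver_options: dict = field(default_factory=dict)

    def local_coefficient(self, i: int) -> np.ndarray:
        loc = self.locals[i]
        if isinstance(loc, WTLSFit):
            return loc.x_hat
        return loc.as_array()

    def coefficient_table(self) -> np.ndarray:
        """(p, n) array of local coefficient vectors, intercept last."""
        return np.array([self.local_coefficient(i) for i in range(len(self.locals))])

    @property
    def converged(self) -> bool:
        return all(l.converged for l in self.locals if isinstance(l, WTLSFit))


# ---------------------------------------------------------------------------
# solvers


def _solve_normal(AtWA, AtWy, *, feature_names, location=None):
    """Solve the (weighted) normal equations, diagnosing rank deficiency."""
    n = AtWA.shape[0]
    if np.linalg.matrix_rank(AtWA, hermitian=True) < n:
        # pivoted QR of the Gram matrix identifies dependent columns
        from scipy.linalg import qr

        _, r, piv = qr(AtWA, pivoting=True)
        diag = np.abs(np.diag(r))
        thresh = diag.max() * max(AtWA.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
        bad = sorted(piv[np.sum(diag > thresh):].tolist())
        names = [(feature_names[j] if j < len(feature_names) else "intercept") for j in bad]
        where = "" if location is None else f" at regression point {tuple(location)}"
        raise SingularSystemError(
            f"singular normal equations{where}; dependent columns: {names}",
            columns=names,
            location=location,
        )
    return np.linalg.solve(AtWA, AtWy)


def ols_fit(system: DesignSystem) -> OLSFit:
    """Ordinary least squares: x = (A^T A)^{-1} A^T y with identity weights.

    Raises :class:`SingularSystemError` naming the dependent columns when
    ``A`` is rank deficient.
    """
    A, y = system.A, system.y
    x = _solve_normal(A.T @ A, A.T @ y, feature_names=system.feature_names)
    fitted = A @ x
    return OLSFit(x_hat=x, fitted=fitted, residuals=y - fitted, hat_trace=float(A.shape[1]))


def _effective_support(w, n):
    return int(np.sum(w > WEIGHT_FLOOR)) >= n


def gwr_fit(system: DesignSystem, bandwidth: float, regression_points=None) -> GWModelResult:
    """Geographically weighted regression with a fixed Gaussian kernel.

    At each regression point the coefficients solve the weighted normal
    equations x(u, v) = (A^T W A)^{-1} A^T W y with W the diagonal Gaussian
    kernel weights.  When the regression points are the sample locations
    (the default) the fitted values, residuals, and hat-matrix trace (the
    effective number of parameters) are also populated.
    """
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be > 0")
    A, y, coords = system.A, system.y, system.coords
    at_samples = regression_points is None
    points = coords if at_samples else np.atleast_2d(np.asarray(regression_points, dtype=float))

    locals_, hat_diag = [], []
    cache: dict[tuple, tuple] = {}
    for i, pt in enumerate(points):
        key = (pt[0], pt[1])
        if key not in cache:
            w = weight_matrix(coords, pt, bandwidth)
            if not _effective_support(w, system.n_params):
                raise SingularSystemError(
                    f"fewer than {system.n_params} samples carry weight above the floor "
                    f"at regression point {key}",
                    location=key,
                )
            AtW = A.T * w
            M = AtW @ A
            x = _solve_normal(M, AtW @ y, feature_names=system.feature_names, location=key)
            Minv = np.linalg.inv(M)
            cache[key] = (x, Minv, w)
        x, Minv, w = cache[key]
        locals_.append(LocalCoefficients(location=key, coeffs=x[:-1].copy(), intercept=float(x[-1])))
        if at_samples:
            # hat-matrix diagonal: r_ii = A_i (A^T W_i A)^{-1} A_i * w_i(i)
            hat_diag.append(float(A[i] @ Minv @ A[i]) * float(w[i]))

    result = GWModelResult(
        model="gwr",
        locals=locals_,
        bandwidth=float(bandwidth),
        regression_points=points.copy(),
        system=system,
    )
    if at_samples:
        fitted = np.array([A[i] @ result.local_coefficient(i) for i in range(system.m)])
        result.fitted = fitted
        result.residuals = y - fitted
        result.hat_trace = float(np.sum(hat_diag))
    return result


def _wtls_objective(system_qy, qa, A, y, x, E):
    """Weighted sum of squared errors at coefficients ``x`` and design errors ``E``.

    Cells with zero variance contribute only through their (necessarily zero)
    errors; the 0/0 convention for them is 0.
    """
    ey = y - (A - E) @ x
    obj = float(ey @ (ey / system_qy))
    mask = qa > 0
    obj += float(np.sum(E[mask] ** 2 / qa[mask]))
    return obj


def _wtls_iterate(A, y, qa, qy, feature_names, tol, max_iter, x0=None, location=None):
    """Fixed-point iteration of the WTLS Lagrangian stationarity conditions.

    Per cycle: combined covariance Q_y~ = Q_y + sum_j x_j^2 diag(qa_j);
    multipliers lambda = Q_y~^{-1}(y - A x); design errors
    E[:, j] = -x_j qa_j lambda; then the generalized least-squares update of
    x on the corrected system (A - E, y - E x).  The diagonal design
    covariance makes every step O(mn).
    """
    m, n = A.shape
    if x0 is None:
        x = _solve_normal(A.T @ A, A.T @ y, feature_names=feature_names, location=location)
    else:
        x = np.asarray(x0, dtype=float).copy()
    E = np.zeros_like(A)
    lam = np.zeros(m)
    qyt = qy.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        qyt = qy + qa @ (x * x)
        resid = y - A @ x
        lam = resid / qyt
        E = -qa * (lam[:, None] * x[None, :])
        At = A - E
        yt = y - E @ x
        AtQ = At.T / qyt
        x_new = _solve_normal(AtQ @ At, AtQ @ yt, feature_names=feature_names, location=location)
        step = np.max(np.abs(x_new - x)) / max(1.0, np.max(np.abs(x_new)))
        x = x_new
        if step < tol:
            converged = True
            break
    # refresh error estimates at the final coefficients
    qyt = qy + qa @ (x * x)
    resid = y - A @ x
    lam = resid / qyt
    E = -qa * (lam[:, None] * x[None, :])
    ey = y - (A - E) @ x
    obj = _wtls_objective(qy, qa, A, y, x, E)
    return WTLSFit(
        x_hat=x,
        E_A_tilde=E,
        lambda_hat=lam,
        qy_tilde=qyt,
        ey_tilde=ey,
        objective=obj,
        iterations=it,
        converged=converged,
    )


def wtls_fit(system: DesignSystem, tol: float = 1e-10, max_iter: int = 100) -> WTLSFit:
    """Weighted total least squares on the global system.

    Starts from the OLS solution and iterates the stationarity conditions of
    the Lagrangian until the relative coefficient change falls below ``tol``.
    Returns the fit with an honest ``converged`` flag; non-convergence in
    ``max_iter`` emits a :class:`ConvergenceWarning` rather than raising.
    """
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    fit = _wtls_iterate(
        system.A, system.y, system.qa_variances, system.qy,
        system.feature_names, tol, max_iter,
    )
    if not fit.converged:
        warnings.warn(
            f"WTLS did not converge in {max_iter} iterations", ConvergenceWarning, stacklevel=2
        )
    return fit


def gwtlsr_fit(
    system: DesignSystem,
    bandwidth: float,
    tol: float = 1e-10,
    max_iter: int = 100,
    regression_points=None,
    mode: str = "iterate",
) -> GWModelResult:
    """Geographically weighted total least squares regression.

    At each regression point the observation covariance is the inverse of
    the Gaussian kernel weights, Q_y = W(u, v)^{-1} (weights clamped at a
    small floor before inversion), and the full per-cell design covariance
    is carried through the WTLS solution.  ``mode="iterate"`` (default) runs
    the fixed-point cycle to convergence per point; ``mode="one_shot"``
    applies a single design-error correction to the local GWR solution
    followed by one corrected solve.

    The hat-matrix trace uses the corrected local design A - E_A and the
    combined covariance weights, so AICc comparisons against GWR reflect the
    errors-in-variables adjustment.
    """
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be > 0")
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    if mode not in ("iterate", "one_shot"):
        raise ValidationError(f"unknown mode {mode!r}")
    A, y, coords, qa = system.A, system.y, system.coords, system.qa_variances
    at_samples = regression_points is None
    points = coords if at_samples else np.atleast_2d(np.asarray(regression_points, dtype=float))

    locals_, hat_diag = [], []
    not_converged = []
    cache: dict[tuple, WTLSFit] = {}
    for i, pt in enumerate(points):
        key = (pt[0], pt[1])
        if key not in cache:
            # kernel underflow is handled by the weight floor: clamped weights
            # invert into a huge-but-finite variance, keeping the local
            # problem well posed even far from all samples
            w = weight_matrix(coords, pt, bandwidth, floor=WEIGHT_FLOOR)
            qy_local = 1.0 / w
            if mode == "iterate":
                fit = _wtls_iterate(
                    A, y, qa, qy_local, system.feature_names, tol, max_iter, location=key
                )
            else:
                fit = _one_shot_correction(A, y, qa, qy_local, system.feature_names, key)
            cache[key] = fit
        fit = cache[key]
        locals_.append(fit)
        if not fit.converged:
            not_converged.append(key)
        if at_samples:
            At = A - fit.E_A_tilde
            AtQ = At.T / fit.qy_tilde
            Minv = np.linalg.inv(AtQ @ At)
            hat_diag.append(float(At[i] @ Minv @ At[i]) / float(fit.qy_tilde[i]))

    if not_converged:
        uniq = sorted(set(not_converged))
        warnings.warn(
            f"GWTLSR did not converge at {len(uniq)} regression point(s): {uniq[:5]}",
            ConvergenceWarning,
            stacklevel=2,
        )

    result = GWModelResult(
        model="gwtlsr",
        locals=locals_,
        bandwidth=float(bandwidth),
        regression_points=points.copy(),
        system=system,
        solver_options={"tol": tol, "max_iter": max_iter, "mode": mode},
    )
    if at_samples:
        fitted = np.array([A[i] @ result.local_coefficient(i) for i in range(system.m)])
        result.fitted = fitted
        result.residuals = y - fitted
        result.hat_trace = float(np.sum(hat_diag))
    return result


def _one_shot_correction(A, y, qa, qy, feature_names, location):
    """Single design-error correction applied to the local GWR solution."""
    AtQ = A.T / qy
    x = _solve_normal(AtQ @ A, AtQ @ y, feature_names=feature_names, location=location)
    resid = y - A @ x
    lam = resid / qy  # raw observation weights, not the combined covariance
    E = -qa * (lam[:, None] * x[None, :])
    At = A - E
    yt = y - E @ x
    AtQ2 = At.T / qy
    x2 = _solve_normal(AtQ2 @ At, AtQ2 @ yt, feature_names=feature_names, location=location)
    qyt = qy + qa @ (x2 * x2)
    ey = y - (A - E) @ x2
    obj = _wtls_objective(qy, qa, A, y, x2, E)
    return WTLSFit(
        x_hat=x2, E_A_tilde=E, lambda_hat=lam, qy_tilde=qyt, ey_tilde=ey,
        objective=obj, iterations=1, converged=True,
    )


def predict(result: GWModelResult, new_points, X_new, mode: str = "refit") -> np.ndarray:
    """Predict the dependent variable at new locations.

    ``mode="refit"`` (default) fits fresh local coefficients at each query
    point from the training system; ``mode="nearest"`` reuses the
    coefficients of the nearest fitted regression point.  Covariate rows are
    used raw (no error correction is applied to prediction inputs).
    """
    if result.system is None:
        raise ValidationError("result carries no training system; cannot predict")
    new_points = np.atleast_2d(np.asarray(new_points, dtype=float))
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    k = result.system.n_features
    if X_new.shape[1] != k:
        raise SchemaError(
            f"covariate mismatch: prediction rows have {X_new.shape[1]} features, "
            f"training system has {k} ({list(result.system.feature_names)})"
        )
    if X_new.shape[0] != new_points.shape[0]:
        raise SchemaError("new_points and covariate rows must align row-for-row")
    rows = np.column_stack([X_new, np.ones(X_new.shape[0])])

    if mode == "nearest":
        pts = result.regression_points
        out = np.empty(new_points.shape[0])
        for i, p in enumerate(new_points):
            j = int(np.argmin(np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1])))
            out[i] = rows[i] @ result.local_coefficient(j)
        return out
    if mode != "refit":
        raise ValidationError(f"unknown prediction mode {mode!r}")

    if result.model == "gwr":
        refit = gwr_fit(result.system, result.bandwidth, regression_points=new_points)
    else:
        opts = dict(result.solver_options)
        refit = gwtlsr_fit(
            result.system,
            result.bandwidth,
            tol=opts.get("tol", 1e-10),
            max_iter=opts.get("max_iter", 100),
            regression_points=new_points,
            mode=opts.get("mode", "iterate"),
        )
    return np.array([rows[i] @ refit.local_coefficient(i) for i in range(rows.shape[0])])
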
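"""Two-stage predictor selection and station-wise cross-validation.

Stage one screens candidate covariates by Pearson correlation with the
response; when the same base variable was extracted in several buffer radii
(e.g. ``traffic_150``, ``traffic_300``), only the buffer with the highest
absolute correlation survives.  Stage two enumerates all subsets of the
surviving candidates up to a size cap, fits an OLS model to each, discards
subsets in which any covariate is non-significant (p > 0.05), and keeps the
subset with the highest R^2.  Model comparison uses leave-one-station-out
cross-validation: each fold holds out every sample of one station.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ValidationError
from .linear_models import DesignSystem, gwr_fit, gwtlsr_fit, ols_fit, predict, wtls_fit
from .metrics import mae as _mae
from .metrics import rmse as _rmse

__all__ = [
    "CandidateFeature",
    "ScreenResult",
    "SelectionResult",
    "CVResult",
    "pearson_screen",
    "subset_search",
    "loocv_by_station",
]

logger = logging.getLogger(__name__)

_BUFFER_RE = re.compile(r"^(?P<base>.+?)_(?P<radius>\d+)$")


@dataclass
class CandidateFeature:
    """A candidate covariate, possibly one buffer radius of a base variable."""

    name: str
    base: str
    buffer: float | None
    r: float
    p_value: float | None = None


@dataclass
class ScreenResult:
    kept: list          # CandidateFeature, ranked by |r| descending
    dropped: list       # (CandidateFeature | name, reason)


@dataclass
class SelectionResult:
    chosen: tuple
    chosen_r2: float
    table: pd.DataFrame          # one row per surviving subset: subset, size, r2, rmse
    rmse_profile: pd.DataFrame   # best RMSE per subset size over all enumerated subsets
    discarded: list              # (subset | name, reason)


@dataclass
class CVResult:
    folds: pd.DataFrame          # station, n_test, rmse/mae test & train
    skipped: list = field(default_factory=list)

    @property
    def means(self) -> dict:
        cols = ["rmse_test", "rmse_train", "mae_test", "mae_train"]
        return {c: float(self.folds[c].mean()) for c in cols}


def split_buffer_name(name: str):
    """Parse ``base_<radius>`` column names; plain names have no buffer."""
    m = _BUFFER_RE.match(name)
    if m:
        return m.group("base"), float(m.group("radius"))
    return name, None


def pearson_screen(X: pd.DataFrame, y, min_abs_r: float = 0.0) -> ScreenResult:
    """Stage-one screen: Pearson r per candidate, best buffer per base variable.

    Zero-variance candidates are dropped with a logged reason; ties in |r|
    within a base variable go to the smaller buffer radius, then to the
    lexicographically smaller name.  An optional |r| floor (default 0 = off)
    drops weakly correlated survivors.
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(X) != y.size:
        raise ValidationError("X and y must have equal length")
    if y.size < 3:
        raise ValidationError("need at least 3 samples per feature")
    dropped: list = []
    candidates: list[CandidateFeature] = []
    for name in X.columns:
        col = X[name].to_numpy(dtype=float)
        if np.std(col) == 0:
            logger.info("dropping %s: zero variance", name)
            dropped.append((name, "zero variance"))
            continue
        r, p = stats.pearsonr(col, y)
        base, buffer = split_buffer_name(name)
        candidates.append(CandidateFeature(name=name, base=base, buffer=buffer, r=float(r), p_value=float(p)))

    kept: list[CandidateFeature] = []
    for base in sorted({c.base for c in candidates}):
        group = [c for c in candidates if c.base == base]
        # max |r|; ties -> smaller buffer, then name
        group.sort(key=lambda c: (-abs(c.r), c.buffer if c.buffer is not None else -1.0, c.name))
        best = group[0]
        for other in group[1:]:
            dropped.append((other, f"lower |r| than {best.name} for base {base!r}"))
            if abs(other.r) == abs(best.r):
                logger.info("tie on |r| for base %r broken toward %s", base, best.name)
        if abs(best.r) < min_abs_r:
            dropped.append((best, f"|r|={abs(best.r):.3f} below floor {min_abs_r}"))
        else:
            kept.append(best)
    kept.sort(key=lambda c: (-abs(c.r), c.name))
    return ScreenResult(kept=kept, dropped=dropped)


def subset_search(
    X: pd.DataFrame,
    y,
    candidates=None,
    max_size: int = 5,
    alpha: float = 0.05,
) -> SelectionResult:
    """Stage-two exhaustive subset search with a per-subset significance filter.

    Every subset of the candidates up to ``max_size`` is fitted by OLS (with
    intercept).  A subset survives only if every covariate's coefficient is
    significant at ``alpha`` in that subset's own fit.  Among survivors the
    subset with the highest R^2 wins; ties go to the smaller subset, then
    lexicographic order.  The RMSE-versus-size profile is reported over all
    enumerated subsets (before filtering), where it is non-increasing by
    nesting.
    """
    if candidates is None:
        candidates = list(X.columns)
    else:
        candidates = [c.name if isinstance(c, CandidateFeature) else c for c in candidates]
    missing = [c for c in candidates if c not in X.columns]
    if missing:
        raise ValidationError(f"candidates not in X: {missing}")
    if len(candidates) > 12:
        raise ValidationError("exhaustive search supports at most 12 candidates")
    y = np.asarray(y, dtype=float).ravel()

    rows, discarded = [], []
    best_rmse_by_size: dict[int, float] = {}
    for size in range(1, min(max_size, len(candidates)) + 1):
        for subset in itertools.combinations(sorted(candidates), size):
            exog = sm.add_constant(X[list(subset)].to_numpy(dtype=float), has_constant="add")
            fit = sm.OLS(y, exog).fit()
            model_rmse = float(np.sqrt(np.mean(fit.resid**2)))
            best_rmse_by_size[size] = min(best_rmse_by_size.get(size, np.inf), model_rmse)
            pvals = fit.pvalues[1:]  # slopes only; the intercept is always kept
            if np.any(pvals > alpha):
                bad = [subset[j] for j in np.flatnonzero(pvals > alpha)]
                discarded.append((subset, f"p > {alpha} for {bad}"))
                continue
            rows.append(
                {"subset": subset, "size": size, "r2": float(fit.rsquared), "rmse": model_rmse}
            )

    table = pd.DataFrame(rows, columns=["subset", "size", "r2", "rmse"])
    profile = pd.DataFrame(
        {"size": sorted(best_rmse_by_size), "rmse": [best_rmse_by_size[s] for s in sorted(best_rmse_by_size)]}
    )
    if table.empty:
        logger.warning("no subset survived the p-value filter")
        return SelectionResult(chosen=(), chosen_r2=np.nan, table=table,
                               rmse_profile=profile, discarded=discarded)
    order = table.sort_values(["r2", "size", "subset"], ascending=[False, True, True])
    best = order.iloc[0]
    return SelectionResult(
        chosen=tuple(best["subset"]),
        chosen_r2=float(best["r2"]),
        table=table,
        rmse_profile=profile,
        discarded=discarded,
    )


def _build_system(frame: pd.DataFrame, features, default_variance: float = 0.0) -> DesignSystem:
    var_cols = []
    for f in features:
        col = f"{f}__var"
        if col in frame.columns:
            var_cols.append(frame[col].to_numpy(dtype=float))
        else:
            var_cols.append(np.full(len(frame), default_variance))
    return DesignSystem.from_features(
        X=frame[list(features)].to_numpy(dtype=float),
        y=frame["y"].to_numpy(dtype=float),
        coords=frame[["u", "v"]].to_numpy(dtype=float),
        feature_variances=np.column_stack(var_cols),
        feature_names=list(features),
    )


def _fit_and_predict(model, train, test, features, bandwidth, **opts):
    sys_train = _build_system(train, features)
    X_test = test[list(features)].to_numpy(dtype=float)
    rows_test = np.column_stack([X_test, np.ones(len(test))])
    if model == "ols":
        fit = ols_fit(sys_train)
        return fit.fitted, rows_test @ fit.x_hat
    if model == "wtls":
        fit = wtls_fit(sys_train, **opts)
        fitted = sys_train.A @ fit.x_hat
        return fitted, rows_test @ fit.x_hat
    if model in ("gwr", "gwtlsr"):
        if bandwidth is None:
            raise ValidationError(f"{model} requires a bandwidth")
        fit_fn = gwr_fit if model == "gwr" else gwtlsr_fit
        fit = fit_fn(sys_train, bandwidth=bandwidth, **opts)
        pts = test[["u", "v"]].to_numpy(dtype=float)
        return fit.fitted, predict(fit, pts, X_test, mode="refit")
    raise ValidationError(f"unknown model {model!r}")


def loocv_by_station(
    frame: pd.DataFrame,
    features,
    model: str = "ols",
    bandwidth: float | None = None,
    station_col: str = "station_id",
    **model_options,
) -> CVResult:
    """Leave-one-station-out cross-validation.

    One fold per distinct station: the fold trains on every other station's
    samples and tests on all samples of the held-out station.  Reports
    per-fold and mean RMSE/MAE on both the test and the training side.
    Stations whose samples are all invalid (non-finite response or
    covariates) are skipped with a warning.
    """
    stations = frame[station_col].unique()
    if len(stations) < 3:
        raise ValidationError("need at least 3 distinct stations for station-wise CV")
    needed = ["y", "u", "v", *features]
    valid = np.isfinite(frame[needed].to_numpy(dtype=float)).all(axis=1)

    rows, skipped = [], []
    for sid in stations:
        test_mask = (frame[station_col] == sid).to_numpy() & valid
        train_mask = (frame[station_col] != sid).to_numpy() & valid
        if not test_mask.any():
            logger.warning("station %s has no valid samples; fold skipped", sid)
            skipped.append(sid)
            continue
        train, test = frame.loc[train_mask], frame.loc[test_mask]
        fitted_train, pred_test = _fit_and_predict(
            model, train, test, features, bandwidth, **model_options
        )
        rows.append(
            {
                "station": sid,
                "n_test": int(test_mask.sum()),
                "rmse_test": _rmse(test["y"], pred_test),
                "mae_test": _mae(test["y"], pred_test),
                "rmse_train": _rmse(train["y"], fitted_train),
                "mae_train": _mae(train["y"], fitted_train),
            }
        )
    return CVResult(folds=pd.DataFrame(rows), skipped=skipped)
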
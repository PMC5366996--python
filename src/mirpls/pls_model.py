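"""PLS1 regression for single-analyte spectroscopic calibration.

The model is classical NIPALS PLS1: X and y are centred, then latent
variables are extracted one at a time — the weight vector is the
covariance direction X'y (normalised), scores t = Xw, loadings
p = X't/t't, q = y't/t't, and X is deflated by t p' (y deflation is
redundant for a single response).  The regression vector collapsing all
latent variables into one affine map is

    b = W (P'W)^{-1} q,        b0 = y_mean - x_mean . b

so prediction of a pre-treated spectrum x is x.b + b0.  NIPALS scores are
mutually orthogonal, and with as many latent variables as the rank of the
centred X block the model coincides with least squares.

Model selection follows routine chemometric practice: leave-one-out
cross-validation (with any stateful pre-treatment re-fitted inside each
fold, so no information leaks from the held-out spectrum), an RMSECV curve
over the latent-variable count, and a parsimony rule choosing the smallest
count within a relative tolerance of the curve minimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from . import metrics as _metrics
from .exceptions import DegenerateDataError, GridError, RankError
from .preprocess import PretreatmentPipeline, build_pipeline
from .spectra_io import SpectrumSet, WavenumberGrid

_EPS = np.finfo(float).eps


@dataclass
class PLSModel:
    """Fitted PLS1 model: latent structure plus the collapsed affine map."""

    n_lv: int
    weights: np.ndarray        # (p, n_lv) NIPALS weight vectors
    x_loadings: np.ndarray     # (p, n_lv)
    y_loadings: np.ndarray     # (n_lv,)
    scores: np.ndarray         # (n, n_lv) training scores
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray   # (p,) regression vector on pre-treated spectra
    intercept: float
    pipeline: PretreatmentPipeline | None = None
    grid: WavenumberGrid | None = None
    fitted_values: np.ndarray | None = None

    def predict_pretreated(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coefficients + self.intercept

    def to_json(self, path=None) -> str:
        payload = {
            "format": "mirpls-model",
            "n_lv": self.n_lv,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "pipeline": {
                "name": self.pipeline.name if self.pipeline else "raw",
                "steps": self.pipeline.descriptors() if self.pipeline else [],
            },
            "grid": self.grid.values.tolist() if self.grid is not None else None,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "PLSModel":
        with open(path) as fh:
            payload = json.load(fh)
        coef = np.asarray(payload["coefficients"])
        p = coef.size
        pipe = PretreatmentPipeline.from_descriptors(
            payload["pipeline"]["steps"], name=payload["pipeline"]["name"]
        )
        grid = (
            WavenumberGrid(np.asarray(payload["grid"]))
            if payload.get("grid") is not None
            else None
        )
        n_lv = payload["n_lv"]
        return cls(
            n_lv=n_lv,
            weights=np.zeros((p, 0)),
            x_loadings=np.zeros((p, 0)),
            y_loadings=np.zeros(0),
            scores=np.zeros((0, 0)),
            x_mean=np.asarray(payload["x_mean"]),
            y_mean=payload["y_mean"],
            coefficients=coef,
            intercept=payload["intercept"],
            pipeline=pipe,
            grid=grid,
        )


@dataclass
class ModelMetrics:
    """Error and determination record for one calibration model."""

    n_lv: int
    rmsee: float | None = None
    rmsecv: float | None = None
    rmsep: float | None = None
    r2_cal: float | None = None
    r2_cval: float | None = None
    r2_pred: float | None = None
    sec: float | None = None
    secv: float | None = None
    sep: float | None = None
    cv_predictions: np.ndarray | None = field(default=None, repr=False)


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit PLS1 by NIPALS on pre-treated spectra X against concentrations y.

    Deterministic: NIPALS for a single response needs no iteration or
    random start, each latent variable is obtained in closed form.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"X has {n} rows but y has {y.size} entries")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("X and y must be finite")
    if n < n_lv + 1:
        raise RankError(f"need at least n_lv+1={n_lv + 1} samples, got {n}")
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise RankError(f"n_lv must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    if np.ptp(y) == 0:
        raise DegenerateDataError("y has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    # scale guard for the rank checks below
    x_scale = max(float(np.abs(Xc).max()), _EPS)

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    Xd = Xc.copy()
    for a in range(n_lv):
        w = Xd.T @ yc
        wn = np.linalg.norm(w)
        if wn <= 1e-12 * x_scale * np.linalg.norm(yc):
            raise RankError(
                f"X exhausted after {a} latent variables; requested {n_lv}"
            )
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt <= (1e-12 * x_scale) ** 2 * n:
            raise RankError(
                f"zero-variance score at latent variable {a + 1}; rank exceeded"
            )
        p_a = Xd.T @ t / tt
        q_a = float(yc @ t / tt)
        Xd -= np.outer(t, p_a)
        W[:, a], P[:, a], Q[a], T[:, a] = w, p_a, q_a, t

    coef = W @ np.linalg.solve(P.T @ W, Q)
    intercept = y_mean - float(x_mean @ coef)
    model = PLSModel(
        n_lv=n_lv,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        x_mean=x_mean,
        y_mean=y_mean,
        coefficients=coef,
        intercept=intercept,
    )
    model.fitted_values = model.predict_pretreated(X)
    return model


def calibrate(
    sset: SpectrumSet,
    y: np.ndarray,
    pipeline: str | PretreatmentPipeline,
    n_lv: int,
) -> PLSModel:
    """Fit pipeline + PLS on a SpectrumSet; model remembers both."""
    if isinstance(pipeline, str):
        pipeline = build_pipeline(pipeline, spacing=sset.grid.spacing)
    Xt = pipeline.fit_transform(sset.absorbance)
    model = fit_pls(Xt, y, n_lv)
    model.pipeline = pipeline
    model.grid = sset.grid
    return model


def predict(model: PLSModel, sset: SpectrumSet) -> np.ndarray:
    """Predict concentrations for new spectra using stored state only."""
    if model.grid is not None and sset.grid != model.grid:
        raise GridError("prediction grid does not match the training grid")
    X = sset.absorbance
    if model.pipeline is not None:
        X = model.pipeline.transform(X)
    return model.predict_pretreated(X)


def pca_screen(
    X: np.ndarray, n_components: int, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Centered-PCA screening of calibration spectra.

    Returns (scores, hotelling_t2, outlier_flags, explained_variance_ratio).
    A sample is flagged when its Hotelling T^2 over the retained components
    exceeds the (1-alpha) limit k(n-1)/(n-k) F_{1-alpha}(k, n-k).  Screening
    is advisory: nothing is dropped.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 3:
        raise RankError("PCA screening needs at least 3 samples")
    if not (0 < n_components < n):
        raise RankError(f"n_components must be in [1, {n - 1}], got {n_components}")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((s**2).sum())
    if total_var == 0:
        raise DegenerateDataError("all spectra identical; PCA undefined")
    evr = s**2 / total_var
    k = n_components
    scores = U[:, :k] * s[:k]
    lam = s[:k] ** 2 / (n - 1)  # per-component score variance
    lam = np.maximum(lam, _EPS)
    t2 = ((scores**2) / lam).sum(axis=1)
    limit = k * (n - 1) / (n - k) * f_dist.ppf(1 - alpha, k, n - k)
    return scores, t2, t2 > limit, evr


def loo_cv(
    X: np.ndarray,
    y: np.ndarray,
    pipeline: str | PretreatmentPipeline | None,
    n_lv: int,
    spacing: float = 1.0,
) -> ModelMetrics:
    """Leave-one-out cross-validation with fold-internal pre-treatment.

    For each of the n samples a calibration model is built on the other
    n-1 (the pipeline's stateful parameters re-estimated on those n-1
    alone) and the held-out spectrum is predicted, yielding n out-of-fold
    predictions and the RMSECV over them.  Calibration-side statistics
    (RMSEE, SEC, R^2cal) come from the model fitted on all n.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise RankError("LOO cross-validation needs at least 3 samples")

    def make_pipe() -> PretreatmentPipeline | None:
        if pipeline is None:
            return None
        if isinstance(pipeline, str):
            return build_pipeline(pipeline, spacing=spacing)
        return PretreatmentPipeline.from_descriptors(
            [
                {k: v for k, v in d.items() if k != "means"}
                for d in pipeline.descriptors()
            ],
            name=pipeline.name,
        )

    full_pipe = make_pipe()
    Xt_full = full_pipe.fit_transform(X) if full_pipe is not None else X
    full_model = fit_pls(Xt_full, y, n_lv)
    fitted = full_model.fitted_values

    cv_pred = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold_pipe = make_pipe()
        try:
            Xt = fold_pipe.fit_transform(X[mask]) if fold_pipe is not None else X[mask]
            fold_model = fit_pls(Xt, y[mask], n_lv)
            xt_i = (
                fold_pipe.transform(X[i : i + 1]) if fold_pipe is not None else X[i : i + 1]
            )
            cv_pred[i] = fold_model.predict_pretreated(xt_i)[0]
        except Exception as exc:
            raise type(exc)(f"LOO fold {i} (held out {i}): {exc}") from exc

    return ModelMetrics(
        n_lv=n_lv,
        rmsee=_metrics.rmse(fitted, y),
        rmsecv=_metrics.rmse(cv_pred, y),
        r2_cal=_metrics.r_squared(fitted, y),
        r2_cval=_metrics.r_squared(cv_pred, y),
        sec=_metrics.standard_error(fitted, y, n_lv) if n > n_lv + 1 else None,
        secv=_metrics.standard_error(cv_pred, y, n_lv) if n > n_lv + 1 else None,
        cv_predictions=cv_pred,
    )


def select_n_lv(
    X: np.ndarray,
    y: np.ndarray,
    pipeline: str | PretreatmentPipeline | None,
    max_lv: int,
    spacing: float = 1.0,
    rel_tolerance: float = 0.02,
) -> tuple[int, np.ndarray]:
    """Choose the latent-variable count by the parsimony rule.

    Computes the RMSECV curve for 1..max_lv and returns the smallest count
    whose RMSECV is within ``rel_tolerance`` (relative) of the curve
    minimum — extra latent variables must buy a real error reduction.  If
    the data run out of rank before max_lv the curve is truncated there.
    """
    n = np.atleast_2d(X).shape[0]
    if max_lv > n - 2:
        raise RankError(f"max_lv must be <= n-2 = {n - 2} for LOO selection")
    values = []
    for a in range(1, max_lv + 1):
        try:
            values.append(loo_cv(X, y, pipeline, a, spacing=spacing).rmsecv)
        except RankError:
            if not values:
                raise
            break
    curve = np.array(values)
    best = float(curve.min())
    chosen = int(np.flatnonzero(curve <= best * (1 + rel_tolerance))[0]) + 1
    return chosen, curve


def compare_pretreatments(
    cal_set: SpectrumSet,
    y_cal: np.ndarray,
    val_set: SpectrumSet,
    y_val: np.ndarray,
    pipeline_names: list[str],
    max_lv: int = 10,
    rel_tolerance: float = 0.02,
) -> pd.DataFrame:
    """Build one model per named pre-treatment and rank them.

    Each pipeline gets its latent-variable count from ``select_n_lv`` on
    the calibration set, calibration-side errors from the full fit, and
    external RMSEP/R^2pred from the validation set.  Ranking is
    lexicographic: higher R^2pred, then lower RMSEP, then fewer latent
    variables, then input order — mirroring the usual preference for the
    most predictive, simplest model.  A pipeline failing on the data is
    recorded as a failed row rather than aborting the comparison.
    """
    spacing = cal_set.grid.spacing
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    rows = []
    for order, name in enumerate(pipeline_names):
        row: dict = {"pipeline": name, "order": order, "failed": False, "error": ""}
        try:
            n_lv, _ = select_n_lv(
                cal_set.absorbance, y_cal, name, max_lv,
                spacing=spacing, rel_tolerance=rel_tolerance,
            )
            cv = loo_cv(cal_set.absorbance, y_cal, name, n_lv, spacing=spacing)
            model = calibrate(cal_set, y_cal, name, n_lv)
            pred = predict(model, val_set)
            row.update(
                n_lv=n_lv,
                rmsee=cv.rmsee,
                r2_cal=cv.r2_cal,
                rmsecv=cv.rmsecv,
                r2_cval=cv.r2_cval,
                rmsep=_metrics.rmse(pred, y_val),
                r2_pred=_metrics.r_squared(pred, y_val),
                sep=(
                    _metrics.standard_error(pred, y_val, n_lv)
                    if y_val.size > n_lv + 1
                    else np.nan
                ),
            )
        except Exception as exc:  # record, don't abort the table
            row.update(
                failed=True, error=str(exc),
                n_lv=np.nan, rmsee=np.nan, r2_cal=np.nan, rmsecv=np.nan,
                r2_cval=np.nan, rmsep=np.nan, r2_pred=np.nan, sep=np.nan,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["failed", "r2_pred", "rmsep", "n_lv", "order"],
        ascending=[True, False, True, True, True],
    ).reset_index(drop=True)
    return df.drop(columns=["order"])
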
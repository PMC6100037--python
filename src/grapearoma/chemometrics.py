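"""OPLS regression and supporting chemometrics.

This module implements the numerical core of the liking-prediction
analysis: unit-variance (UV) scaling, PCA with Hotelling's T² outlier
screening, single-response orthogonal PLS (O-PLS) with the NIPALS-style
orthogonal-filtering algorithm, seven-fold cross-validation with Q²Y and
RMSECV, Y-permutation validation, and VIP variable-importance scores.

Model notation
--------------
With X (n × k) and y (n) both UV-scaled, the predictive weight is
w ∝ X'y (unit norm).  Each orthogonal component is extracted as
w_o ∝ p − (w'p)w from the current loading p = X't/(t't), scored as
t_o = X w_o and removed from X by deflation X ← X − t_o p_o'.  After
removing the requested orthogonal components, the predictive component is
t = X w with response loading q = y't/(t't), so fitted values are t·q in
scaled units.  With zero orthogonal components the model coincides with
one-component PLS1.

Fit statistics follow the conventions of the originating chemometrics
software: R²X is the cumulative X-variance captured by all components, R²Y
the explained response variance, Q²Y = 1 − PRESS/SS from cross-validated
residuals, RMSEE = sqrt(SS_res / (N − 1 − A)) and RMSECV = sqrt(PRESS/N),
both reported on the original response scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ModelError, ValidationError

_ORTHO_TOL = 1e-10


# ---------------------------------------------------------------------------
# UV scaling
# ---------------------------------------------------------------------------
@dataclass
class ScalingParams:
    """Column means/SDs of a UV-scaling fit (SD with ddof=1).

    Zero-variance columns are dropped at fit time and recorded in
    ``dropped`` so the same columns are removed when the params are applied
    to new data.
    """

    mean: np.ndarray
    std: np.ndarray
    columns: list[str] | None = None
    dropped: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "columns": self.columns,
            "dropped": self.dropped,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            std=np.asarray(d["std"], dtype=float),
            columns=d.get("columns"),
            dropped=list(d.get("dropped", [])),
        )


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    return np.asarray(X, dtype=float), None


def uv_scale(X, mode: str = "fit", params: ScalingParams | None = None):
    """Unit-variance scale a matrix (columns → mean 0, SD 1).

    ``mode='fit'`` estimates means/SDs (SD with ddof=1) from ``X`` and drops
    zero-variance columns; ``mode='apply'`` re-uses previously fitted
    ``params`` (training-set statistics) on new data.  Returns
    ``(scaled, params)``.
    """
    mat, columns = _as_matrix(X)
    if mat.ndim == 1:
        mat = mat[:, None]
    if mode == "fit":
        mean = mat.mean(axis=0)
        std = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
        keep = std > 0
        dropped = []
        if columns is not None:
            dropped = [c for c, k in zip(columns, keep) if not k]
            columns = [c for c, k in zip(columns, keep) if k]
        elif not keep.all():
            dropped = [str(i) for i in np.nonzero(~keep)[0]]
        params = ScalingParams(mean=mean[keep], std=std[keep], columns=columns, dropped=dropped)
        scaled = (mat[:, keep] - params.mean) / params.std
        return scaled, params
    if mode == "apply":
        if params is None:
            raise ModelError("mode='apply' requires fitted ScalingParams")
        if params.columns is not None:
            if columns is None:
                raise ModelError("apply requires a DataFrame with named columns")
            missing = [c for c in params.columns if c not in columns]
            if missing:
                raise ModelError(f"missing columns at apply time: {missing}")
            idx = [columns.index(c) for c in params.columns]
            mat = mat[:, idx]
        elif mat.shape[1] != params.mean.size:
            # positional matrices must already exclude dropped columns
            raise ModelError(
                f"expected {params.mean.size} columns, got {mat.shape[1]}"
            )
        return (mat - params.mean) / params.std, params
    raise ValueError(f"unknown mode {mode!r}")


def uv_unscale(scaled: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Inverse of :func:`uv_scale` for the retained columns."""
    return np.asarray(scaled, dtype=float) * params.std + params.mean


# ---------------------------------------------------------------------------
# PCA + Hotelling's T² screening
# ---------------------------------------------------------------------------
@dataclass
class HotellingScreen:
    flags: np.ndarray          # boolean, True = outlier
    t2: np.ndarray             # per-sample T²
    limit: float               # F-distribution control limit
    n_components: int
    alpha: float
    sample_ids: list[str] | None = None

    @property
    def outliers(self) -> list:
        if self.sample_ids is not None:
            return [s for s, f in zip(self.sample_ids, self.flags) if f]
        return list(np.nonzero(self.flags)[0])


def pca_hotelling_screen(
    X,
    alpha: float = 0.01,
    n_components: int | None = None,
    r2x_target: float = 0.8,
    max_components: int = 5,
) -> HotellingScreen:
    """Flag strong multivariate outliers with Hotelling's T² on PCA scores.

    X is UV-scaled internally.  Unless ``n_components`` is given, the score
    space uses the smallest number of principal components reaching a
    cumulative explained X-variance of ``r2x_target`` (capped at
    ``max_components``).  T²ᵢ = Σ_a t²ᵢₐ/λₐ with λₐ the score variance; the
    control limit is A(N−1)/(N−A) · F₁₋α(A, N−A) and samples above it are
    flagged.  Screening is intended as a single pass: flag, remove, refit
    once.
    """
    mat, columns = _as_matrix(X)
    ids = None
    if isinstance(X, pd.DataFrame):
        ids = [str(i) for i in X.index]
    n = mat.shape[0]
    if n < 3:
        raise ModelError("Hotelling screening needs at least 3 samples")
    scaled, _ = uv_scale(mat, "fit")
    u, s, _vt = np.linalg.svd(scaled, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components is None:
        var = s**2
        ratio = np.cumsum(var) / var.sum()
        a = int(np.searchsorted(ratio, r2x_target) + 1)
        a = min(a, max_components, rank)
    else:
        a = int(n_components)
        if a > rank:
            raise ModelError(f"requested {a} components but rank is {rank}")
    if a < 1:
        raise ModelError("no non-trivial principal components")
    if n - a < 2:
        raise ModelError(
            f"N={n} samples with A={a} components leaves no residual degrees "
            "of freedom for the T² limit (need N > A + 1)"
        )
    scores = u[:, :a] * s[:a]
    lam = s[:a] ** 2 / (n - 1)
    t2 = ((scores**2) / lam).sum(axis=1)
    limit = a * (n - 1) / (n - a) * stats.f.ppf(1 - alpha, a, n - a)
    return HotellingScreen(
        flags=t2 > limit, t2=t2, limit=float(limit), n_components=a, alpha=alpha, sample_ids=ids
    )


# ---------------------------------------------------------------------------
# OPLS
# ---------------------------------------------------------------------------
@dataclass
class OplsModel:
    """A fitted single-response O-PLS model (1 predictive + A orthogonal
    components, no PLS-expansion components: "1 + A + 0")."""

    x_scaling: ScalingParams
    y_scaling: ScalingParams
    w: np.ndarray                 # predictive weight, unit norm
    p: np.ndarray                 # predictive loading
    t: np.ndarray                 # predictive score (training)
    q: float                      # response loading
    w_ortho: np.ndarray           # (A, k)
    p_ortho: np.ndarray           # (A, k)
    t_ortho: np.ndarray           # (A, n)
    ssy_components: np.ndarray    # response SS captured per component (pred first)
    stats: dict = field(default_factory=dict)

    @property
    def n_ortho(self) -> int:
        return int(self.w_ortho.shape[0])

    @property
    def n_components_label(self) -> str:
        return f"1 + {self.n_ortho} + 0"

    @property
    def variables(self) -> list[str] | None:
        return self.x_scaling.columns

    def coefficients(self) -> np.ndarray:
        """Regression vector b in scaled space: ŷ_scaled = X_scaled · b."""
        k = self.w.size
        m = np.eye(k)
        for w_o, p_o in zip(self.w_ortho, self.p_ortho):
            m = m @ (np.eye(k) - np.outer(w_o, p_o))
        return m @ self.w * self.q

    def _filter(self, xs: np.ndarray) -> np.ndarray:
        """Remove the model's orthogonal components from scaled data."""
        xs = xs.copy()
        for w_o, p_o in zip(self.w_ortho, self.p_ortho):
            t_o = xs @ w_o
            xs -= np.outer(t_o, p_o)
        return xs

    def predict(self, X_new) -> np.ndarray:
        """Predict responses on the original (1–5) scale.

        New samples are scaled with the stored training parameters, their
        projection on the orthogonal subspace is removed, and the predictive
        projection t = Xw is mapped through q and back-transformed.
        """
        xs, _ = uv_scale(X_new, "apply", self.x_scaling)
        t = self._filter(xs) @ self.w
        return uv_unscale(t * self.q, self.y_scaling).ravel()

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "grapearoma-opls",
            "version": 1,
            "x_scaling": self.x_scaling.to_dict(),
            "y_scaling": self.y_scaling.to_dict(),
            "w": self.w.tolist(),
            "p": self.p.tolist(),
            "t": self.t.tolist(),
            "q": self.q,
            "w_ortho": self.w_ortho.tolist(),
            "p_ortho": self.p_ortho.tolist(),
            "t_ortho": self.t_ortho.tolist(),
            "ssy_components": self.ssy_components.tolist(),
            "n_components_label": self.n_components_label,
            "stats": self.stats,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "OplsModel":
        if d.get("format") != "grapearoma-opls":
            raise ModelError("not a grapearoma OPLS model document")
        k = len(d["w"])
        return cls(
            x_scaling=ScalingParams.from_dict(d["x_scaling"]),
            y_scaling=ScalingParams.from_dict(d["y_scaling"]),
            w=np.asarray(d["w"], dtype=float),
            p=np.asarray(d["p"], dtype=float),
            t=np.asarray(d["t"], dtype=float),
            q=float(d["q"]),
            w_ortho=np.asarray(d["w_ortho"], dtype=float).reshape(-1, k),
            p_ortho=np.asarray(d["p_ortho"], dtype=float).reshape(-1, k),
            t_ortho=np.asarray(d["t_ortho"], dtype=float).reshape(-1, len(d["t"])),
            ssy_components=np.asarray(d["ssy_components"], dtype=float),
            stats=dict(d.get("stats", {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "OplsModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_opls(X, y, n_ortho: int = 0) -> OplsModel:
    """Fit a single-response O-PLS model with ``n_ortho`` orthogonal
    components.  X and y are UV-scaled internally (training statistics are
    stored on the model).  With ``n_ortho=0`` predictions coincide with
    one-component PLS1."""
    ys_raw = np.asarray(y, dtype=float).ravel()
    if ys_raw.std(ddof=1) == 0:
        raise ModelError("response y is constant; cannot fit a regression model")
    if n_ortho < 0:
        raise ModelError("n_ortho must be >= 0")
    xs, x_params = uv_scale(X, "fit")
    ys, y_params = uv_scale(ys_raw[:, None], "fit")
    ys = ys.ravel()
    n, k = xs.shape
    rank = np.linalg.matrix_rank(xs)
    if n_ortho > max(rank - 1, 0):
        raise ModelError(f"n_ortho={n_ortho} exceeds rank−1={rank - 1}")

    xd = xs.copy()
    w = xs.T @ ys
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ModelError("X carries no covariance with y")
    w /= nw

    w_os, p_os, t_os, r2x_parts = [], [], [], []
    for _ in range(n_ortho):
        t = xd @ w
        p = xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            raise ModelError("no orthogonal variation left to extract")
        w_o /= n_o
        t_o = xd @ w_o
        p_o = xd.T @ t_o / (t_o @ t_o)
        xd = xd - np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)
        r2x_parts.append((t_o @ t_o) * (p_o @ p_o))

    t = xd @ w
    p = xd.T @ t / (t @ t)
    q = (ys @ t) / (t @ t)
    yhat_s = t * q
    res_s = ys - yhat_s

    ss_x = (xs**2).sum()
    r2x = (sum(r2x_parts) + (t @ t) * (p @ p)) / ss_x
    ss_y = (ys**2).sum()
    r2y = 1.0 - (res_s**2).sum() / ss_y
    r2 = float(np.corrcoef(yhat_s, ys)[0, 1] ** 2) if yhat_s.std() > 0 else 0.0
    a_total = 1 + n_ortho
    res_raw = res_s * y_params.std[0]
    dof = max(n - 1 - a_total, 1)
    rmsee = float(np.sqrt((res_raw**2).sum() / dof))

    # Response SS captured per component (predictive first, then orthogonal),
    # used as VIP weights.
    ssy = [float((t @ ys) ** 2 / (t @ t))]
    for t_o in t_os:
        ssy.append(float((t_o @ ys) ** 2 / (t_o @ t_o)))

    k_shape = (0, k)
    model = OplsModel(
        x_scaling=x_params,
        y_scaling=y_params,
        w=w,
        p=p,
        t=t,
        q=float(q),
        w_ortho=np.array(w_os, dtype=float) if w_os else np.empty(k_shape),
        p_ortho=np.array(p_os, dtype=float) if p_os else np.empty(k_shape),
        t_ortho=np.array(t_os, dtype=float) if t_os else np.empty((0, n)),
        ssy_components=np.asarray(ssy, dtype=float),
        stats={
            "R2X": float(r2x),
            "R2Y": float(r2y),
            "R2": r2,
            "RMSEE": rmsee,
            "n": int(n),
            "k": int(k),
            "n_ortho": int(n_ortho),
        },
    )
    return model


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------
@dataclass
class CrossValResult:
    chosen_n_ortho: int
    q2y: dict[int, float]          # candidate n_ortho -> Q²Y
    rmsecv: dict[int, float]       # candidate n_ortho -> RMSECV (raw y scale)
    folds: int
    seed: int

    @property
    def chosen_q2y(self) -> float:
        return self.q2y[self.chosen_n_ortho]

    @property
    def chosen_rmsecv(self) -> float:
        return self.rmsecv[self.chosen_n_ortho]


def assign_folds(y, folds: int, seed: int = 0) -> np.ndarray:
    """Deterministic, response-balanced fold assignment.

    Samples are ordered by y; within each consecutive block of ``folds``
    samples the fold labels are a seeded permutation, so every fold covers
    the response range (interleaved sampling of sorted-y order).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if folds > n:
        raise ModelError(f"folds={folds} exceeds N={n}")
    if folds < 2:
        raise ModelError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    assignment = np.empty(n, dtype=int)
    for start in range(0, n, folds):
        block = order[start : start + folds]
        labels = rng.permutation(folds)[: block.size]
        assignment[block] = labels
    return assignment


def cross_validate(
    X,
    y,
    folds: int = 7,
    n_ortho_grid=None,
    seed: int = 0,
    min_improvement: float = 0.01,
    max_ortho: int = 9,
) -> CrossValResult:
    """Choose the orthogonal-component count by k-fold cross-validation.

    Per fold, UV scaling and the model are refitted on the training part
    only; held-out predictions accumulate PRESS.  Q²Y = 1 − PRESS/SS(y) and
    RMSECV = sqrt(PRESS/N) on the original y scale.  The component count
    grows while Q²Y improves by more than ``min_improvement`` (cap
    ``max_ortho``).
    """
    mat, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = yv.size
    if folds > n:
        raise ModelError(f"folds={folds} exceeds N={n}")
    if n_ortho_grid is None:
        n_ortho_grid = range(0, max_ortho + 1)
    assignment = assign_folds(yv, folds, seed)
    ss = ((yv - yv.mean()) ** 2).sum()

    q2y: dict[int, float] = {}
    rmsecv: dict[int, float] = {}
    for a in n_ortho_grid:
        press = 0.0
        try:
            for f in range(folds):
                test = assignment == f
                frame_train = mat[~test]
                model = fit_opls(frame_train, yv[~test], n_ortho=a)
                # positional apply: drop the columns the fold's scaling dropped
                keep = _kept_indices(model.x_scaling, mat.shape[1])
                pred = model.predict(mat[test][:, keep])
                press += ((yv[test] - pred) ** 2).sum()
        except ModelError:
            break
        q2y[a] = 1.0 - press / ss
        rmsecv[a] = float(np.sqrt(press / n))
    if not q2y:
        raise ModelError("cross-validation failed for every candidate component count")

    candidates = sorted(q2y)
    best = candidates[0]
    for a in candidates[1:]:
        if q2y[a] > q2y[best] + min_improvement:
            best = a
        else:
            break
    return CrossValResult(chosen_n_ortho=best, q2y=q2y, rmsecv=rmsecv, folds=folds, seed=seed)


def _kept_indices(params: ScalingParams, total: int) -> np.ndarray:
    """Positional indices of columns retained by a fit (zero-variance drop)."""
    if params.columns is not None or not params.dropped:
        return np.arange(total)
    dropped = {int(i) for i in params.dropped}
    return np.array([i for i in range(total) if i not in dropped])


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------
@dataclass
class PermutationResult:
    """Y-permutation validation of a fixed model configuration.

    ``correlations`` holds |corr(y_perm, y)| per permutation; ``r2y`` and
    ``q2y`` the refitted statistics.  The original (unpermuted) model enters
    the regression lines at correlation 1; ``r2_intercept``/``q2_intercept``
    are the line values at correlation 0.  A negative Q² intercept is the
    classical signature of a non-overfitted model.
    """

    correlations: np.ndarray
    r2y: np.ndarray
    q2y: np.ndarray
    original_r2y: float
    original_q2y: float
    r2_intercept: float
    q2_intercept: float
    n_perm: int


def _line_intercept(x: np.ndarray, y: np.ndarray) -> float:
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept)


def permutation_test(
    X,
    y,
    n_ortho: int,
    folds: int = 7,
    n_perm: int = 200,
    seed: int = 0,
) -> PermutationResult:
    """Refit and cross-validate the model on ``n_perm`` random permutations
    of y, keeping the component count and fold count fixed."""
    if n_perm < 2:
        raise ModelError("n_perm must be >= 2")
    mat, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)

    def _evaluate(y_cur: np.ndarray, cv_seed: int) -> tuple[float, float]:
        model = fit_opls(mat, y_cur, n_ortho=n_ortho)
        cv = cross_validate(
            mat, y_cur, folds=folds, n_ortho_grid=[n_ortho], seed=cv_seed
        )
        return model.stats["R2Y"], cv.q2y[n_ortho]

    orig_r2, orig_q2 = _evaluate(yv, seed)
    cors, r2s, q2s = [], [], []
    for i in range(n_perm):
        yp = rng.permutation(yv)
        r2, q2 = _evaluate(yp, seed + 1 + i)
        c = abs(float(np.corrcoef(yp, yv)[0, 1]))
        cors.append(c)
        r2s.append(r2)
        q2s.append(q2)
    cors_arr = np.array(cors)
    r2_arr = np.array(r2s)
    q2_arr = np.array(q2s)
    xs = np.concatenate([cors_arr, [1.0]])
    return PermutationResult(
        correlations=cors_arr,
        r2y=r2_arr,
        q2y=q2_arr,
        original_r2y=orig_r2,
        original_q2y=orig_q2,
        r2_intercept=_line_intercept(xs, np.concatenate([r2_arr, [orig_r2]])),
        q2_intercept=_line_intercept(xs, np.concatenate([q2_arr, [orig_q2]])),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------
@dataclass
class VipScores:
    vip: pd.Series                 # per-variable VIP, >= 0
    coefficient_sign: pd.Series    # sign of the scaled-space regression vector

    def above(self, cutoff: float = 1.0) -> pd.Series:
        return self.vip[self.vip > cutoff]


def vip(model: OplsModel, kind: str = "total") -> VipScores:
    """Variable importance in projection.

    VIPⱼ = sqrt( K · Σₐ SSYₐ (wₐⱼ/‖wₐ‖)² / Σₐ SSYₐ ), summing over the
    predictive and (for ``kind='total'``) the orthogonal components, with
    SSYₐ the response sum of squares captured by component a.  By
    construction the mean of squared VIPs is exactly 1.  ``kind='pred'``
    restricts the sum to the predictive component.
    """
    k = model.w.size
    weights = [model.w] + [w for w in model.w_ortho]
    ssy = model.ssy_components
    if kind == "pred":
        weights, ssy = weights[:1], ssy[:1]
    elif kind != "total":
        raise ValueError(f"unknown VIP kind {kind!r}")
    total = float(np.sum(ssy))
    if total <= 0:
        raise ModelError("model captured no response variance; VIP undefined")
    acc = np.zeros(k)
    for w_a, ssy_a in zip(weights, ssy):
        wn = w_a / np.linalg.norm(w_a)
        acc += ssy_a * wn**2
    scores = np.sqrt(k * acc / total)
    names = model.variables if model.variables is not None else list(range(k))
    coef = model.coefficients()
    return VipScores(
        vip=pd.Series(scores, index=names, name="vip"),
        coefficient_sign=pd.Series(np.sign(coef), index=names, name="sign"),
    )
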
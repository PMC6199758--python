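"""Two-component multivariate-response PLSR for survival-curve prediction.

The central model: a partial least squares regression of a preparations x
timepoints survival matrix on a preparations x analytes concentration
matrix, both column-standardized, with a small number of latent components
(two by default).  The fitted model yields

* a (p + 1) x q coefficient matrix ``coef_`` with the intercept row first,
  mapping standardized expression to standardized survival,
* per-component variance-explained fractions for both blocks,
* a 2-D loading map of analytes and timepoints on the latent components,
  from which biomarkers are ranked by loading proximity (analytes whose
  loading vectors point where the survival-timepoint loadings point are
  the ones most strongly correlated with survival).

Two algorithms are available.  SIMPLS (default) computes each weight
vector from the projected cross-covariance matrix and is the algorithm
behind MATLAB's ``plsregress``.  NIPALS-style PLS2 deflates the data
blocks instead; its weight fixed point is the dominant left singular
vector of the deflated X'Y, which is computed here directly by SVD (no
iteration).  The two coincide for a univariate response and differ
slightly for multivariate responses.  Both are deterministic; component
signs are fixed so the largest-magnitude entry of each X-weight vector is
positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.isotonic import IsotonicRegression

from .datamodel import ExpressionMatrix, SurvivalCurveMatrix, ValidationError

__all__ = [
    "ColumnStandardizer", "SecretomeSurvivalPLS",
    "variance_explained", "LoadingMap", "loading_map",
    "BiomarkerRanking", "rank_biomarkers_by_proximity",
    "ConsensusResult", "consensus_biomarkers",
    "save_model", "load_model",
]

_SD_TOL = 1e-12


class ColumnStandardizer(BaseEstimator, TransformerMixin):
    """Column-wise z-scoring with sample (n-1) standard deviations.

    Zero-variance columns are mapped to all-zeros and flagged; the inverse
    transform restores them to their (constant) training mean, so the
    round-trip reconstructs the training data exactly.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValidationError("standardization needs a 2-D array with >= 2 rows")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.zero_variance_ = sd < _SD_TOL
        self.scale_ = np.where(self.zero_variance_, 1.0, sd)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        Z[:, self.zero_variance_] = 0.0
        return Z

    def inverse_transform(self, Z):
        Z = np.asarray(Z, dtype=float)
        X = Z * self.scale_ + self.mean_
        X[:, self.zero_variance_] = np.broadcast_to(
            self.mean_[self.zero_variance_], X[:, self.zero_variance_].shape)
        return X


def _fix_signs(R, T, P, Q):
    for a in range(R.shape[1]):
        j = int(np.argmax(np.abs(R[:, a])))
        if R[j, a] < 0:
            R[:, a] *= -1; T[:, a] *= -1; P[:, a] *= -1; Q[:, a] *= -1
    return R, T, P, Q


def _simpls(X0, Y0, A):
    """SIMPLS: weights from the successively projected cross-covariance."""
    n, p = X0.shape
    q = Y0.shape[1]
    S = X0.T @ Y0
    R = np.zeros((p, A)); T = np.zeros((n, A))
    P = np.zeros((p, A)); Q = np.zeros((q, A)); V = np.zeros((p, A))
    for a in range(A):
        u, s, vt = np.linalg.svd(S, full_matrices=False)
        r = u[:, 0]
        t = X0 @ r
        t = t - t.mean()
        normt = np.linalg.norm(t)
        if normt < 1e-300:
            raise ValidationError(
                f"component {a + 1} is degenerate: X block exhausted")
        t /= normt; r = r / normt
        pa = X0.T @ t
        qa = Y0.T @ t
        v = pa.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pa)
        v /= np.linalg.norm(v)
        S = S - np.outer(v, v @ S)
        R[:, a] = r; T[:, a] = t; P[:, a] = pa; Q[:, a] = qa; V[:, a] = v
    return _fix_signs(R, T, P, Q)


def _nipals(X0, Y0, A):
    """PLS2 with block deflation; weights computed exactly via SVD."""
    X = X0.copy(); Y = Y0.copy()
    n, p = X.shape
    q = Y.shape[1]
    W = np.zeros((p, A)); T = np.zeros((n, A))
    P = np.zeros((p, A)); Q = np.zeros((q, A))
    for a in range(A):
        u, s, vt = np.linalg.svd(X.T @ Y, full_matrices=False)
        w = u[:, 0]
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-300:
            raise ValidationError(
                f"component {a + 1} is degenerate: X block exhausted")
        pa = X.T @ t / tt
        qa = Y.T @ t / tt
        X = X - np.outer(t, pa)
        Y = Y - np.outer(t, qa)
        W[:, a] = w; T[:, a] = t; P[:, a] = pa; Q[:, a] = qa
    # scores as a direct map of X0: T = X0 R with R = W (P'W)^-1
    R = W @ np.linalg.inv(P.T @ W)
    # rescale Q to the SIMPLS convention q_a = Y0' t_a (projection numerators)
    return _fix_signs(R, T, P, Q)


class SecretomeSurvivalPLS(BaseEstimator, RegressorMixin):
    """Predict survival curves from secretome concentrations via PLSR.

    Parameters
    ----------
    n_components : int, default 2
        Number of latent components A (must satisfy A <= min(n-1, p)).
    algorithm : {"simpls", "nipals"}, default "simpls"
    clip : bool, default True
        Project predicted proportions into [0, 1].
    monotone : bool, default False
        Replace each predicted curve by its best non-increasing
        approximation (pool-adjacent-violators).
    proximity_metric : {"cosine", "euclidean"}, default "cosine"
        Metric used by :func:`rank_biomarkers_by_proximity`.

    Attributes (after ``fit``)
    --------------------------
    x_weights_ : (p, A) weights R such that scores = X_std @ R
    x_loadings_, y_loadings_ : (p, A), (q, A)
    x_scores_ : (n, A), mutually orthogonal
    coef_ : (p + 1, q) regression coefficients on the standardized scale,
        intercept row first
    x_variance_explained_, y_variance_explained_ : (A,) fractions of the
        standardized block sum of squares captured per component
    x_standardizer_, y_standardizer_ : fitted :class:`ColumnStandardizer`
    analyte_names_, timepoint_labels_, group_names_ : labels (or None)
    """

    def __init__(self, n_components: int = 2, algorithm: str = "simpls",
                 clip: bool = True, monotone: bool = False,
                 proximity_metric: str = "cosine"):
        self.n_components = n_components
        self.algorithm = algorithm
        self.clip = clip
        self.monotone = monotone
        self.proximity_metric = proximity_metric

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        Xf, self.analyte_names_, x_groups = _as_frame(X)
        Yf, self.timepoint_labels_, y_groups = _as_frame(y)
        if x_groups is not None and y_groups is not None:
            if set(x_groups) != set(y_groups):
                raise ValidationError(
                    "expression and survival tables cover different groups: "
                    f"{sorted(map(str, set(x_groups) ^ set(y_groups)))}")
            Yf = Yf.loc[x_groups]
        self.group_names_ = x_groups
        Xv = Xf.to_numpy(dtype=float)
        Yv = Yf.to_numpy(dtype=float)
        n, p = Xv.shape
        if Yv.shape[0] != n:
            raise ValidationError("X and Y row counts differ")
        if n < 3:
            raise ValidationError(f"need at least 3 observations, got {n}")
        A = int(self.n_components)
        if not 1 <= A <= min(n - 1, p):
            raise ValidationError(
                f"n_components={A} must be in [1, min(n-1, p)] = "
                f"[1, {min(n - 1, p)}]")
        if self.algorithm not in ("simpls", "nipals"):
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")

        self.x_standardizer_ = ColumnStandardizer().fit(Xv)
        self.y_standardizer_ = ColumnStandardizer().fit(Yv)
        if self.x_standardizer_.zero_variance_.all():
            raise ValidationError("all X columns are constant")
        X0 = self.x_standardizer_.transform(Xv)
        Y0 = self.y_standardizer_.transform(Yv)

        algo = _simpls if self.algorithm == "simpls" else _nipals
        R, T, P, Q = algo(X0, Y0, A)
        self.x_weights_ = R
        self.x_scores_ = T
        self.x_loadings_ = P
        self.y_loadings_ = Q

        # B on the standardized scale.  For simpls Q stores Y0' t with unit
        # t; for nipals Q stores Y' t / t't -- in both cases B = R Q'.
        B = R @ Q.T
        intercept = Y0.mean(axis=0) - X0.mean(axis=0) @ B
        self.coef_ = np.vstack([intercept, B])

        # variance accounting on the standardized blocks; zero-variance
        # columns are excluded from the denominators
        ss_x = (n - 1) * int((~self.x_standardizer_.zero_variance_).sum())
        ss_y = (n - 1) * int((~self.y_standardizer_.zero_variance_).sum())
        if ss_y == 0:
            raise ValidationError("all Y columns are constant")
        tt = (T * T).sum(axis=0)
        if self.algorithm == "simpls":
            # t has unit norm; p = X0' t, q = Y0' t are projection numerators
            self.x_variance_explained_ = (P * P).sum(axis=0) / ss_x
            self.y_variance_explained_ = (Q * Q).sum(axis=0) / ss_y
        else:
            self.x_variance_explained_ = tt * (P * P).sum(axis=0) / ss_x
            self.y_variance_explained_ = tt * (Q * Q).sum(axis=0) / ss_y
        return self

    # -- prediction --------------------------------------------------------

    def predict(self, X, clip: bool | None = None, monotone: bool | None = None,
                destandardize: bool = True):
        """Predict survival curves for new expression data.

        Labeled input is aligned to the training analytes by name (any
        missing/extra analytes raise).  Returns a
        :class:`SurvivalCurveMatrix` (non-strict: raw regression output
        need not be a valid curve) for labeled input, else an ndarray.
        """
        self._check_fitted()
        clip = self.clip if clip is None else clip
        monotone = self.monotone if monotone is None else monotone
        Xf, names, groups = _as_frame(X)
        if names is not None and self.analyte_names_ is not None:
            missing = [a for a in self.analyte_names_ if a not in set(names)]
            extra = [a for a in names if a not in set(self.analyte_names_)]
            if missing or extra:
                raise ValidationError(
                    f"analyte set mismatch: missing {missing}, extra {extra}")
            Xf = Xf[list(self.analyte_names_)]
        Xv = Xf.to_numpy(dtype=float)
        if Xv.shape[1] != self.coef_.shape[0] - 1:
            raise ValidationError(
                f"expected {self.coef_.shape[0] - 1} analytes, got {Xv.shape[1]}")
        Z = self.x_standardizer_.transform(Xv)
        Zhat = self.coef_[0] + Z @ self.coef_[1:]
        post = []
        if not destandardize:
            out = Zhat
        else:
            out = self.y_standardizer_.inverse_transform(Zhat)
            if clip:
                out = np.clip(out, 0.0, 1.0)
                post.append("clip[0,1]")
            if monotone:
                out = np.apply_along_axis(_pav_nonincreasing, 1, out)
                post.append("monotone(PAV)")
        if groups is not None and self.timepoint_labels_ is not None \
                and destandardize:
            return SurvivalCurveMatrix(
                pd.DataFrame(out, index=groups,
                             columns=list(self.timepoint_labels_)),
                metadata={"predicted": True, "postprocessing": post},
                strict=False)
        return out

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise ValidationError("model is not fitted")


def _as_frame(X):
    """Normalize input to (DataFrame, column labels or None, index or None)."""
    if isinstance(X, ExpressionMatrix):
        return X.frame, list(X.frame.columns), list(X.frame.index)
    if isinstance(X, SurvivalCurveMatrix):
        return X.frame, list(X.frame.columns), list(X.frame.index)
    if isinstance(X, pd.DataFrame):
        return X, list(X.columns), list(X.index)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr), None, None


def _pav_nonincreasing(y: np.ndarray) -> np.ndarray:
    """Best non-increasing approximation in least squares (PAV)."""
    x = np.arange(y.size, dtype=float)
    return IsotonicRegression(increasing=False).fit(x, y).predict(x)


# ---------------------------------------------------------------------------
# model inspection

def variance_explained(model: SecretomeSurvivalPLS) -> pd.DataFrame:
    """Per-component and cumulative variance fractions for both blocks."""
    model._check_fitted()
    xv = model.x_variance_explained_
    yv = model.y_variance_explained_
    return pd.DataFrame({
        "component": np.arange(1, len(xv) + 1),
        "x_fraction": xv, "y_fraction": yv,
        "x_cumulative": np.cumsum(xv), "y_cumulative": np.cumsum(yv),
    })


@dataclass
class LoadingMap:
    """2-D loading coordinates of analytes (predictors) and timepoints."""

    frame: pd.DataFrame   # name, kind in {analyte, timepoint}, comp1, comp2

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def loading_map(model: SecretomeSurvivalPLS) -> LoadingMap:
    """Project analyte and timepoint loadings on the first two components."""
    model._check_fitted()
    if model.x_loadings_.shape[1] < 2:
        raise ValidationError("loading map needs at least 2 components")
    rows = []
    p = model.x_loadings_.shape[0]
    a_names = model.analyte_names_ or [f"x{j}" for j in range(p)]
    q = model.y_loadings_.shape[0]
    t_names = (list(model.timepoint_labels_) if model.timepoint_labels_
               is not None else [f"y{j}" for j in range(q)])
    for name, (c1, c2) in zip(a_names, model.x_loadings_[:, :2]):
        rows.append((str(name), "analyte", c1, c2))
    for name, (c1, c2) in zip(t_names, model.y_loadings_[:, :2]):
        rows.append((str(name), "timepoint", c1, c2))
    return LoadingMap(pd.DataFrame(rows, columns=["name", "kind",
                                                  "comp1", "comp2"]))


@dataclass
class BiomarkerRanking:
    """Analytes ranked by loading proximity to the survival timepoints."""

    frame: pd.DataFrame        # analyte, proximity, rank
    metric: str
    anti_correlated: list      # analytes pointing away from every timepoint
    excluded: list             # degenerate analytes (zero-length loading)

    def top(self, k: int) -> list:
        return list(self.frame.nsmallest(k, "rank")["analyte"])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def rank_biomarkers_by_proximity(model: SecretomeSurvivalPLS,
                                 top_k: int | None = None,
                                 metric: str | None = None) -> BiomarkerRanking:
    """Rank analytes by how close their 2-D loadings sit to any timepoint.

    With the default cosine metric the proximity score is the maximum
    cosine similarity between the analyte's loading vector and any
    timepoint loading vector (in [-1, 1]; angle only, so loading magnitude
    does not conflate variance with direction).  ``metric="euclidean"``
    ranks by negative minimum distance instead.  Ties break by analyte
    name; analytes with zero-length loadings are excluded with a warning.
    """
    model._check_fitted()
    if model.x_loadings_.shape[1] < 2:
        raise ValidationError("proximity ranking needs at least 2 components")
    metric = metric or model.proximity_metric
    if metric not in ("cosine", "euclidean"):
        raise ValidationError(f"unknown proximity metric {metric!r}")
    Xl = model.x_loadings_[:, :2]
    Yl = model.y_loadings_[:, :2]
    a_names = [str(a) for a in (model.analyte_names_
               or [f"x{j}" for j in range(Xl.shape[0])])]
    y_norm = np.linalg.norm(Yl, axis=1)
    Yl = Yl[y_norm > _SD_TOL]
    y_norm = y_norm[y_norm > _SD_TOL]
    if Yl.shape[0] == 0:
        raise ValidationError("all timepoint loadings are degenerate")
    rows, anti, excluded = [], [], []
    for name, u in zip(a_names, Xl):
        nu = np.linalg.norm(u)
        if nu < _SD_TOL:
            excluded.append(name)
            continue
        if metric == "cosine":
            cos = (Yl @ u) / (y_norm * nu)
            prox = float(cos.max())
            if cos.max() < 0:
                anti.append(name)
        else:
            d = np.linalg.norm(Yl - u, axis=1)
            prox = -float(d.min())
        rows.append((name, prox))
    if excluded:
        warnings.warn(f"excluded degenerate analytes: {excluded}", stacklevel=2)
    frame = pd.DataFrame(rows, columns=["analyte", "proximity"])
    frame = frame.sort_values(["proximity", "analyte"],
                              ascending=[False, True], kind="mergesort",
                              ignore_index=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    if top_k is not None:
        frame = frame.head(int(top_k))
    return BiomarkerRanking(frame, metric, anti, excluded)


@dataclass
class ConsensusResult:
    """Intersection of the Pearson-screen and PLSR-proximity hit lists."""

    overlap: list
    n_pearson: int
    n_plsr: int

    @property
    def n_overlap(self) -> int:
        return len(self.overlap)

    def __iter__(self):
        return iter(self.overlap)


def consensus_biomarkers(pearson_hits, plsr_hits) -> ConsensusResult:
    """Analytes flagged by both regression methods, ordered by name."""
    a, b = set(pearson_hits), set(plsr_hits)
    return ConsensusResult(sorted(a & b, key=str), len(a), len(b))


# ---------------------------------------------------------------------------
# serialization

def save_model(model: SecretomeSurvivalPLS, path) -> None:
    """Write a fitted model to JSON (named arrays, labels embedded)."""
    model._check_fitted()
    obj = {
        "format": "secretosurv-pls/1",
        "params": model.get_params(),
        "analyte_names": model.analyte_names_,
        "timepoint_labels": ([float(t) for t in model.timepoint_labels_]
                             if model.timepoint_labels_ is not None else None),
        "group_names": ([str(g) for g in model.group_names_]
                        if model.group_names_ is not None else None),
        "arrays": {
            "x_weights": model.x_weights_.tolist(),
            "x_loadings": model.x_loadings_.tolist(),
            "y_loadings": model.y_loadings_.tolist(),
            "x_scores": model.x_scores_.tolist(),
            "coef": model.coef_.tolist(),
            "x_variance_explained": model.x_variance_explained_.tolist(),
            "y_variance_explained": model.y_variance_explained_.tolist(),
        },
        "x_standardizer": _std_obj(model.x_standardizer_),
        "y_standardizer": _std_obj(model.y_standardizer_),
    }
    Path(path).write_text(json.dumps(obj, indent=1) + "\n", encoding="utf-8")


def load_model(path) -> SecretomeSurvivalPLS:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    if obj.get("format") != "secretosurv-pls/1":
        raise ValidationError(f"not a model file: {path}")
    model = SecretomeSurvivalPLS(**obj["params"])
    model.analyte_names_ = obj["analyte_names"]
    model.timepoint_labels_ = obj["timepoint_labels"]
    model.group_names_ = obj["group_names"]
    arr = obj["arrays"]
    model.x_weights_ = np.asarray(arr["x_weights"])
    model.x_loadings_ = np.asarray(arr["x_loadings"])
    model.y_loadings_ = np.asarray(arr["y_loadings"])
    model.x_scores_ = np.asarray(arr["x_scores"])
    model.coef_ = np.asarray(arr["coef"])
    model.x_variance_explained_ = np.asarray(arr["x_variance_explained"])
    model.y_variance_explained_ = np.asarray(arr["y_variance_explained"])
    model.x_standardizer_ = _std_from(obj["x_standardizer"])
    model.y_standardizer_ = _std_from(obj["y_standardizer"])
    return model


def _std_obj(s: ColumnStandardizer) -> dict:
    return {"mean": s.mean_.tolist(), "scale": s.scale_.tolist(),
            "zero_variance": s.zero_variance_.tolist()}


def _std_from(obj: dict) -> ColumnStandardizer:
    s = ColumnStandardizer()
    s.mean_ = np.asarray(obj["mean"])
    s.scale_ = np.asarray(obj["scale"])
    s.zero_variance_ = np.asarray(obj["zero_variance"], dtype=bool)
    return s
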
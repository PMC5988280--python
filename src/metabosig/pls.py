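"""Projection-to-latent-structures chemometrics.

Implements NIPALS PLS / PLS-DA and OPLS-DA (orthogonal signal partitioning),
the standard model diagnostics used in metabolomics workflows — VIP, p(corr),
seven-fold cross-validated Q2, CV-ANOVA, jack-knife weight uncertainty — plus
the model acceptance rules and the iterative low-VIP variable exclusion used
to reduce a model to its most discriminant variables.

Conventions
-----------
* Tables arrive column-autoscaled (see :mod:`metabosig.preprocess`); the
  response is centred internally.  Binary class labels are coded {0, 1} in
  sorted label order and predicted with a 0.5 threshold.
* Q2(cum) defaults to the additive rule 1 - PRESS/SS where SS is the
  cross-validated sum of squares of the mean-only model, so a model that
  predicts the training mean scores exactly 0.  A per-component
  multiplicative rule is available via ``q2_rule="multiplicative"``.
* "Eigenvalues" in the rejection rule are per-component score sums of
  squares t'>t / (N - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import FeatureTable

__all__ = [
    "PlsFit", "ModelQuality", "CvResult", "JackknifeCI", "PcaScreen",
    "pca_screen", "fit_pls", "fit_oplsda", "vip", "pcorr",
    "cross_validate", "cv_anova", "classify_status", "jackknife_ci",
    "optimize_by_exclusion", "ExclusionResult", "top_discriminants",
    "evaluate_model",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PlsFit:
    """A fitted (O)PLS(-DA) model on an autoscaled table."""

    features: list[str]
    level_meta: str
    n_pred: int
    n_orth: int
    W: np.ndarray            # X-weights, feature x comp
    P: np.ndarray            # X-loadings
    T: np.ndarray            # X-scores, sample x comp
    C: np.ndarray            # y-loadings, per comp
    W_o: np.ndarray | None
    P_o: np.ndarray | None
    T_o: np.ndarray | None
    r2x_cum: float
    r2y_cum: float
    vip: np.ndarray
    pcorr: np.ndarray
    converged: bool
    n_iter: list[int]
    y_mean: float
    classes: list | None
    eigenvalues: np.ndarray
    q2_cum: float | None = None

    def x_rotations(self) -> np.ndarray:
        """W* = W (P'W)^-1 so that T = X W*."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    def _filter_orthogonal(self, X: np.ndarray) -> np.ndarray:
        if self.n_orth == 0:
            return X
        Xf = X.copy()
        for a in range(self.n_orth):
            t_o = Xf @ self.W_o[:, a]
            Xf -= np.outer(t_o, self.P_o[:, a])
        return Xf

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Numeric prediction (centred-y scale restored)."""
        Xf = self._filter_orthogonal(np.asarray(X, dtype=float))
        T = Xf @ self.x_rotations()
        return T @ self.C + self.y_mean

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        if self.classes is None:
            raise ValueError("not a discriminant model")
        yhat = self.predict(X)
        return np.where(yhat >= 0.5, self.classes[1], self.classes[0])


@dataclass
class CvResult:
    """Cross-validation outcome: PRESS, Q2 and per-fold sub-model weights."""

    q2_cum: float
    q2_per_comp: list[float]
    press: float
    ss0: float
    n: int
    dof_model: int
    fold_ids: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    sub_weights: np.ndarray   # fold x feature, first predictive component


@dataclass
class ModelQuality:
    q2_cum: float
    r2x_cum: float
    r2y_cum: float
    cv_anova_F: float
    cv_anova_p: float
    eigenvalues: np.ndarray
    status: str = "unset"


@dataclass
class JackknifeCI:
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    estimate: np.ndarray
    unstable: bool


@dataclass
class PcaScreen:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    t2: np.ndarray
    t2_crit: float
    outliers: np.ndarray


@dataclass
class ExclusionResult:
    fit: PlsFit
    quality: ModelQuality
    cv: CvResult
    features: list[str]
    excluded: list[str]
    log: list[tuple[str, float]]   # (feature removed, Q2 after removal)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _encode_y(table: FeatureTable) -> tuple[np.ndarray, list | None]:
    if table.y_kind == "class":
        classes = table.classes
        if len(classes) != 2:
            raise ValueError(f"discriminant models need 2 classes, got {classes}")
        y = np.array([classes.index(v) for v in table.y], dtype=float)
        return y, classes
    y = np.asarray(table.y, dtype=float)
    return y, None


def _nipals(X: np.ndarray, y: np.ndarray, n_comp: int, max_iter: int, tol: float):
    """NIPALS with single-column response; returns weights/loadings/scores.

    With one y column the inner loop converges at the first iteration, but the
    general iteration (with a ``max_iter`` cap) is retained so convergence is
    always checked and recorded.
    """
    n, p = X.shape
    Xd = X.copy()
    yd = y.copy()
    W = np.zeros((p, n_comp))
    P = np.zeros((p, n_comp))
    T = np.zeros((n, n_comp))
    C = np.zeros(n_comp)
    n_iter, converged = [], True
    for a in range(n_comp):
        u = yd.copy()
        w = np.zeros(p)
        it = 0
        for it in range(1, max_iter + 1):
            w_new = Xd.T @ u / (u @ u + _EPS)
            nw = np.linalg.norm(w_new)
            if nw < _EPS:
                raise ValueError("zero weight vector: no covariance left in X'y")
            w_new /= nw
            t = Xd @ w_new
            c = (yd @ t) / (t @ t + _EPS)
            u_new = yd * 1.0  # single-column y: u = y c / c^2 is collinear with y
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        else:
            converged = False
        n_iter.append(it)
        t = Xd @ w
        c = (yd @ t) / (t @ t + _EPS)
        pload = Xd.T @ t / (t @ t + _EPS)
        Xd -= np.outer(t, pload)
        yd = yd - c * t
        W[:, a], P[:, a], T[:, a], C[a] = w, pload, t, c
    return W, P, T, C, n_iter, converged


def _vip_scores(W: np.ndarray, T: np.ndarray, C: np.ndarray) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SSY_a (w_aj/||w_a||)^2 / sum_a SSY_a)."""
    p, A = W.shape
    ssy = np.array([(T[:, a] @ T[:, a]) * C[a] ** 2 for a in range(A)])
    if ssy.sum() < _EPS:
        return np.full(p, 1.0)
    wnorm2 = (W / (np.linalg.norm(W, axis=0, keepdims=True) + _EPS)) ** 2
    return np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())


def _pcorr_scores(t1: np.ndarray, X: np.ndarray) -> np.ndarray:
    tc = t1 - t1.mean()
    Xc = X - X.mean(axis=0)
    denom = np.linalg.norm(tc) * np.linalg.norm(Xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ tc) / denom
    return np.clip(np.nan_to_num(r), -1.0, 1.0)


def _orthogonal_filter(X: np.ndarray, y: np.ndarray, n_orth: int):
    """Extract class-orthogonal components (predictive weight stays X'y)."""
    Xf = X.copy()
    n, p = X.shape
    W_o = np.zeros((p, n_orth))
    P_o = np.zeros((p, n_orth))
    T_o = np.zeros((n, n_orth))
    for a in range(n_orth):
        w = Xf.T @ y
        nw = np.linalg.norm(w)
        if nw < _EPS:
            raise ValueError("no predictive direction left")
        w /= nw
        t = Xf @ w
        pload = Xf.T @ t / (t @ t + _EPS)
        w_o = pload - (w @ pload) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < _EPS:
            raise ValueError(
                f"no orthogonal variation left for component {a + 1}"
            )
        w_o /= n_wo
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o + _EPS)
        Xf -= np.outer(t_o, p_o)
        W_o[:, a], P_o[:, a], T_o[:, a] = w_o, p_o, t_o
    return Xf, W_o, P_o, T_o


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def pca_screen(table: FeatureTable, n_comp: int = 2) -> PcaScreen:
    """SVD-based PCA screening with Hotelling T2 outlier flags (95% limit)."""
    X = np.asarray(table.X, dtype=float)
    n, p = X.shape
    if n_comp > min(n - 1, p):
        raise ValueError("n_comp exceeds min(rows - 1, features)")
    Xc = X - X.mean(axis=0)
    total_var = (Xc ** 2).sum()
    if total_var < _EPS:
        raise ValueError("degenerate (constant) table")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_comp] * s[:n_comp]
    loadings = Vt[:n_comp].T
    evr = (s ** 2 / total_var)[:n_comp]
    lam = s[:n_comp] ** 2 / (n - 1)
    t2 = ((scores ** 2) / lam).sum(axis=1)
    a = n_comp
    t2_crit = a * (n - 1) * (n + 1) / (n * (n - a)) * stats.f.ppf(0.95, a, n - a)
    return PcaScreen(scores, loadings, evr, t2, float(t2_crit), t2 > t2_crit)


def fit_pls(
    table: FeatureTable,
    n_comp: int,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> PlsFit:
    """NIPALS PLS(-DA) with ``n_comp`` predictive components."""
    if n_comp < 1:
        raise ValueError("n_comp must be >= 1")
    X = np.asarray(table.X, dtype=float)
    y, classes = _encode_y(table)
    if np.std(y) < _EPS:
        raise ValueError("zero-variance response")
    y_mean = float(y.mean())
    yc = y - y_mean
    W, P, T, C, n_iter, converged = _nipals(X, yc, n_comp, max_iter, tol)
    ssx = (X ** 2).sum()
    ssy = (yc ** 2).sum()
    r2x = sum((T[:, a] @ T[:, a]) * (P[:, a] @ P[:, a]) for a in range(n_comp)) / ssx
    r2y = sum((T[:, a] @ T[:, a]) * C[a] ** 2 for a in range(n_comp)) / ssy
    vip_ = _vip_scores(W, T, C)
    eig = np.array([(T[:, a] @ T[:, a]) / (len(y) - 1) for a in range(n_comp)])
    return PlsFit(
        features=list(table.features), level_meta=f"{table.level}/{table.response_name}",
        n_pred=n_comp, n_orth=0, W=W, P=P, T=T, C=C,
        W_o=None, P_o=None, T_o=None,
        r2x_cum=float(min(r2x, 1.0)), r2y_cum=float(min(r2y, 1.0)),
        vip=vip_, pcorr=_pcorr_scores(T[:, 0], X),
        converged=converged, n_iter=n_iter, y_mean=y_mean, classes=classes,
        eigenvalues=eig,
    )


def fit_oplsda(
    table: FeatureTable,
    n_orth: int,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> PlsFit:
    """OPLS-DA: remove ``n_orth`` class-orthogonal components, then one
    predictive component."""
    if n_orth < 1:
        raise ValueError("n_orth must be >= 1 (use fit_pls for plain PLS-DA)")
    X = np.asarray(table.X, dtype=float)
    y, classes = _encode_y(table)
    if classes is None:
        raise ValueError("OPLS-DA requires a binary class response")
    n, p = X.shape
    if n_orth >= min(n - 1, p):
        raise ValueError("n_orth must be below the rank of X")
    y_mean = float(y.mean())
    yc = y - y_mean
    Xf, W_o, P_o, T_o = _orthogonal_filter(X, yc, n_orth)
    W, P, T, C, n_iter, converged = _nipals(Xf, yc, 1, max_iter, tol)
    ssx = (X ** 2).sum()
    ssy = (yc ** 2).sum()
    r2x_pred = (T[:, 0] @ T[:, 0]) * (P[:, 0] @ P[:, 0]) / ssx
    r2x_orth = sum(
        (T_o[:, a] @ T_o[:, a]) * (P_o[:, a] @ P_o[:, a]) for a in range(n_orth)
    ) / ssx
    r2y = (T[:, 0] @ T[:, 0]) * C[0] ** 2 / ssy
    eig_pred = np.array([(T[:, 0] @ T[:, 0]) / (n - 1)])
    eig_orth = np.array([(T_o[:, a] @ T_o[:, a]) / (n - 1) for a in range(n_orth)])
    return PlsFit(
        features=list(table.features), level_meta=f"{table.level}/{table.response_name}",
        n_pred=1, n_orth=n_orth, W=W, P=P, T=T, C=C,
        W_o=W_o, P_o=P_o, T_o=T_o,
        r2x_cum=float(min(r2x_pred + r2x_orth, 1.0)), r2y_cum=float(min(r2y, 1.0)),
        vip=_vip_scores(W, T, C), pcorr=_pcorr_scores(T[:, 0], X),
        converged=converged, n_iter=n_iter, y_mean=y_mean, classes=classes,
        eigenvalues=np.concatenate([eig_pred, eig_orth]),
    )


def vip(fit: PlsFit) -> np.ndarray:
    """Variable importance in projection; mean(VIP^2) = 1 by construction."""
    return fit.vip


def pcorr(fit: PlsFit, table: FeatureTable) -> np.ndarray:
    """Correlation between the first predictive score and each feature column."""
    return _pcorr_scores(fit.T[:, 0], np.asarray(table.X, dtype=float))


def _make_folds(y: np.ndarray, classes, folds: int, rng: np.random.Generator):
    """Deterministic fold ids; stratified for class responses."""
    n = len(y)
    ids = np.empty(n, dtype=int)
    if classes is not None:
        for cls_val in (0.0, 1.0):
            idx = np.flatnonzero(y == cls_val)
            if len(idx) < 2:
                raise ValueError("a class has fewer than 2 members")
            idx = rng.permutation(idx)
            ids[idx] = np.arange(len(idx)) % folds
        # ensure each non-empty fold keeps both classes
        for f in range(folds):
            mask = ids == f
            if mask.any() and len(np.unique(y[mask])) < 2 and n >= 2 * folds:
                raise ValueError("stratification failed: a fold lost a class")
    else:
        idx = rng.permutation(n)
        ids[idx] = np.arange(n) % folds
    return ids


def cross_validate(
    table: FeatureTable,
    n_comp: int = 1,
    folds: int = 7,
    fold_seed: int = 0,
    n_orth: int = 0,
    q2_rule: str = "additive",
    max_iter: int = 200,
) -> CvResult:
    """K-fold (default 1/7th-out) cross-validation of a PLS or OPLS model.

    Each sample is predicted exactly once.  SS is the cross-validated sum of
    squares of the mean-only model, so PRESS = SS gives Q2 = 0 exactly.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(table.X, dtype=float)
    y, classes = _encode_y(table)
    n = len(y)
    rng = np.random.default_rng(fold_seed)
    fold_ids = _make_folds(y, classes, folds, rng)

    press_per_comp = np.zeros(n_comp)
    ss0 = 0.0
    y_pred = np.zeros(n)
    sub_weights = []
    full_resid_ss = None
    for f in np.unique(fold_ids):
        te = fold_ids == f
        tr = ~te
        y_tr_mean = y[tr].mean()
        yc_tr = y[tr] - y_tr_mean
        if np.std(yc_tr) < _EPS:
            raise ValueError("zero-variance response in a training fold")
        Xtr, Xte = X[tr], X[te]
        if n_orth > 0:
            Xtr, W_o, P_o, _ = _orthogonal_filter(Xtr, yc_tr, n_orth)
            Xte = Xte.copy()
            for a in range(n_orth):
                t_o = Xte @ W_o[:, a]
                Xte -= np.outer(t_o, P_o[:, a])
        W, P, T, C, _, _ = _nipals(Xtr, yc_tr, n_comp, max_iter, 1e-10)
        sub_weights.append(W[:, 0])
        ss0 += float(((y[te] - y_tr_mean) ** 2).sum())
        # accumulate test predictions component by component (NIPALS nesting)
        Xd = Xte.copy()
        yhat = np.full(te.sum(), y_tr_mean)
        for a in range(n_comp):
            t = Xd @ W[:, a]
            yhat = yhat + C[a] * t
            Xd = Xd - np.outer(t, P[:, a])
            press_per_comp[a] += float(((y[te] - yhat) ** 2).sum())
        y_pred[te] = yhat

    press = float(press_per_comp[-1])
    if q2_rule == "additive":
        q2_per_comp = [1.0 - press_per_comp[a] / ss0 for a in range(n_comp)]
        q2_cum = q2_per_comp[-1]
    elif q2_rule == "multiplicative":
        # per-component PRESS ratios against the residual SS of the full model
        yc = y - y.mean()
        fit = (fit_oplsda(table, n_orth, max_iter) if n_orth > 0
               else fit_pls(table, n_comp, max_iter))
        resid_ss = [float((yc ** 2).sum())]
        resid = yc.copy()
        for a in range(fit.n_pred):
            resid = resid - fit.C[a] * fit.T[:, a]
            resid_ss.append(float((resid ** 2).sum()))
        ratios = []
        prev = ss0
        for a in range(n_comp):
            ratios.append(press_per_comp[a] / prev)
            prev = resid_ss[min(a + 1, len(resid_ss) - 1)]
        q2_cum = 1.0 - float(np.prod(ratios))
        q2_per_comp = [1.0 - float(np.prod(ratios[: a + 1])) for a in range(n_comp)]
    else:
        raise ValueError(f"unknown q2_rule {q2_rule!r}")

    return CvResult(
        q2_cum=float(q2_cum), q2_per_comp=[float(v) for v in q2_per_comp],
        press=press, ss0=float(ss0), n=n, dof_model=n_comp + n_orth,
        fold_ids=fold_ids, y_true=y, y_pred=y_pred,
        sub_weights=np.vstack(sub_weights),
    )


def cv_anova(cv: CvResult) -> tuple[float, float]:
    """F-test of cross-validated predictive residuals vs the mean-only model.

    F = [(SS0 - PRESS)/(DF0 - DF)] / [PRESS/DF] with DF0 = N - 1 and
    DF = N - 1 - (number of fitted components); p from the F(DF0-DF, DF) tail.
    """
    df0 = cv.n - 1
    df = cv.n - 1 - cv.dof_model
    if df <= 0 or df0 <= df:
        raise ValueError("non-positive degrees of freedom for CV-ANOVA")
    F = ((cv.ss0 - cv.press) / (df0 - df)) / (cv.press / df)
    if F <= 0:
        return float(F), 1.0
    return float(F), float(stats.f.sf(F, df0 - df, df))


def classify_status(quality: ModelQuality) -> str:
    """Apply the rejection/robustness rules.

    Rejected when Q2(cum) < 0, or Q2(cum) < 0.05 with any component
    eigenvalue > 2; robust when Q2 > 0.40 and R2Y > 0.50; acceptable
    otherwise.
    """
    q2 = quality.q2_cum
    if q2 < 0:
        return "rejected"
    if q2 < 0.05 and np.any(np.asarray(quality.eigenvalues) > 2):
        return "rejected"
    if q2 > 0.40 and quality.r2y_cum > 0.50:
        return "robust"
    return "acceptable"


def jackknife_ci(cv: CvResult, conf: float = 0.95) -> JackknifeCI:
    """Jack-knife weight uncertainty from the CV sub-models.

    Sub-model first-component weights are sign-aligned to their consensus
    before the SE computation; an alignment correlation below 0.3 flags the
    interval as unstable.
    """
    Wk = cv.sub_weights.copy()
    g = Wk.shape[0]
    if g < 3:
        raise ValueError("need >= 3 CV sub-models")
    ref = Wk[0]
    unstable = False
    for k in range(g):
        denom = np.linalg.norm(Wk[k]) * np.linalg.norm(ref)
        r = float(Wk[k] @ ref / denom) if denom > _EPS else 0.0
        if r < 0:
            Wk[k] = -Wk[k]
            r = -r
        if r < 0.3:
            unstable = True
    if unstable:
        warnings.warn("jack-knife sign alignment weak (|corr| < 0.3); "
                      "confidence intervals flagged unstable", stacklevel=2)
    mean = Wk.mean(axis=0)
    se = np.sqrt((g - 1) / g * ((Wk - mean) ** 2).sum(axis=0))
    tq = stats.t.ppf(0.5 + conf / 2, g - 1)
    return JackknifeCI(
        se=se, ci_lower=mean - tq * se, ci_upper=mean + tq * se,
        estimate=mean, unstable=unstable,
    )


def _fit_and_cv(table, model, n_comp, n_orth, folds, fold_seed, q2_rule):
    if model == "oplsda":
        fit = fit_oplsda(table, n_orth)
        cv = cross_validate(table, 1, folds, fold_seed, n_orth=n_orth, q2_rule=q2_rule)
    else:
        fit = fit_pls(table, n_comp)
        cv = cross_validate(table, n_comp, folds, fold_seed, q2_rule=q2_rule)
    fit.q2_cum = cv.q2_cum
    F, p = cv_anova(cv)
    quality = ModelQuality(
        q2_cum=cv.q2_cum, r2x_cum=fit.r2x_cum, r2y_cum=fit.r2y_cum,
        cv_anova_F=F, cv_anova_p=p, eigenvalues=fit.eigenvalues,
    )
    quality.status = classify_status(quality)
    return fit, quality, cv


def evaluate_model(
    table: FeatureTable,
    model: str = "auto",
    folds: int = 7,
    fold_seed: int = 0,
    q2_rule: str = "additive",
    max_components: int = 3,
    improvement: float = 0.01,
) -> tuple[PlsFit, ModelQuality, CvResult]:
    """Fit with cross-validated complexity selection.

    ``model="auto"`` uses OPLS-DA for binary class responses and PLS for
    continuous ones.  Components (orthogonal for OPLS-DA, predictive for PLS)
    are added while Q2 improves by more than ``improvement`` (cap
    ``max_components``); an OPLS-DA that never benefits from an orthogonal
    component falls back to 1-component PLS-DA.
    """
    if model == "auto":
        model = "oplsda" if table.y_kind == "class" else "pls"
    if model == "plsda":
        model = "pls"
    if model == "oplsda":
        best = _fit_and_cv(table, "pls", 1, 0, folds, fold_seed, q2_rule)
        for n_orth in range(1, max_components + 1):
            try:
                cand = _fit_and_cv(table, "oplsda", 1, n_orth, folds, fold_seed, q2_rule)
            except ValueError:
                break
            if cand[1].q2_cum > best[1].q2_cum + improvement:
                best = cand
            else:
                break
        return best
    best = _fit_and_cv(table, "pls", 1, 0, folds, fold_seed, q2_rule)
    for n_comp in range(2, max_components + 1):
        cand = _fit_and_cv(table, "pls", n_comp, 0, folds, fold_seed, q2_rule)
        if cand[1].q2_cum > best[1].q2_cum + improvement:
            best = cand
        else:
            break
    return best


def optimize_by_exclusion(
    table: FeatureTable,
    model: str = "auto",
    patience: int = 5,
    min_features: int = 3,
    folds: int = 7,
    fold_seed: int = 0,
    q2_rule: str = "additive",
) -> ExclusionResult:
    """Iteratively drop the lowest-VIP feature and keep the best-Q2 model.

    Ties on VIP break by lower \\|p(corr)\\| then name order.  Stops after
    ``patience`` consecutive removals without a Q2 improvement, or when fewer
    than ``min_features`` + 1 features remain.
    """
    current = table
    fit, quality, cv = evaluate_model(current, model, folds, fold_seed, q2_rule)
    # complexity is chosen once on the full table and then held fixed
    kind = "oplsda" if fit.n_orth > 0 else "pls"
    n_comp, n_orth = fit.n_pred, fit.n_orth
    best = ExclusionResult(fit, quality, cv, list(current.features), [], [])
    best_q2 = quality.q2_cum
    excluded: list[str] = []
    log_: list[tuple[str, float]] = []
    since_improve = 0
    while current.n_features > min_features and since_improve < patience:
        order = sorted(
            range(current.n_features),
            key=lambda j: (fit.vip[j], abs(fit.pcorr[j]), current.features[j]),
        )
        victim = current.features[order[0]]
        keep = [f for f in current.features if f != victim]
        current = current.select(keep)
        excluded.append(victim)
        fit, quality, cv = _fit_and_cv(current, kind, n_comp, n_orth,
                                       folds, fold_seed, q2_rule)
        log_.append((victim, quality.q2_cum))
        if quality.q2_cum > best_q2:
            best = ExclusionResult(fit, quality, cv, list(current.features),
                                   list(excluded), [])
            best_q2 = quality.q2_cum
            since_improve = 0
        else:
            since_improve += 1
    best.log = log_
    return best


def top_discriminants(fit: PlsFit, k: int = 15) -> list[str]:
    """Top-k features by VIP; ties break by |p(corr)| then name."""
    p = len(fit.features)
    if k > p:
        warnings.warn(f"k={k} exceeds {p} features; returning all", stacklevel=2)
        k = p
    order = sorted(
        range(p),
        key=lambda j: (-fit.vip[j], -abs(fit.pcorr[j]), fit.features[j]),
    )
    return [fit.features[j] for j in order[:k]]
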
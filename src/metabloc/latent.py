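"""NIPALS PLS-DA / OPLS-DA, cross-validated Q2Y, permutation validation, VIP.

The class contrast is binary (Prem vs Term); the dummy response is coded
{0, 1} and centered, so PLS-DA reduces to single-response (PLS1) NIPALS,
which is non-iterative per component:

    w_a = X_a' y_a / ||.||,  t_a = X_a w_a,  p_a = X_a' t_a / t_a't_a,
    c_a = y_a' t_a / t_a't_a,  X_{a+1} = X_a - t_a p_a',  y_{a+1} = y_a - c_a t_a.

OPLS-DA (Trygg-Wold orthogonal signal correction) removes components of
X uncorrelated with y before extracting one predictive component; the
predictive score t1 concentrates the class-related variation and serves
as a block's summary in the multiblock model.

Model quality is reported as R2Y (in-fit) and Q2Y (out-of-fold PRESS,
stratified K-fold with autoscaling re-estimated inside each training
fold) and validated by label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LatentModel",
    "PermutationResult",
    "fit_plsda",
    "fit_oplsda",
    "predict",
    "cross_validate_q2",
    "permutation_test",
    "vip_scores",
    "vip_table",
    "normality_threshold",
]

_EPS = 1e-12


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray, list, list]:
    """Coerce inputs to arrays; dummy-code a binary label vector as {0, 1}."""
    if hasattr(X, "data") and isinstance(getattr(X, "data"), pd.DataFrame):
        X = X.data
    if isinstance(X, pd.DataFrame):
        features = list(X.columns)
        samples = list(X.index)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        features = list(range(Xv.shape[1]))
        samples = list(range(Xv.shape[0]))
    yv = np.asarray(y)
    if yv.dtype.kind in "OUS" or set(np.unique(yv).tolist()) - {0, 1, 0.0, 1.0}:
        levels = sorted(pd.unique(pd.Series(yv)))
        if len(levels) != 2:
            raise ValueError(f"exactly two classes required, got {levels}")
        yv = (pd.Series(yv) == levels[1]).to_numpy(dtype=float)
    else:
        yv = yv.astype(float)
        if len(np.unique(yv)) != 2:
            raise ValueError("exactly two classes required (both must be present)")
    if yv.shape[0] != Xv.shape[0]:
        raise ValueError("X and y have different numbers of samples")
    return Xv, yv, features, samples


@dataclass
class LatentModel:
    """A fitted PLS-DA or OPLS-DA model (binary class, PLS1 NIPALS)."""

    kind: str
    weights: np.ndarray          # p x A, unit columns
    loadings: np.ndarray         # p x A
    scores: np.ndarray           # n x A, predictive scores (t1 = first column)
    y_loadings: np.ndarray       # A,
    r2y: float
    x_means: np.ndarray
    y_mean: float
    feature_names: list
    sample_names: list
    ortho_weights: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    ortho_loadings: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    ortho_scores: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    q2y: float | None = None

    @property
    def n_predictive(self) -> int:
        return self.weights.shape[1]

    @property
    def n_orthogonal(self) -> int:
        return self.ortho_weights.shape[1] if self.ortho_weights.size else 0

    @property
    def t1(self) -> np.ndarray:
        return self.scores[:, 0]


def _sign_fix(w: np.ndarray) -> float:
    """Sign convention: the largest-magnitude weight element is positive."""
    j = int(np.argmax(np.abs(w)))
    return -1.0 if w[j] < 0 else 1.0


def fit_plsda(X, y, n_components: int = 2) -> LatentModel:
    """Fit a PLS-DA model by NIPALS on centered X and centered dummy y."""
    Xv, yv, features, samples = _as_xy(X, y)
    n, p = Xv.shape
    if n_components < 1:
        raise ValueError("n_components must be at least 1")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds the rank bound min(n-1, p)={min(n - 1, p)}"
        )
    x_means = Xv.mean(axis=0)
    X0 = Xv - x_means
    y_mean = yv.mean()
    y0 = yv - y_mean
    ss_tot = float(y0 @ y0)
    if ss_tot <= 0:
        raise ValueError("response has no variance (single class?)")

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    C = np.zeros(n_components)
    for a in range(n_components):
        wv = X0.T @ y0
        nw = np.linalg.norm(wv)
        if nw < _EPS:
            raise ValueError(f"n_components={n_components} exceeds the effective rank of X")
        w = wv / nw
        t = X0 @ w
        tt = float(t @ t)
        if tt < _EPS:
            raise ValueError(f"n_components={n_components} exceeds the effective rank of X")
        sgn = _sign_fix(w)
        w, t = sgn * w, sgn * t
        pv = X0.T @ t / tt
        c = float(y0 @ t) / tt
        X0 = X0 - np.outer(t, pv)
        y0 = y0 - c * t
        W[:, a], P[:, a], T[:, a], C[a] = w, pv, t, c

    r2y = 1.0 - float(y0 @ y0) / ss_tot
    return LatentModel(
        kind="plsda",
        weights=W,
        loadings=P,
        scores=T,
        y_loadings=C,
        r2y=r2y,
        x_means=x_means,
        y_mean=float(y_mean),
        feature_names=features,
        sample_names=samples,
    )


def fit_oplsda(X, y, n_orthogonal: int = 1) -> LatentModel:
    """Fit an OPLS-DA model: n_orthogonal filtering components + 1 predictive.

    The orthogonal weights are built from the part of the loading vector
    orthogonal to w (Trygg-Wold), so each orthogonal score has exactly
    zero covariance with y and with the final predictive score t1.
    """
    Xv, yv, features, samples = _as_xy(X, y)
    n, p = Xv.shape
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be non-negative")
    x_means = Xv.mean(axis=0)
    X0 = Xv - x_means
    y_mean = yv.mean()
    y0 = yv - y_mean
    ss_tot = float(y0 @ y0)
    if ss_tot <= 0:
        raise ValueError("response has no variance (single class?)")

    wv = X0.T @ y0
    nw = np.linalg.norm(wv)
    if nw < _EPS:
        raise ValueError("X carries no covariance with y; cannot fit")
    w = wv / nw

    Wo = np.zeros((p, n_orthogonal))
    Po = np.zeros((p, n_orthogonal))
    To = np.zeros((n, n_orthogonal))
    for a in range(n_orthogonal):
        t = X0 @ w
        pv = X0.T @ t / float(t @ t)
        wo = pv - float(w @ pv) * w
        nwo = np.linalg.norm(wo)
        if nwo < 1e-8 * max(np.linalg.norm(pv), 1.0):
            # no y-orthogonal structure left (e.g. rank-deficient X):
            # remaining components stay zero
            break
        wo = wo / nwo
        to = X0 @ wo
        po = X0.T @ to / float(to @ to)
        X0 = X0 - np.outer(to, po)
        Wo[:, a], Po[:, a], To[:, a] = wo, po, to

    # predictive component from the filtered matrix
    wv = X0.T @ y0
    w = wv / np.linalg.norm(wv)
    t = X0 @ w
    tt = float(t @ t)
    sgn = _sign_fix(w)
    w, t = sgn * w, sgn * t
    pv = X0.T @ t / tt
    c = float(y0 @ t) / tt
    resid = y0 - c * t
    r2y = 1.0 - float(resid @ resid) / ss_tot

    return LatentModel(
        kind="oplsda",
        weights=w[:, None],
        loadings=pv[:, None],
        scores=t[:, None],
        y_loadings=np.array([c]),
        r2y=r2y,
        x_means=x_means,
        y_mean=float(y_mean),
        feature_names=features,
        sample_names=samples,
        ortho_weights=Wo,
        ortho_loadings=Po,
        ortho_scores=To,
    )


def predict(model: LatentModel, X) -> np.ndarray:
    """Predict the (uncentered) dummy response for new samples.

    For OPLS-DA the orthogonal filtering is applied to the new samples
    before projecting onto the predictive component.
    """
    if hasattr(X, "data") and isinstance(getattr(X, "data"), pd.DataFrame):
        X = X.data
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    X0 = Xv - model.x_means
    if model.kind == "oplsda":
        for a in range(model.n_orthogonal):
            wo = model.ortho_weights[:, a]
            if not np.any(wo):
                continue
            to = X0 @ wo
            X0 = X0 - np.outer(to, model.ortho_loadings[:, a])
        t = X0 @ model.weights[:, 0]
        return model.y_mean + model.y_loadings[0] * t
    W, P, C = model.weights, model.loadings, model.y_loadings
    # B = W (P'W)^{-1} C  (standard PLS1 regression coefficients)
    B = W @ np.linalg.solve(P.T @ W, C)
    return model.y_mean + X0 @ B


def _fold_scale(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Autoscale using training-fold parameters only; constant columns get scale 1."""
    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=1)
    sds = np.where(sds <= 0, 1.0, sds)
    return (train - means) / sds, (test - means) / sds


def cross_validate_q2(
    X,
    y,
    n_components: int = 2,
    n_folds: int = 7,
    seed: int = 0,
    scale: bool = True,
    kind: str = "plsda",
) -> float:
    """Out-of-fold predictive ability Q2Y = 1 - PRESS / SS_tot.

    Stratified K-fold so both classes appear in every training fold;
    autoscaling parameters are re-estimated on each training fold and
    applied to its test fold (no leakage through scaling).
    """
    Xv, yv, _, _ = _as_xy(X, y)
    counts = np.bincount(yv.astype(int))
    if counts.min() < n_folds:
        n_folds = max(2, int(counts.min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    press = 0.0
    for train_idx, test_idx in skf.split(Xv, yv):
        ytr = yv[train_idx]
        if len(np.unique(ytr)) < 2:  # pragma: no cover - stratification guarantees this
            raise ValueError("a training fold lost a class; use fewer folds")
        if scale:
            xtr, xte = _fold_scale(Xv[train_idx], Xv[test_idx])
        else:
            xtr, xte = Xv[train_idx], Xv[test_idx]
        ncomp = min(n_components, len(train_idx) - 1, xtr.shape[1])
        if kind == "oplsda":
            model = fit_oplsda(xtr, ytr, n_orthogonal=max(0, ncomp - 1))
        else:
            model = fit_plsda(xtr, ytr, n_components=ncomp)
        yhat = predict(model, xte)
        press += float(np.sum((yv[test_idx] - yhat) ** 2))
    y0 = yv - yv.mean()
    return 1.0 - press / float(y0 @ y0)


@dataclass
class PermutationResult:
    """Label-permutation validation of R2Y and Q2Y."""

    n_permutations: int
    observed_r2y: float
    observed_q2y: float
    permuted_r2y: np.ndarray
    permuted_q2y: np.ndarray
    p_r2y: float
    p_q2y: float


def permutation_test(
    X,
    y,
    n_components: int = 2,
    n_permutations: int = 200,
    seed: int = 0,
    n_folds: int = 7,
    scale: bool = True,
) -> PermutationResult:
    """Permute class labels and recompute R2Y / Q2Y.

    p = (1 + #{permuted >= observed}) / (n_permutations + 1), so p is
    never zero; cross-validation folds are re-drawn per permutation.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    Xv, yv, _, _ = _as_xy(X, y)
    rng = np.random.default_rng(seed)

    def _scaled(mat: np.ndarray) -> np.ndarray:
        if not scale:
            return mat
        sds = mat.std(axis=0, ddof=1)
        sds = np.where(sds <= 0, 1.0, sds)
        return (mat - mat.mean(axis=0)) / sds

    Xs = _scaled(Xv)
    obs_r2 = fit_plsda(Xs, yv, n_components).r2y
    obs_q2 = cross_validate_q2(
        Xv, yv, n_components, n_folds, seed=int(rng.integers(2**31)), scale=scale
    )
    perm_r2 = np.empty(n_permutations)
    perm_q2 = np.empty(n_permutations)
    for b in range(n_permutations):
        yp = rng.permutation(yv)
        perm_r2[b] = fit_plsda(Xs, yp, n_components).r2y
        perm_q2[b] = cross_validate_q2(
            Xv, yp, n_components, n_folds, seed=int(rng.integers(2**31)), scale=scale
        )
    p_r2 = (1.0 + np.sum(perm_r2 >= obs_r2)) / (n_permutations + 1.0)
    p_q2 = (1.0 + np.sum(perm_q2 >= obs_q2)) / (n_permutations + 1.0)
    return PermutationResult(
        n_permutations=n_permutations,
        observed_r2y=obs_r2,
        observed_q2y=obs_q2,
        permuted_r2y=perm_r2,
        permuted_q2y=perm_q2,
        p_r2y=float(p_r2),
        p_q2y=float(p_q2),
    )


def vip_scores(model: LatentModel) -> pd.Series:
    """Variable importance in projection over the predictive components.

    VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ) with
    SSY_a = c_a^2 t_a't_a and unit-norm w_a; the squared scores average
    to 1 over features by construction.
    """
    if model.weights.size == 0:
        raise ValueError("model is not fitted")
    p = model.weights.shape[0]
    ssy = model.y_loadings**2 * np.einsum("na,na->a", model.scores, model.scores)
    if ssy.sum() <= 0:
        raise ValueError("model explains no response variance; VIP undefined")
    vip = np.sqrt(p * (model.weights**2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=model.feature_names, name="vip")


def vip_table(
    model: LatentModel,
    threshold: float | None = None,
    k_sd: float = 2.0,
) -> tuple[pd.DataFrame, float]:
    """VIP scores plus a selection threshold (normality-plot unless manual)."""
    vip = vip_scores(model)
    thr = float(threshold) if threshold is not None else normality_threshold(vip.to_numpy(), k_sd=k_sd)
    out = pd.DataFrame({"vip": vip})
    out["selected"] = out["vip"] >= thr
    return out.sort_values("vip", ascending=False), thr


def normality_threshold(
    scores,
    k_sd: float = 2.0,
    min_tail: int = 1,
    central_frac: float = 0.5,
) -> float:
    """Threshold where scores start to deviate upward from normality.

    Operationalizes the visual "normality plot" selection: scores are
    placed on a normal QQ plot (Blom plotting positions), a reference
    line is least-squares fitted through the central ``central_frac`` of
    points, and the largest score is compared against a pointwise band
    of half-width ``k_sd * max(s_robust, sigma_i)``, where ``s_robust``
    is the scaled MAD of the central residuals and ``sigma_i`` is the
    asymptotic sd of the top normal order statistic under the fitted
    line (the band a QQ-plot envelope draws).  A score outside the band
    is peeled off and the plot is recomputed without it — peeling stops
    at the first score inside its band, so already-removed outliers
    cannot displace the plotting positions of the remaining bulk.  The
    threshold is the smallest peeled score; ``+inf`` (nothing selected)
    if the largest score already sits inside its band.
    """
    s = np.sort(np.asarray(scores, dtype=float))
    n = s.size
    if n < 10:
        raise ValueError("need at least 10 values; choose a manual threshold instead")
    if np.isnan(s).any():
        raise ValueError("scores contain NaN")
    if (s < 0).any():
        raise ValueError("scores must be non-negative")

    removed: list[float] = []
    work = s.copy()
    while work.size >= 10:
        m = work.size
        pos = (np.arange(1, m + 1) - 0.375) / (m + 0.25)  # Blom plotting positions
        q = stats.norm.ppf(pos)
        lo = int(np.floor(m * (0.5 - central_frac / 2)))
        hi = int(np.ceil(m * (0.5 + central_frac / 2)))
        slope, intercept = np.polyfit(q[lo:hi], work[lo:hi], 1)
        resid = work - (slope * q + intercept)
        central = resid[lo:hi]
        s_robust = 1.4826 * float(np.median(np.abs(central - np.median(central))))
        sigma_top = abs(slope) * np.sqrt(pos[-1] * (1 - pos[-1]) / m) / stats.norm.pdf(q[-1])
        band = k_sd * max(s_robust, sigma_top)
        if resid[-1] > band:
            removed.append(float(work[-1]))
            work = work[:-1]
        else:
            break
    if len(removed) < max(1, min_tail):
        return float("inf")
    return float(min(removed))
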
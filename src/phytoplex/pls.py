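"""NIPALS PLS1 regression with VIP-based variable selection.

Projection-to-latent-structures regression for a single response: successive
components maximize the covariance between X scores and y.  For one response
the NIPALS weight vector per component is closed-form (w ∝ Xᵀy on the
deflated matrix), so no inner iteration is needed.  On top of the fitter sit

* VIP — variable influence on projection, normalized so mean VIP² = 1;
* Q²/SDECV — seven-fold full cross-validation with fold-internal centering;
* VIP-threshold selection maximizing Q² over the threshold grid;
* a response permutation test against over-fitting;
* model post-transformation isolating a single predictive component;
* PCA for exploratory cluster structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, ParameterError, StateError

__all__ = [
    "PLSModel",
    "SelectionResult",
    "fit_pls1",
    "vip_scores",
    "q2_sdecv",
    "choose_components",
    "select_by_vip",
    "permutation_test",
    "post_transform",
    "pca",
]

MAX_COMPONENTS_DEFAULT = 5


@dataclass
class PLSModel:
    """Fitted PLS1 model.

    W, P are variables × A weight and loading matrices, q the y-loadings,
    T the samples × A scores, b the regression coefficients on the original
    (uncentered) variable scale.  ``vip`` satisfies mean(vip²) = 1.
    ``q2``/``sdecv`` are filled by cross-validation, ``tp`` by
    :func:`post_transform`.
    """

    n_components: int
    variables: list[str]
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    b: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    r2: float
    vip: np.ndarray
    q2: float | None = None
    sdecv: float | None = None
    tp: np.ndarray | None = None
    cv_seed: int | None = None

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xa = np.asarray(X, dtype=float)
        return (Xa - self.x_mean) @ self.b + self.y_mean

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "variables": self.variables,
            "b": self.b.tolist(),
            "vip": self.vip.tolist(),
            "r2": self.r2,
            "q2": self.q2,
            "sdecv": self.sdecv,
            "cv_seed": self.cv_seed,
        }


def _as_arrays(X, y) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j+1}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float).ravel()
    if Xa.shape[0] != ya.shape[0]:
        raise ParameterError("X and y disagree on the number of samples")
    return Xa, ya, names


def _nipals_components(
    Xc: np.ndarray, yc: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """NIPALS PLS1 decomposition of centered data.

    Stops early (returning the number of components actually extracted) when
    the deflated X retains no covariance with y — the rank-deficient case.
    """
    n, p = Xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    Xd = Xc.copy()
    scale = max(1.0, float(np.abs(Xc).max(initial=0.0)) * float(np.abs(yc).max(initial=0.0)))
    for a in range(n_components):
        w = Xd.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-12 * scale:
            return W[:, :a], P[:, :a], q[:a], T[:, :a], a
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-300:
            return W[:, :a], P[:, :a], q[:a], T[:, :a], a
        pa = Xd.T @ t / tt
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, float(yc @ t) / tt, t
        Xd -= np.outer(t, pa)
    return W, P, q, T, n_components


def _coef_path(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> list[np.ndarray]:
    """Regression coefficients for every truncation 1..A of a component set."""
    return [
        W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
        for a in range(1, W.shape[1] + 1)
    ]


def fit_pls1(X, y, n_components: int) -> PLSModel:
    """Fit a PLS1 model with the requested number of latent components.

    Centering is applied internally (means are stored on the model).  Per
    component a: w_a ∝ X_aᵀy (unit norm), t_a = X_a w_a,
    p_a = X_aᵀt_a/(t_aᵀt_a), q_a = yᵀt_a/(t_aᵀt_a), then X is deflated by
    t_a p_aᵀ.  Coefficients b = W (PᵀW)⁻¹ q.
    """
    Xa, ya, names = _as_arrays(X, y)
    n, p = Xa.shape
    if np.ptp(ya) == 0:
        raise DegenerateDesignError("response has zero variance")
    if n_components < 1:
        raise ParameterError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise ParameterError(
            f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}"
        )
    x_mean = Xa.mean(axis=0)
    y_mean = float(ya.mean())
    Xc = Xa - x_mean
    yc = ya - y_mean
    W, P, q, T, a_used = _nipals_components(Xc, yc, n_components)
    if a_used < n_components:
        warnings.warn(
            f"PLS1 stopped after {a_used} of {n_components} components: "
            "deflated X orthogonal to y",
            stacklevel=2,
        )
        if a_used == 0:
            # y carries no covariance with X at all: the zero-coefficient model
            model = PLSModel(
                n_components=0, variables=names,
                W=W[:, :0], P=P[:, :0], q=q[:0], T=T[:, :0],
                b=np.zeros(p), x_mean=x_mean, y_mean=y_mean,
                r2=0.0, vip=np.ones(p),
            )
            return model
        W, P, q, T = W[:, :a_used], P[:, :a_used], q[:a_used], T[:, :a_used]

    b = W @ np.linalg.solve(P.T @ W, q)
    resid = yc - Xc @ b
    ss_tot = float(yc @ yc)
    r2 = 1.0 - float(resid @ resid) / ss_tot
    model = PLSModel(
        n_components=W.shape[1], variables=names,
        W=W, P=P, q=q, T=T, b=b, x_mean=x_mean, y_mean=y_mean,
        r2=r2, vip=np.ones(p),
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable influence on projection.

    vip_j = sqrt( p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a ) with
    SSY_a = q_a² t_aᵀt_a, the y-variance captured by component a.  The
    normalization makes mean(vip²) = 1, so VIP ≈ 1 marks an averagely
    influential variable.
    """
    if model.n_components < 1:
        raise StateError("VIP requires a model with at least one component")
    p = model.W.shape[0]
    ssy = model.q**2 * np.einsum("ia,ia->a", model.T, model.T)
    wnorm2 = (model.W**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    frac = (model.W**2) / wnorm2
    return np.sqrt(p * (frac @ ssy) / ssy.sum())


def _fold_assignments(
    n: int, folds: int, rng: np.random.Generator, groups=None
) -> np.ndarray:
    """Random fold labels; with group labels, members of each group are spread
    round-robin across folds (stratification by cultivar)."""
    if groups is None:
        return rng.permutation(np.arange(n) % folds)
    groups = np.asarray(groups)
    order = rng.permutation(n)
    ordered = order[np.argsort(groups[order], kind="stable")]
    fold = np.empty(n, dtype=int)
    fold[ordered] = np.arange(n) % folds
    return fold


def q2_sdecv(
    X, y, n_components: int, folds: int = 7, seed: int = 0, groups=None
) -> tuple[float, float]:
    """Cross-validated Q² and SDECV.

    Q² = 1 − PRESS/TSS where PRESS sums squared errors of held-out samples
    predicted by models trained on the remaining folds, and TSS is taken
    about the training-fold means (centering is re-estimated inside each
    training fold, so no information leaks).  SDECV = sqrt(PRESS/n), in
    response units.
    """
    q2, sdecv = _cv_path(X, y, n_components, folds, seed, groups)
    return float(q2[-1]), float(sdecv[-1])


def _cv_path(
    X, y, max_a: int, folds: int, seed: int, groups=None
) -> tuple[np.ndarray, np.ndarray]:
    """Q² and SDECV for every component count 1..max_a in one CV pass.

    PLS1 components are nested, so each training fold is decomposed once at
    the largest count and truncated coefficient vectors predict the held-out
    fold for every smaller count.  A fold whose training set cannot support
    ``max_a`` components contributes its deepest available model to the
    larger counts.
    """
    Xa, ya, _ = _as_arrays(X, y)
    n = Xa.shape[0]
    if folds > n:
        raise ParameterError(f"folds={folds} exceeds n={n}")
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    if max_a < 1:
        raise ParameterError("component count must be >= 1")
    rng = np.random.default_rng(seed)
    fold = _fold_assignments(n, folds, rng, groups)
    press = np.zeros(max_a)
    tss = 0.0
    for k in range(folds):
        test = fold == k
        if not test.any():
            continue
        train = ~test
        n_tr = int(train.sum())
        if n_tr < 2:
            raise ParameterError("training fold too small for one component")
        Xtr, ytr = Xa[train], ya[train]
        xm = Xtr.mean(axis=0)
        ym = ytr.mean()
        a_k = min(max_a, n_tr - 1, Xa.shape[1])
        W, P, q, _, a_used = _nipals_components(Xtr - xm, ytr - ym, a_k)
        if a_used < 1:
            # no X–y covariance in this fold: the mean is the prediction
            preds = [np.full(int(test.sum()), ym)] * max_a
        else:
            bs = _coef_path(W, P, q)
            Xte_c = Xa[test] - xm
            preds = [Xte_c @ bs[min(a, a_used) - 1] + ym for a in range(1, max_a + 1)]
        for a in range(max_a):
            press[a] += float(((ya[test] - preds[a]) ** 2).sum())
        tss += float(((ya[test] - ym) ** 2).sum())
    return 1.0 - press / tss, np.sqrt(press / n)


def choose_components(
    X, y, folds: int = 7, seed: int = 0, max_a: int = MAX_COMPONENTS_DEFAULT,
    groups=None,
) -> tuple[int, float, float]:
    """Pick the component count maximizing Q² over A = 1..min(max_a, n−1, p)."""
    Xa, ya, _ = _as_arrays(X, y)
    hi = max(min(max_a, Xa.shape[0] - 1, Xa.shape[1]), 1)
    q2, sdecv = _cv_path(Xa, ya, hi, folds, seed, groups)
    best = int(np.argmax(q2 > q2.max() - 1e-12))  # smallest A attaining the max
    return best + 1, float(q2[best]), float(sdecv[best])


@dataclass
class SelectionResult:
    """Outcome of VIP-threshold selection.

    ``selected`` are the variables of the parent model with VIP above
    ``threshold``; ``model`` is the refit on that subset; ``q2_path`` records
    (threshold, q2, n_selected) along the grid.
    """

    threshold: float
    selected: list[str]
    model: PLSModel
    q2_path: list[tuple[float, float, int]] = field(default_factory=list)
    permutation_p: float | None = None
    full_model: PLSModel | None = None
    fallback: bool = False


def select_by_vip(
    X, y, folds: int = 7, seed: int = 0,
    max_a: int = MAX_COMPONENTS_DEFAULT, n_components: int | None = None,
    groups=None,
) -> SelectionResult:
    """VIP-threshold variable selection maximizing cross-validated Q².

    A full model (component count chosen by Q² unless ``n_components`` is
    given) provides the VIP vector; candidate thresholds are 0 plus the
    sorted unique VIPs.  For each threshold the model is refit on the
    variables with VIP strictly above it — re-choosing the component count —
    and the threshold with the best Q² wins, ties broken toward the sparser
    model.  If every candidate is degenerate the full model is returned with
    ``fallback=True``.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    Xa, ya, names = _as_arrays(Xdf, y)
    Xdf = Xdf.set_axis(names, axis=1)
    if Xa.shape[1] < 2:
        raise ParameterError("selection needs at least 2 variables")
    if n_components is None:
        a_full, _, _ = choose_components(Xa, ya, folds=folds, seed=seed,
                                         max_a=max_a, groups=groups)
    else:
        a_full = n_components
    full = fit_pls1(Xa, ya, a_full)
    vip = full.vip
    thresholds = np.concatenate(([0.0], np.unique(vip)))
    path: list[tuple[float, float, int]] = []
    best = None  # (q2, threshold, mask, a, sdecv)
    # descending thresholds: the sparsest model is seen first and kept on ties
    for thr in sorted(thresholds, reverse=True):
        mask = vip > thr
        k = int(mask.sum())
        if k == 0:
            continue
        Xsub = Xa[:, mask]
        try:
            a_sub, q2, sdecv = choose_components(
                Xsub, ya, folds=folds, seed=seed, max_a=max_a, groups=groups
            )
        except (ParameterError, DegenerateDesignError):
            continue
        path.append((float(thr), float(q2), k))
        if best is None or q2 > best[0] + 1e-12:
            best = (q2, float(thr), mask, a_sub, sdecv)
    if best is None:
        warnings.warn("all VIP thresholds degenerate; returning full model",
                      stacklevel=2)
        full.q2, full.sdecv = q2_sdecv(Xa, ya, a_full, folds=folds, seed=seed,
                                       groups=groups)
        return SelectionResult(
            threshold=0.0, selected=list(names), model=full,
            q2_path=path, full_model=full, fallback=True,
        )
    q2, thr, mask, a_sub, sdecv = best
    sel_names = [nm for nm, m in zip(names, mask) if m]
    refit = fit_pls1(Xdf.loc[:, sel_names] if isinstance(X, pd.DataFrame) else Xa[:, mask],
                     ya, a_sub)
    refit.q2, refit.sdecv, refit.cv_seed = q2, sdecv, seed
    return SelectionResult(
        threshold=thr, selected=sel_names, model=refit,
        q2_path=sorted(path), full_model=full,
    )


def permutation_test(
    X, y, n_perm: int = 1000, folds: int = 7, seed: int = 0,
    n_components: int | None = None, groups=None,
) -> float:
    """Response permutation test on cross-validated Q².

    The observed Q² (at the chosen component count) is compared with Q²
    values obtained after randomly permuting y; the p-value uses the +1
    correction, p = (1 + #{Q²_perm ≥ Q²_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    Xa, ya, _ = _as_arrays(X, y)
    if n_components is None:
        n_components, q2_obs, _ = choose_components(
            Xa, ya, folds=folds, seed=seed, groups=groups
        )
    else:
        q2_obs, _ = q2_sdecv(Xa, ya, n_components, folds=folds, seed=seed,
                             groups=groups)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xBEEF)))
    count = 0
    for _ in range(n_perm):
        yp = rng.permutation(ya)
        if np.ptp(yp) == 0:
            count += 1
            continue
        q2p, _ = q2_sdecv(Xa, yp, n_components, folds=folds, seed=seed,
                          groups=groups)
        if q2p >= q2_obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def post_transform(model: PLSModel) -> PLSModel:
    """Rotate the score space so a single component is predictive of y.

    The predictive score is t_p = X_c b/‖b‖ — the projection of centered X
    onto the coefficient direction, hence perfectly correlated with the
    fitted values.  Remaining score directions are orthogonalized against
    t_p (they carry no y-predictive variation).  Coefficients, and therefore
    predictions, are untouched.
    """
    bnorm = np.linalg.norm(model.b)
    if bnorm == 0:
        raise DegenerateDesignError("zero coefficient vector: nothing to rotate")
    # NIPALS identity T = Xc W(PᵀW)⁻¹ gives Xc b = T q exactly, so the
    # predictive score is available from the stored training scores.
    tp = (model.T @ model.q) / bnorm
    T_ortho = np.empty((model.T.shape[0], 0))
    denom = float(tp @ tp)
    if denom > 0:
        resid = model.T - np.outer(tp, (tp @ model.T) / denom)
        keep = [a for a in range(resid.shape[1])
                if np.linalg.norm(resid[:, a]) > 1e-10 * max(1.0, np.linalg.norm(model.T[:, a]))]
        T_ortho = resid[:, keep]
    out = PLSModel(
        n_components=model.n_components, variables=model.variables,
        W=model.W, P=model.P, q=model.q, T=model.T, b=model.b,
        x_mean=model.x_mean, y_mean=model.y_mean, r2=model.r2,
        vip=model.vip, q2=model.q2, sdecv=model.sdecv, cv_seed=model.cv_seed,
    )
    out.tp = tp
    out.T_orthogonal = T_ortho  # type: ignore[attr-defined]
    return out


def pca(
    X, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal component analysis by SVD of the centered matrix.

    Returns (scores, loadings, explained variance fractions); fractions are
    non-increasing and sum to at most 1.  Requests beyond the matrix rank
    are truncated with a warning.
    """
    Xa = np.asarray(X, dtype=float)
    Xc = Xa - Xa.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = S.max(initial=0.0) * max(Xc.shape) * np.finfo(float).eps
    rank = int((S > tol).sum())
    if n_components is None:
        n_components = rank
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    total = float((S**2).sum())
    k = n_components
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    explained = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    return scores, loadings, explained
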
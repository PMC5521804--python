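"""Monte-Carlo stability selection around VIP-based PLS and simple linear
regression.

Each of ``n_subsamples`` Monte-Carlo draws includes every sample
independently with probability ``inclusion_prob`` (0.70 by default — the
"prior probability" of inclusion).  VIP-based PLS selection runs on the
included samples; its selected variable set is recorded, and the refit model
predicts the excluded samples to give a standard deviation error in
prediction, SDEP = sqrt(Σ(ŷ−y)²/n_excluded).  Variables selected in more
than half of the models form the relevant set.  A per-subsample permutation
gate discards selections whose model fails a response permutation test
(p > 0.05), guarding against over-fitting.

The simple-linear-regression analogue regresses y on each variable alone per
subsample, recording r², the slope-test p-value and the out-of-subsample
SDEP; "selected" within a subsample means slope p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ParameterError
from .pls import MAX_COMPONENTS_DEFAULT, fit_pls1, select_by_vip, permutation_test

__all__ = [
    "StabilityResult",
    "SLRStabilityResult",
    "stability_select_pls",
    "stability_select_slr",
]


@dataclass
class StabilityResult:
    """Aggregated outcome of Monte-Carlo stability selection."""

    n_subsamples: int
    inclusion_prob: float
    freq_threshold: float
    variables: list[str]
    frequency: pd.Series
    relevant: list[str]
    mean_sdep: float
    per_model_sdep: list[float]
    mean_vip: pd.Series
    seed: int
    no_holdout: bool = False

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variables,
                "frequency": self.frequency.reindex(self.variables).to_numpy(),
                "mean_vip": self.mean_vip.reindex(self.variables).to_numpy(),
                "relevant": [v in set(self.relevant) for v in self.variables],
            }
        )


@dataclass
class SLRStabilityResult:
    """Per-variable univariate regression summaries over subsamples."""

    n_subsamples: int
    inclusion_prob: float
    variables: list[str]
    mean_r2: pd.Series
    mean_sdep: pd.Series
    mean_p: pd.Series
    frequency: pd.Series
    relevant: list[str]
    excluded_variables: list[str] = field(default_factory=list)
    seed: int = 0


def _draw_subsample(
    rng: np.random.Generator, n: int, inclusion_prob: float, min_train: int
) -> np.ndarray:
    for _ in range(100):
        mask = rng.random(n) < inclusion_prob
        if mask.sum() >= min_train:
            return mask
    raise ConfigurationError(
        f"could not draw a subsample with >= {min_train} samples at "
        f"inclusion probability {inclusion_prob} in 100 attempts"
    )


def stability_select_pls(
    X, y,
    n_subsamples: int = 1000,
    inclusion_prob: float = 0.70,
    freq_threshold: float = 0.5,
    seed: int = 0,
    folds: int = 7,
    max_a: int = MAX_COMPONENTS_DEFAULT,
    gate_n_perm: int = 19,
    gate_alpha: float = 0.05,
    groups=None,
) -> StabilityResult:
    """Monte-Carlo stability selection with VIP-based PLS.

    Per subsample: draw an inclusion mask (redrawn until the training set can
    support a model), run :func:`select_by_vip`, apply the permutation gate
    (``gate_n_perm`` response permutations; failure empties the selection),
    and score SDEP on the excluded samples with the selected-variable refit.
    Frequencies aggregate over all subsamples; the relevant set is the
    variables with frequency strictly above ``freq_threshold``.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    ya = np.asarray(y, dtype=float).ravel()
    n, p = Xdf.shape
    if n < 10:
        raise ParameterError("stability selection needs >= 10 samples")
    if not (0 < inclusion_prob <= 1):
        raise ParameterError("inclusion_prob must be in (0, 1]")
    names = [str(c) for c in Xdf.columns]
    Xa = Xdf.to_numpy(dtype=float)
    min_train = max(folds, max_a + 2)
    master = np.random.default_rng(np.random.SeedSequence((seed, 0x57AB)))
    counts = np.zeros(p)
    vip_sum = np.zeros(p)
    vip_n = 0
    per_model_sdep: list[float] = []
    groups_arr = None if groups is None else np.asarray(groups)

    for i in range(n_subsamples):
        sub_seed = int(master.integers(2**31))
        rng = np.random.default_rng(sub_seed)
        if inclusion_prob == 1.0:
            mask = np.ones(n, dtype=bool)
        else:
            mask = _draw_subsample(rng, n, inclusion_prob, min_train)
        Xtr, ytr = Xa[mask], ya[mask]
        gtr = None if groups_arr is None else groups_arr[mask]
        sel = select_by_vip(
            pd.DataFrame(Xtr, columns=names), ytr,
            folds=folds, seed=sub_seed, max_a=max_a, groups=gtr,
        )
        if gate_n_perm > 0:
            p_gate = permutation_test(
                Xtr, ytr, n_perm=gate_n_perm, folds=folds, seed=sub_seed,
                n_components=sel.full_model.n_components if sel.full_model else None,
                groups=gtr,
            )
            if p_gate > gate_alpha:
                continue  # over-fit model contributes an empty selection
        sel_idx = [names.index(v) for v in sel.selected]
        counts[sel_idx] += 1
        if sel.full_model is not None:
            vip_sum += sel.full_model.vip
            vip_n += 1
        excluded = ~mask
        if excluded.any():
            pred = sel.model.predict(Xa[np.ix_(excluded, sel_idx)])
            sdep = float(np.sqrt(((ya[excluded] - pred) ** 2).mean()))
            per_model_sdep.append(sdep)

    frequency = pd.Series(counts / n_subsamples, index=names, name="frequency")
    relevant = [v for v in names if frequency[v] > freq_threshold]
    mean_vip = pd.Series(
        vip_sum / vip_n if vip_n else np.full(p, np.nan), index=names, name="mean_vip"
    )
    return StabilityResult(
        n_subsamples=n_subsamples,
        inclusion_prob=inclusion_prob,
        freq_threshold=freq_threshold,
        variables=names,
        frequency=frequency,
        relevant=relevant,
        mean_sdep=float(np.mean(per_model_sdep)) if per_model_sdep else float("nan"),
        per_model_sdep=per_model_sdep,
        mean_vip=mean_vip,
        seed=seed,
        no_holdout=not per_model_sdep,
    )


def _univariate_stats(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, yte: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-variable simple linear regression.

    Returns (r2, p, sdep, constant_mask); textbook slope t-test with n−2
    degrees of freedom.  Variables constant within the training subsample
    come back masked.
    """
    n = Xtr.shape[0]
    xm = Xtr.mean(axis=0)
    ym = ytr.mean()
    Xc = Xtr - xm
    yc = ytr - ym
    sxx = (Xc**2).sum(axis=0)
    syy = float((yc**2).sum())
    const = sxx <= 0
    sxx_safe = np.where(const, 1.0, sxx)
    sxy = Xc.T @ yc
    slope = sxy / sxx_safe
    r2 = np.where(const | (syy == 0), 0.0, sxy**2 / (sxx_safe * syy))
    r2 = np.clip(r2, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = r2 * (n - 2) / np.maximum(1.0 - r2, 0.0)
        tstat = np.sqrt(np.where(t2 < 0, 0.0, t2))
    pval = 2.0 * stats.t.sf(tstat, df=n - 2)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    pval = np.where(const, 1.0, pval)
    if Xte.shape[0]:
        pred = ym + (Xte - xm) * slope
        sdep = np.sqrt(((yte[:, None] - pred) ** 2).mean(axis=0))
    else:
        sdep = np.full(Xtr.shape[1], np.nan)
    return r2, pval, sdep, const


def stability_select_slr(
    X, y,
    n_subsamples: int = 1000,
    inclusion_prob: float = 0.70,
    freq_threshold: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> SLRStabilityResult:
    """Simple-linear-regression analogue of stability selection.

    Univariate OLS of y on each variable within every Monte-Carlo subsample;
    a variable counts as selected in a subsample when its slope test gives
    p < ``alpha``.  Variables constant across all samples are flagged and
    excluded from the result.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    ya = np.asarray(y, dtype=float).ravel()
    n, p = Xdf.shape
    if n < 10:
        raise ParameterError("stability selection needs >= 10 samples")
    if not (0 < inclusion_prob <= 1):
        raise ParameterError("inclusion_prob must be in (0, 1]")
    names = [str(c) for c in Xdf.columns]
    Xa = Xdf.to_numpy(dtype=float)
    globally_const = [names[j] for j in range(p) if np.ptp(Xa[:, j]) == 0]
    master = np.random.default_rng(np.random.SeedSequence((seed, 0x51A2)))
    r2_sum = np.zeros(p); p_sum = np.zeros(p); sdep_sum = np.zeros(p)
    sdep_n = np.zeros(p); sel_count = np.zeros(p); used = np.zeros(p)

    for i in range(n_subsamples):
        sub_seed = int(master.integers(2**31))
        rng = np.random.default_rng(sub_seed)
        if inclusion_prob == 1.0:
            mask = np.ones(n, dtype=bool)
        else:
            mask = _draw_subsample(rng, n, inclusion_prob, 4)
        r2, pv, sdep, const = _univariate_stats(
            Xa[mask], ya[mask], Xa[~mask], ya[~mask]
        )
        ok = ~const
        r2_sum[ok] += r2[ok]
        p_sum[ok] += pv[ok]
        used[ok] += 1
        sel_count[ok & (pv < alpha)] += 1
        good_sdep = ok & ~np.isnan(sdep)
        sdep_sum[good_sdep] += sdep[good_sdep]
        sdep_n[good_sdep] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = pd.Series(r2_sum / used, index=names)
        mean_p = pd.Series(p_sum / used, index=names)
        mean_sdep = pd.Series(sdep_sum / np.where(sdep_n > 0, sdep_n, np.nan),
                              index=names)
        frequency = pd.Series(sel_count / n_subsamples, index=names)
    keep = [v for v in names if v not in set(globally_const)]
    relevant = [v for v in keep if frequency[v] > freq_threshold]
    return SLRStabilityResult(
        n_subsamples=n_subsamples,
        inclusion_prob=inclusion_prob,
        variables=keep,
        mean_r2=mean_r2[keep],
        mean_sdep=mean_sdep[keep],
        mean_p=mean_p[keep],
        frequency=frequency[keep],
        relevant=relevant,
        excluded_variables=globally_const,
        seed=seed,
    )
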
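"""Cohort-level statistics: collinearity filtering and predictor ranking.

The geometric descriptors from Hip Structural Analysis (HSA) are strongly
inter-correlated, so the ranking pipeline first removes collinear variables
by iterative Variance Inflation Factor (VIF) pruning, then fits every
non-empty subset of the retained predictors as an ordinary least-squares
model of the patient risk score and ranks variables by their cumulative
Akaike weight: the summed model weights w_i = exp(-Delta_i/2)/sum(...) over
all models containing the variable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm


@dataclass
class VIFResult:
    retained: list[str]
    vif: dict[str, float]                 # final VIFs of retained variables
    removed: list[tuple[str, float]]      # (name, VIF at removal) in order


def _vif_one(x: pd.DataFrame, col: str) -> float:
    """VIF of one column: 1 / (1 - R^2) regressing it on the other columns."""
    others = x.drop(columns=[col])
    model = sm.OLS(x[col].to_numpy(), sm.add_constant(others.to_numpy()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r2 = model.fit().rsquared
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return float(1.0 / (1.0 - r2))


def vif_filter(x: pd.DataFrame, threshold: float = 10.0) -> VIFResult:
    """Iteratively drop the highest-VIF variable until all VIFs <= threshold.

    Perfectly collinear columns (infinite VIF) are removed first, with a
    warning.  Ties break alphabetically so the result does not depend on the
    column order of the input.
    """
    current = sorted(x.columns)
    removed: list[tuple[str, float]] = []
    while len(current) > 1:
        vifs = {c: _vif_one(x[current], c) for c in current}
        worst = max(sorted(vifs), key=lambda c: vifs[c])
        if not np.isfinite(vifs[worst]):
            warnings.warn(f"perfectly collinear variable {worst!r} removed")
        elif vifs[worst] <= threshold:
            break
        removed.append((worst, vifs[worst]))
        current = [c for c in current if c != worst]
    final = {c: (_vif_one(x[current], c) if len(current) > 1 else 1.0) for c in current}
    return VIFResult(retained=current, vif=final, removed=removed)


@dataclass
class AICRanking:
    cumulative_weights: pd.Series        # per variable, sorted descending
    models: pd.DataFrame                 # subset, k, rss, aic, delta, weight
    best_model: tuple[str, ...]


def _ols_rss(xmat: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of an intercept-included least-squares fit."""
    coef, _, _, _ = np.linalg.lstsq(xmat, y, rcond=None)
    resid = y - xmat @ coef
    return float(resid @ resid)


def aic_rank(
    x: pd.DataFrame,
    y: pd.Series | np.ndarray,
    use_aicc: bool = False,
    max_exhaustive_p: int = 15,
) -> AICRanking:
    """Exhaustive-subset AIC ranking of predictors of ``y``.

    Every non-empty subset of the columns of ``x`` is fitted by OLS (with an
    intercept; predictors standardized beforehand, which does not affect the
    ranking but improves conditioning).  The Gaussian-likelihood criterion
    AIC = n ln(RSS/n) + 2 (k + 1) is used, with k = predictors + intercept
    and the extra 1 for the error variance; AICc adds the small-sample
    correction 2 K (K + 1) / (n - K - 1) with K = k + 1.
    """
    names = list(x.columns)
    p = len(names)
    if p > max_exhaustive_p:
        raise ValueError(
            f"{p} predictors: exhaustive enumeration over 2^p models is "
            f"capped at p = {max_exhaustive_p}; pre-filter (e.g. vif_filter)"
        )
    y = np.asarray(y, dtype=float)
    n = len(y)
    xs = (x - x.mean()) / x.std(ddof=1)
    xmat_full = xs.to_numpy()

    rows = []
    for r in range(1, p + 1):
        for subset in itertools.combinations(range(p), r):
            xmat = np.column_stack(
                [np.ones(n), xmat_full[:, list(subset)]]
            )
            rss = _ols_rss(xmat, y)
            k = r + 1                      # predictors + intercept
            aic = n * np.log(rss / n) + 2.0 * (k + 1)
            if use_aicc:
                big_k = k + 1
                if n - big_k - 1 <= 0:
                    raise ValueError("AICc undefined: n too small for this model")
                aic += 2.0 * big_k * (big_k + 1) / (n - big_k - 1)
            rows.append((subset, k, rss, aic))

    models = pd.DataFrame(rows, columns=["subset", "k", "rss", "aic"])
    models["delta"] = models["aic"] - models["aic"].min()
    w = np.exp(-models["delta"] / 2.0)
    models["weight"] = w / w.sum()

    cumulative = {}
    for j, name in enumerate(names):
        contains = models["subset"].map(lambda s, j=j: j in s)
        cumulative[name] = float(models.loc[contains, "weight"].sum())
    cum = pd.Series(cumulative).sort_values(ascending=False, kind="stable")
    best = models.loc[models["aic"].idxmin(), "subset"]
    models["subset"] = models["subset"].map(lambda s: tuple(names[j] for j in s))
    return AICRanking(
        cumulative_weights=cum,
        models=models,
        best_model=tuple(names[j] for j in best),
    )


def spearman_rho(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "t",
    rng: np.random.Generator | None = None,
    n_perm: int = 10000,
) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation or permutation p-value.

    Ties receive average ranks.  The permutation option is preferable for
    very small samples (n < 10) where the t approximation is crude.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rho, p_t = scipy.stats.spearmanr(x, y)
    if method == "t":
        return float(rho), float(p_t)
    if method != "permutation":
        raise ValueError(f"unknown p-value method {method!r}")
    rng = np.random.default_rng(0) if rng is None else rng
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ry)
        if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
            count += 1
    return float(rho), float((count + 1) / (n_perm + 1))
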
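"""Cell-cycle classification from replication-dependent histone content.

Canonical histone genes are non-polyadenylated and sharply upregulated during
S-phase, so in a total-RNA protocol the per-cell histone molecule count is
bimodal: a low mode (non-S cells, basal histone turnover) and a high mode
(S-phase cells replicating chromatin).  Cells are classified by a raw-count
threshold (default: more than 35 histone molecules = S-phase); a two-component
Weibull mixture fitted by EM describes the bimodality and can propose a
data-driven threshold at the equal-posterior crossing of the two modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import weibull_min

__all__ = [
    "HistoneScore",
    "WeibullMixtureFit",
    "histone_score",
    "fit_weibull_mixture",
    "call_s_phase",
    "suggest_threshold",
    "cycle_genes",
]


def histone_score(adata: ad.AnnData, histone_flags: pd.Series | None = None) -> pd.Series:
    """Total molecules over flagged histone features per cell (both layers)."""
    flags = histone_flags if histone_flags is not None else adata.var["histone"]
    mask = flags.to_numpy(dtype=bool)
    if "spliced" in adata.layers and "unspliced" in adata.layers:
        total = (
            np.asarray(adata.layers["spliced"][:, mask].sum(axis=1)).ravel()
            + np.asarray(adata.layers["unspliced"][:, mask].sum(axis=1)).ravel()
        )
    else:
        total = np.asarray(adata.X[:, mask].sum(axis=1)).ravel()
    return pd.Series(total.astype(np.int64), index=adata.obs_names, name="histone_score")


@dataclass
class WeibullMixtureFit:
    """Parameters of a (1- or 2-component) Weibull mixture, canonical order
    ascending scale."""

    weights: np.ndarray  # sums to 1
    shapes: np.ndarray  # k_j > 0
    scales: np.ndarray  # lambda_j > 0
    log_likelihood: float
    converged: bool
    n_iter: int

    @property
    def n_components(self) -> int:
        return len(self.weights)


def _weighted_weibull_mle(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted maximum-likelihood Weibull (shape, scale) via the profile
    equation for the shape parameter."""
    logx = np.log(x)
    wsum = w.sum()
    mean_logx = (w * logx).sum() / wsum

    def profile(k: float) -> float:
        xk = x**k
        return (w * xk * logx).sum() / (w * xk).sum() - 1.0 / k - mean_logx

    lo, hi = 1e-3, 1.0
    while profile(hi) < 0 and hi < 1e4:
        hi *= 2.0
    try:
        k = optimize.brentq(profile, lo, hi, xtol=1e-10)
    except ValueError:  # pathological weights; fall back to a moment guess
        k = 1.0
    lam = ((w * x**k).sum() / wsum) ** (1.0 / k)
    return float(k), float(lam)


def _mixture_loglik(x, weights, shapes, scales) -> float:
    dens = np.stack(
        [w * weibull_min.pdf(x, k, scale=lam) for w, k, lam in zip(weights, shapes, scales)]
    )
    return float(np.log(dens.sum(axis=0) + 1e-300).sum())


def fit_weibull_mixture(
    scores: np.ndarray | pd.Series,
    n_components: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    n_restarts: int = 5,
    zero_offset: float = 0.5,
) -> WeibullMixtureFit:
    """Fit a Weibull mixture to histone scores by EM.

    The Weibull density lives on (0, inf); zero scores are offset by
    ``zero_offset`` before fitting (the fit is diagnostic — classification
    uses the raw-count threshold).  EM uses weighted per-component Weibull
    ML updates; initialization is a median split with ``n_restarts`` jittered
    restarts, keeping the best likelihood.  The per-iteration log-likelihood
    is checked to be non-decreasing.  Components are reported in ascending
    scale order.
    """
    x = np.asarray(scores, dtype=float)
    if (x < 0).any():
        raise ValueError("scores must be non-negative")
    x = np.where(x == 0, zero_offset, x)
    if np.ptp(x) == 0:
        raise ValueError("all scores are equal: zero-variance input")
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if (x > 0).sum() < 50:
        raise ValueError("need at least 50 positive scores")

    if n_components == 1:
        w = np.ones_like(x)
        k, lam = _weighted_weibull_mle(x, w)
        ll = _mixture_loglik(x, np.array([1.0]), np.array([k]), np.array([lam]))
        return WeibullMixtureFit(
            np.array([1.0]), np.array([k]), np.array([lam]), ll, True, 0
        )

    rng = np.random.default_rng(seed)
    best: WeibullMixtureFit | None = None
    for restart in range(n_restarts):
        q = 0.5 if restart == 0 else float(np.clip(rng.normal(0.5, 0.12), 0.15, 0.85))
        split = np.quantile(x, q)
        resp = np.zeros((len(x), 2))
        resp[:, 0] = np.where(x <= split, 0.95, 0.05)
        resp[:, 1] = 1.0 - resp[:, 0]

        weights = resp.mean(axis=0)
        shapes = np.empty(2)
        scales = np.empty(2)
        for j in range(2):
            shapes[j], scales[j] = _weighted_weibull_mle(x, resp[:, j])

        prev_ll = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            dens = np.stack(
                [
                    weights[j] * weibull_min.pdf(x, shapes[j], scale=scales[j])
                    for j in range(2)
                ],
                axis=1,
            )
            total = dens.sum(axis=1, keepdims=True) + 1e-300
            ll = float(np.log(total).sum())
            # EM guarantee: the observed-data log-likelihood never decreases
            assert ll >= prev_ll - 1e-8 * max(1.0, abs(prev_ll)), (
                f"log-likelihood decreased at iteration {it}: {prev_ll} -> {ll}"
            )
            if ll - prev_ll < tol * max(1.0, abs(ll)):
                prev_ll = ll
                converged = True
                break
            prev_ll = ll
            resp = dens / total
            weights = resp.mean(axis=0)
            weights = np.clip(weights, 1e-8, None)
            weights /= weights.sum()
            for j in range(2):
                shapes[j], scales[j] = _weighted_weibull_mle(x, resp[:, j])

        order = np.argsort(scales)
        fit = WeibullMixtureFit(
            weights[order], shapes[order], scales[order], prev_ll, converged, it
        )
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


def call_s_phase(scores: pd.Series | np.ndarray, threshold: float = 35) -> pd.Series:
    """S-phase flag: histone score strictly above the threshold."""
    s = pd.Series(np.asarray(scores))
    if isinstance(scores, pd.Series):
        s.index = scores.index
    return (s > threshold).rename("s_phase")


def suggest_threshold(fit: WeibullMixtureFit) -> float:
    """Score minimizing misclassification between the two fitted modes.

    Solves the equal-posterior condition w1 f1(x) = w2 f2(x) between the two
    component scales.  Raises when the fit is not a separated 2-component
    mixture.
    """
    if fit.n_components != 2:
        raise ValueError("threshold suggestion needs a 2-component fit")
    (k1, k2), (l1, l2), (w1, w2) = fit.shapes, fit.scales, fit.weights
    if np.isclose(l1, l2, rtol=1e-3) and np.isclose(k1, k2, rtol=1e-3):
        raise ValueError("components are identical: no crossing exists")

    def diff(x: float) -> float:
        return w1 * weibull_min.pdf(x, k1, scale=l1) - w2 * weibull_min.pdf(
            x, k2, scale=l2
        )

    lo, hi = min(l1, l2), max(l1, l2)
    grid = np.linspace(lo, hi, 512)
    vals = np.array([diff(g) for g in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    if sign_change.size == 0:
        raise ValueError("no posterior crossing between the component scales")
    i = int(sign_change[-1])  # crossing closest to the high mode
    return float(optimize.brentq(diff, grid[i], grid[i + 1], xtol=1e-8))


def cycle_genes(
    adata: ad.AnnData,
    s_flags: pd.Series,
    log2fc_min: float = 1.0,
    p_max: float = 0.01,
    layer: str | None = None,
) -> pd.DataFrame:
    """Cell-cycle gene discovery: S vs non-S differential expression.

    Runs a per-gene two-sided Welch t-test on (normalized log) expression
    between S-phase and non-S cells, with the minimum-positive-mean
    pseudo-count log2 fold-change rule.  P values are reported uncorrected
    (with a BH-adjusted column alongside); genes passing both thresholds are
    flagged in the ``selected`` column.
    """
    from .label_transfer import de_genes

    flags = s_flags.reindex(adata.obs_names).to_numpy(dtype=bool)
    groups = (adata.obs_names[flags], adata.obs_names[~flags])
    if min(len(groups[0]), len(groups[1])) < 2:
        raise ValueError("both S and non-S groups need at least 2 cells")
    table = de_genes(adata, groups[0], groups[1], layer=layer)
    table["selected"] = (table["log2fc"].abs() >= log2fc_min) & (table["pval"] < p_max)
    return table
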
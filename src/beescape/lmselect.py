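"""All-subsets linear modelling with AICc ranking and shrinkage averaging.

Each bee metric is regressed on the four land-cover proportions (grassland,
forest, wind-pollinated crops, flowering annual crops).  All 2^4 = 16
subsets (including the intercept-only model) are fitted by ordinary least
squares, ranked by bias-corrected AICc, and combined by Akaike-weighted
model averaging with shrinkage: a coefficient is counted as zero in models
that exclude its variable.  AICc counts the error variance as a parameter
(k = p_regression + 1).

A distance-binned Moran's I correlogram with a permutation envelope checks
model residuals for spatial autocorrelation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PREDICTORS = ("grassland", "forest", "wind", "flowering_annual")


class ModelError(ValueError):
    pass


@dataclass
class OLSFit:
    predictors: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    rss: float
    n: int
    p: int          # regression parameters incl. intercept
    loglik: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        y = np.full(len(X), self.intercept)
        for name, beta in self.coefficients.items():
            y = y + beta * X[name].to_numpy(dtype=float)
        return y


def ols_fit(y: pd.Series | np.ndarray, X: pd.DataFrame,
            predictors: tuple[str, ...] | None = None) -> OLSFit:
    """Least-squares fit of y on an intercept plus the named predictor columns."""
    if predictors is None:
        predictors = tuple(X.columns)
    yv = np.asarray(y, dtype=float)
    n = yv.size
    mat = np.column_stack([np.ones(n)] + [X[c].to_numpy(dtype=float) for c in predictors])
    p = mat.shape[1]
    if n <= p:
        raise ModelError(f"need n > p ({n} observations, {p} parameters)")
    rank = np.linalg.matrix_rank(mat)
    if rank < p:
        # name the offending columns for the error message
        bad = []
        for j, name in enumerate(predictors, start=1):
            sub = np.delete(mat, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(name)
        raise ModelError(f"design matrix is rank deficient (collinear: {bad or predictors})")
    beta, _, _, _ = np.linalg.lstsq(mat, yv, rcond=None)
    resid = yv - mat @ beta
    rss = float(resid @ resid)
    loglik = -n / 2.0 * (np.log(2.0 * np.pi * max(rss, 1e-300) / n) + 1.0)
    return OLSFit(
        predictors=predictors,
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(predictors, beta[1:])},
        rss=rss, n=n, p=p, loglik=float(loglik),
    )


def aicc(fit: OLSFit) -> float:
    """Bias-corrected AIC with k = p + 1 (error variance counted)."""
    k = fit.p + 1
    if fit.n - k - 1 <= 0:
        raise ModelError(f"AICc undefined: n={fit.n} <= k+1={k + 1}")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (fit.n - k - 1.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """exp(-delta/2) normalized over the model set."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelSet:
    """All subset fits for one metric, sorted ascending by AICc."""

    metric: str
    fits: list[OLSFit]
    aicc: np.ndarray
    delta: np.ndarray
    weights: np.ndarray

    def table(self) -> pd.DataFrame:
        rows = []
        for fit, a, d, w in zip(self.fits, self.aicc, self.delta, self.weights):
            row = {"intercept": fit.intercept}
            for name in PREDICTORS:
                row[name] = fit.coefficients.get(name, np.nan)
            row |= {"aicc": a, "delta_aicc": d, "weight": w,
                    "subset": "+".join(fit.predictors) or "(intercept)"}
            rows.append(row)
        return pd.DataFrame(rows)


def enumerate_models(y: pd.Series | np.ndarray, X: pd.DataFrame,
                     metric: str = "metric",
                     predictors: tuple[str, ...] = PREDICTORS) -> ModelSet:
    """Fit every subset of the predictors (16 models for the default four).

    Ties in AICc are broken by fewer parameters, then by lexicographic
    subset identity, so output order is deterministic.
    """
    subsets = []
    for r in range(len(predictors) + 1):
        subsets.extend(itertools.combinations(predictors, r))
    fits, values = [], []
    for subset in subsets:
        try:
            fit = ols_fit(y, X, subset)
            values.append(aicc(fit))
        except ModelError as err:
            raise ModelError(f"subset {subset or '(intercept)'}: {err}") from err
        fits.append(fit)
    order = sorted(range(len(fits)),
                   key=lambda i: (values[i], fits[i].p, fits[i].predictors))
    fits = [fits[i] for i in order]
    a = np.array([values[i] for i in order])
    delta = a - a[0]
    return ModelSet(metric=metric, fits=fits, aicc=a, delta=delta,
                    weights=akaike_weights(a))


@dataclass
class AveragedModel:
    """Shrinkage model-averaged coefficients for one metric."""

    metric: str
    intercept: float
    coefficients: dict[str, float]
    variable_weights: dict[str, float] = field(default_factory=dict)
    pseudo_r2: float = float("nan")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        y = np.full(len(X), self.intercept)
        for name, beta in self.coefficients.items():
            y = y + beta * X[name].to_numpy(dtype=float)
        return y

    def predict_scalar(self, g: float, f: float, w: float, a: float) -> float:
        c = self.coefficients
        return (self.intercept + c.get("grassland", 0.0) * g + c.get("forest", 0.0) * f
                + c.get("wind", 0.0) * w + c.get("flowering_annual", 0.0) * a)


def average_coefficients(models: ModelSet, delta_cutoff: float | None = None) -> AveragedModel:
    """Akaike-weighted coefficient averages with shrinkage.

    A variable absent from a model contributes zero to its average; the
    variable weight is the summed Akaike weight of models containing it.
    With ``delta_cutoff`` set, averaging is restricted to models with
    delta AICc below the cutoff (weights renormalized).
    """
    keep = np.ones(len(models.fits), dtype=bool)
    if delta_cutoff is not None:
        keep = models.delta < delta_cutoff
    w = models.weights[keep]
    w = w / w.sum()
    fits = [f for f, k in zip(models.fits, keep) if k]
    intercept = float(sum(wi * f.intercept for wi, f in zip(w, fits)))
    coefs, varw = {}, {}
    for name in PREDICTORS:
        coefs[name] = float(sum(wi * f.coefficients.get(name, 0.0)
                                for wi, f in zip(w, fits)))
        varw[name] = float(sum(wi for wi, f in zip(w, fits) if name in f.predictors))
    return AveragedModel(metric=models.metric, intercept=intercept,
                         coefficients=coefs, variable_weights=varw)


def pseudo_r2(observed, predicted) -> float:
    """R^2 of regressing observed on model-averaged predictions.

    Equals the squared Pearson correlation; constant predictions are
    degenerate and return 0 with a warning.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if np.std(pred) == 0 or np.std(obs) == 0:
        import warnings
        warnings.warn("pseudo_r2: constant input; returning 0")
        return 0.0
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# residual spatial autocorrelation


@dataclass
class Correlogram:
    bin_centres: np.ndarray
    morans_i: np.ndarray
    n_pairs: np.ndarray
    envelope_low: np.ndarray | None
    envelope_high: np.ndarray | None
    significant: np.ndarray | None

    def any_significant(self) -> bool:
        return bool(self.significant is not None and np.any(self.significant))


def _binned_morans_i(z: np.ndarray, in_bin: list[np.ndarray]) -> np.ndarray:
    """Moran's I per distance bin for (possibly permuted) residual columns.

    z has shape (n, m) for m replicates; in_bin[b] is a boolean (n, n) weight
    matrix for bin b (zero diagonal).
    """
    denom = (z**2).sum(axis=0)
    n = z.shape[0]
    out = np.empty((len(in_bin), z.shape[1]))
    for b, w in enumerate(in_bin):
        s0 = w.sum()
        num = np.einsum("im,ij,jm->m", z, w, z)
        out[b] = (n / s0) * num / denom
    return out


def residual_correlogram(residuals, coords: np.ndarray, n_bins: int = 6,
                         n_perm: int = 199, seed: int = 0,
                         alpha: float = 0.05) -> Correlogram:
    """Distance-binned Moran's I of residuals with a permutation envelope.

    Bins partition (0, max pairwise distance] into ``n_bins`` equal widths;
    bins with fewer than 2 pairs are dropped with a warning.  With
    ``n_perm`` > 0, a (1 - alpha) two-sided envelope comes from random
    relabelings of the residuals; a bin is flagged significant when the
    observed statistic falls outside its envelope.
    """
    import warnings as _w
    z = np.asarray(residuals, dtype=float)
    z = z - z.mean()
    n = z.size
    coords = np.asarray(coords, dtype=float)
    dist = np.hypot(coords[:, None, 0] - coords[None, :, 0],
                    coords[:, None, 1] - coords[None, :, 1])
    edges = np.linspace(0.0, dist.max(), n_bins + 1)
    off_diag = ~np.eye(n, dtype=bool)
    in_bin, centres, n_pairs = [], [], []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        w = off_diag & (dist > lo) & (dist <= hi)
        pairs = w.sum() // 2
        if pairs < 2:
            _w.warn(f"correlogram: bin ({lo:.0f}, {hi:.0f}] has {pairs} pairs; dropped")
            continue
        in_bin.append(w.astype(float))
        centres.append((lo + hi) / 2.0)
        n_pairs.append(int(pairs))
    if not in_bin:
        raise ModelError("no distance bin has at least 2 pairs")
    observed = _binned_morans_i(z[:, None], in_bin)[:, 0]
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perms = np.stack([rng.permutation(z) for _ in range(n_perm)], axis=1)
        null = _binned_morans_i(perms, in_bin)
        low = np.quantile(null, alpha / 2.0, axis=1)
        high = np.quantile(null, 1.0 - alpha / 2.0, axis=1)
        significant = (observed < low) | (observed > high)
    else:
        low = high = significant = None
    return Correlogram(np.array(centres), observed, np.array(n_pairs),
                       low, high, significant)
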
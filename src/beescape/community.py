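"""Site-level bee community metrics and ordination.

The analysis pipeline mirrors standard community-ecology practice: per-site
abundance is the square root of the mean per-visit count (managed honeybees
excluded); diversity is Simpson's 1-D on pooled counts (honeybees included);
composition is summarized by non-metric multidimensional scaling (NMDS) of
Bray-Curtis dissimilarities computed on a season-mean, square-root,
Wisconsin-double-standardized site x species matrix, with the oriented first
NMDS axis carried forward as the composition response variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .synthgen import HONEYBEE, ValidationError


# ---------------------------------------------------------------------------
# abundance and diversity


def site_abundance(surveys: pd.DataFrame,
                   exclude: tuple[str, ...] = (HONEYBEE,)) -> pd.Series:
    """sqrt(mean per-visit total count) per site, excluding listed species.

    The square-root transform is applied after averaging across visits.
    """
    _check_surveys(surveys)
    kept = surveys[~surveys["species"].isin(exclude)]
    # per-visit totals must include visits where every kept count is zero
    visits = surveys.groupby("site_id")["visit"].nunique()
    if (visits < 1).any():
        raise ValidationError("every site needs at least one visit")
    per_visit = kept.groupby(["site_id", "visit"])["count"].sum()
    totals = per_visit.groupby("site_id").sum().reindex(visits.index, fill_value=0)
    return np.sqrt(totals / visits).rename("abundance")


def simpson_diversity(counts, variant: str = "plugin") -> float:
    """Simpson's diversity 1-D of a count vector.

    variant="plugin" gives 1 - sum(p_i^2); variant="unbiased" gives the
    finite-sample form 1 - sum(n_i(n_i-1)) / (N(N-1)).
    """
    values = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts,
                        dtype=float)
    if np.any(values < 0):
        raise ValidationError("negative counts")
    total = values.sum()
    if total <= 0:
        raise ValidationError("Simpson diversity undefined for all-zero counts")
    if variant == "plugin":
        p = values / total
        return float(1.0 - np.sum(p**2))
    if variant == "unbiased":
        if total <= 1:
            raise ValidationError("unbiased Simpson needs at least two individuals")
        return float(1.0 - np.sum(values * (values - 1.0)) / (total * (total - 1.0)))
    raise ValidationError(f"unknown Simpson variant {variant!r}")


def site_diversity(surveys: pd.DataFrame, variant: str = "plugin") -> pd.Series:
    """Simpson's 1-D per site on counts pooled over visits (honeybees kept).

    A site where no bees were recorded at all has no community to describe;
    its diversity is reported as 0 with a warning rather than NaN.
    """
    _check_surveys(surveys)
    pooled = surveys.groupby(["site_id", "species"])["count"].sum()

    def per_site(s: pd.Series) -> float:
        if s.sum() <= 0:
            warnings.warn("site with zero total count: diversity set to 0")
            return 0.0
        return simpson_diversity(s.to_numpy(), variant=variant)

    return pooled.groupby("site_id").apply(per_site).rename("diversity")


def _check_surveys(surveys: pd.DataFrame) -> None:
    required = {"site_id", "visit", "species", "count"}
    missing = required - set(surveys.columns)
    if missing:
        raise ValidationError(f"survey table missing columns {sorted(missing)}")
    if (surveys["count"] < 0).any():
        raise ValidationError("negative counts in survey table")


# ---------------------------------------------------------------------------
# community matrix


@dataclass
class CommunityMatrix:
    """Ordered site x species abundances with a processing-stage label."""

    values: pd.DataFrame
    stage: str = "raw_mean"

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("community matrix has negative entries")
        if self.stage not in ("raw_mean", "sqrt", "wisconsin"):
            raise ValidationError(f"unknown stage {self.stage!r}")

    @property
    def sites(self) -> list[str]:
        return list(self.values.index)

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)


def build_community_matrix(surveys: pd.DataFrame) -> CommunityMatrix:
    """Season-mean counts -> sqrt -> Wisconsin double standardization.

    Wisconsin standardization divides each species column by its maximum and
    then each site row by its total; all-zero rows or columns are left as
    zeros rather than producing NaN.
    """
    _check_surveys(surveys)
    visits = surveys.groupby("site_id")["visit"].nunique()
    pooled = surveys.groupby(["site_id", "species"])["count"].sum().unstack(fill_value=0)
    raw = pooled.div(visits, axis=0).sort_index()
    if not np.any(raw.to_numpy() > 0):
        raise ValidationError("community matrix is entirely zero")
    return wisconsin(CommunityMatrix(np.sqrt(raw), stage="sqrt"))


def wisconsin(matrix: CommunityMatrix) -> CommunityMatrix:
    values = matrix.values.copy().astype(float)
    col_max = values.max(axis=0).replace(0.0, 1.0)
    values = values.div(col_max, axis=1)
    row_sum = values.sum(axis=1).replace(0.0, 1.0)
    values = values.div(row_sum, axis=0)
    return CommunityMatrix(values, stage="wisconsin")


# ---------------------------------------------------------------------------
# Bray-Curtis


@dataclass
class DistanceMatrix:
    """Symmetric site x site dissimilarities in [0, 1] with zero diagonal."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-12:
            raise ValidationError("distances must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def bray_curtis(matrix: CommunityMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity; a 0/0 pair is defined as 0."""
    x = matrix.values.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValidationError("Bray-Curtis requires nonnegative abundances")
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    summ = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    zero = summ == 0
    if zero.any() and zero[~np.eye(len(x), dtype=bool)].any():
        warnings.warn("all-zero site pair(s): Bray-Curtis distance defined as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(zero, 0.0, diff / np.where(zero, 1.0, summ))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(matrix.values.index))


# ---------------------------------------------------------------------------
# NMDS


@dataclass
class Ordination:
    """NMDS configuration with Kruskal stress-1 and convergence metadata."""

    scores: pd.DataFrame
    stress: float
    k: int
    converged: bool
    n_starts_used: int
    stress_trace: list[float] = field(default_factory=list)

    def axis(self, i: int = 1) -> pd.Series:
        return self.scores.iloc[:, i - 1]


def _kruskal_stress(dhat: np.ndarray, dstar: np.ndarray) -> float:
    denom = float(np.sum(dhat**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dhat - dstar) ** 2) / denom))


def _isotonic_fit(dvec: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    """Monotone regression of configuration distances on dissimilarity order.

    Weak (primary) tie handling: within tied dissimilarities, pairs are
    ordered by their current configuration distance, so ties impose no
    constraint among themselves.
    """
    order = np.lexsort((dhat, dvec))
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(order.size, dtype=float), dhat[order])
    dstar = np.empty_like(fitted)
    dstar[order] = fitted
    return dstar


def _guttman_step(x: np.ndarray, dhat: np.ndarray, dstar: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    ratio = squareform(dstar / np.maximum(dhat, 1e-12), checks=False)
    b = -ratio
    np.fill_diagonal(b, ratio.sum(axis=1))
    return (b @ x) / n


def _classical_start(d: np.ndarray, k: int) -> np.ndarray:
    """Classical (metric) scaling of the dissimilarities as a warm start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    comps = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))
    return comps


def _nmds_single(d: np.ndarray, x0: np.ndarray, max_iter: int, tol: float
                 ) -> tuple[np.ndarray, float, bool, list[float]]:
    dvec = squareform(d, checks=False)
    guard = dvec.min() > 0  # guard against cluster collapse (see _is_collapsed)
    x = x0 - x0.mean(axis=0)
    dhat = np.maximum(pdist(x), 1e-12)
    dstar = _isotonic_fit(dvec, dhat)
    stress = _kruskal_stress(dhat, dstar)
    trace = [stress]
    converged = False
    for _ in range(max_iter):
        target = _guttman_step(x, dhat, dstar)
        alpha, accepted = 1.0, False
        for _ in range(20):
            x_try = x + alpha * (target - x)
            dhat_try = np.maximum(pdist(x_try), 1e-12)
            if guard and dhat_try.min() < 0.005 * dhat_try.max():
                alpha *= 0.5  # step would merge sites; shorten it
                continue
            dstar_try = _isotonic_fit(dvec, dhat_try)
            stress_try = _kruskal_stress(dhat_try, dstar_try)
            if stress_try <= stress:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            converged = True
            break
        improvement = stress - stress_try
        x, dhat, dstar, stress = x_try, dhat_try, dstar_try, stress_try
        trace.append(stress)
        if stress < 1e-8 or improvement <= tol * max(stress, 1e-12):
            converged = True
            break
    return x - x.mean(axis=0), stress, converged, trace


def _is_collapsed(x: np.ndarray, dvec: np.ndarray, ratio: float = 0.005) -> bool:
    """Detect the degenerate cluster solution of weak-tie stress minimization.

    Stress-1 with primary tie handling admits near-zero-stress solutions in
    which sites collapse into a handful of coincident clusters whenever the
    dissimilarities are approximately ultrametric.  Such configurations carry
    no gradient information along the axes, so they are rejected when the
    input dissimilarities themselves keep all site pairs apart.
    """
    dhat = pdist(x)
    if dvec.min() <= 0:
        return False  # genuinely coincident sites are allowed to coincide
    return bool(dhat.min() < ratio * dhat.max())


def nmds(dist: DistanceMatrix, k: int = 2, n_starts: int = 20,
         max_iter: int = 300, tol: float = 1e-7, seed: int = 0) -> Ordination:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    The first start is the classical-scaling configuration; the remaining
    ``n_starts - 1`` starts are random.  Within each start the stress trace
    is non-increasing by construction (monotone line search on the Guttman
    direction with isotonic refits).  Collapsed (degenerate-cluster)
    solutions are rejected in favour of the best non-degenerate start.
    """
    d = dist.values
    if d.shape[0] < k + 2:
        raise ValidationError(f"need at least {k + 2} sites for a {k}-D ordination")
    dvec = squareform(d, checks=False)
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, bool, list[float]] | None = None
    best_any: tuple[float, np.ndarray, bool, list[float]] | None = None
    for start in range(max(1, n_starts)):
        if start == 0:
            x0 = _classical_start(d, k)
            if not np.all(np.isfinite(x0)) or np.allclose(x0, 0):
                x0 = rng.standard_normal((d.shape[0], k))
        else:
            x0 = rng.standard_normal((d.shape[0], k))
        x, stress, conv, trace = _nmds_single(d, x0, max_iter, tol)
        candidate = (stress, x, conv, trace)
        if best_any is None or stress < best_any[0]:
            best_any = candidate
        if not _is_collapsed(x, dvec) and (best is None or stress < best[0]):
            best = candidate
    if best is None:
        warnings.warn("NMDS: every start collapsed to a degenerate cluster "
                      "solution; returning the lowest-stress one")
        best = best_any
    stress, x, conv, trace = best
    # stress-1 is scale-invariant; fix the scale so the mean configuration
    # distance equals the mean input dissimilarity (keeps axis scores on an
    # interpretable scale without touching the stress)
    mean_dhat = float(np.mean(pdist(x)))
    mean_d = float(np.mean(squareform(d, checks=False)))
    if mean_dhat > 0 and mean_d > 0:
        x = x * (mean_d / mean_dhat)
    if not conv:
        warnings.warn("NMDS: no start converged; returning best effort")
    scores = pd.DataFrame(x, index=dist.ids,
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    return Ordination(scores=scores, stress=stress, k=k, converged=conv,
                      n_starts_used=max(1, n_starts), stress_trace=trace)


def orient_axis(ordination: Ordination, anchor: pd.Series) -> Ordination:
    """Reflect axis 1 so it correlates nonnegatively with the anchor variable.

    NMDS solutions are reflection-invariant; by convention the positive end
    of axis 1 is aligned with wind-pollinated-crop cover.
    """
    scores = ordination.scores.copy()
    anchor = anchor.reindex(scores.index)
    axis1 = scores.iloc[:, 0]
    r = np.corrcoef(axis1.to_numpy(), anchor.to_numpy())[0, 1]
    if np.isnan(r) or r == 0.0:
        warnings.warn("axis orientation anchor uncorrelated with axis 1; leaving as-is")
    elif r < 0:
        scores.iloc[:, 0] = -axis1
    return Ordination(scores=scores, stress=ordination.stress, k=ordination.k,
                      converged=ordination.converged,
                      n_starts_used=ordination.n_starts_used,
                      stress_trace=list(ordination.stress_trace))


# ---------------------------------------------------------------------------
# environmental vector fitting


@dataclass
class VectorFit:
    variable: str
    direction: np.ndarray
    r2: float
    p_value: float


def envfit(ordination: Ordination, env: pd.DataFrame, n_perm: int = 999,
           seed: int = 0) -> list[VectorFit]:
    """Fit environmental vectors to ordination scores with permutation tests.

    For each variable the direction is proportional to the least-squares
    coefficients of the (centred) variable on the (centred) scores; r2 is the
    squared multiple correlation, and the p-value is
    (1 + #{permuted r2 >= observed}) / (n_perm + 1).
    """
    scores = ordination.scores.to_numpy(dtype=float)
    s = scores - scores.mean(axis=0)
    # orthonormal basis of the score space for fast projected r2
    q, _ = np.linalg.qr(s)
    rng = np.random.default_rng(seed)
    fits = []
    for name in env.columns:
        v = env[name].reindex(ordination.scores.index).to_numpy(dtype=float)
        vc = v - v.mean()
        tss = float(vc @ vc)
        if tss <= 0:
            warnings.warn(f"envfit: variable {name!r} is constant")
            fits.append(VectorFit(name, np.zeros(s.shape[1]), 0.0, 1.0))
            continue
        beta, *_ = np.linalg.lstsq(s, vc, rcond=None)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        proj = q.T @ vc
        r2 = float(proj @ proj / tss)
        if n_perm > 0:
            perms = np.stack([rng.permutation(vc) for _ in range(n_perm)], axis=1)
            perm_proj = q.T @ perms
            perm_r2 = (perm_proj**2).sum(axis=0) / (perms**2).sum(axis=0)
            p = float((1 + np.count_nonzero(perm_r2 >= r2 - 1e-15)) / (n_perm + 1))
        else:
            p = 1.0
        fits.append(VectorFit(name, direction, min(r2, 1.0), p))
    return fits


# ---------------------------------------------------------------------------
# SIMPER


def simper(matrix: CommunityMatrix, groups: dict[str, str] | pd.Series) -> pd.DataFrame:
    """Similarity-percentages decomposition of between-group dissimilarity.

    For every between-group site pair the per-species contribution is
    |x_is - x_js| / sum_t (x_it + x_jt); the species contribution is the mean
    over pairs, and contributions sum to the mean between-group Bray-Curtis
    dissimilarity.  Returns a table sorted by decreasing contribution.
    """
    groups = pd.Series(dict(groups) if isinstance(groups, dict) else groups)
    labels = set(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"SIMPER needs exactly two groups, got {sorted(labels)}")
    hi_label, lo_label = sorted(labels)
    values = matrix.values
    a_sites = [s for s in values.index if groups.get(s) == hi_label]
    b_sites = [s for s in values.index if groups.get(s) == lo_label]
    if not a_sites or not b_sites:
        raise ValidationError("both SIMPER groups must be nonempty")
    xa = values.loc[a_sites].to_numpy(dtype=float)
    xb = values.loc[b_sites].to_numpy(dtype=float)
    diff = np.abs(xa[:, None, :] - xb[None, :, :])          # pairs x species
    denom = (xa[:, None, :] + xb[None, :, :]).sum(axis=2)   # pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib_pairs = np.where(denom[..., None] > 0, diff / np.maximum(denom, 1e-300)[..., None], 0.0)
    contrib = contrib_pairs.mean(axis=(0, 1))
    total = contrib.sum()
    if total > 0:
        percent = 100.0 * contrib / total
    else:
        warnings.warn("SIMPER: groups are identical; zero total dissimilarity")
        percent = np.zeros_like(contrib)
    table = pd.DataFrame({
        "species": values.columns,
        "contribution": contrib,
        "percent": percent,
        f"mean_{hi_label}": xa.mean(axis=0),
        f"mean_{lo_label}": xb.mean(axis=0),
    }).sort_values("contribution", ascending=False, kind="stable").reset_index(drop=True)
    table["cumulative_percent"] = table["percent"].cumsum()
    return table
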
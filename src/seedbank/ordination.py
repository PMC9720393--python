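"""Community ordination and permutation inference.

The field-level community matrix holds per-field importance values (rows
sum to 3).  Pairwise Bray–Curtis dissimilarities feed a non-metric
multidimensional scaling (Kruskal stress-1, monotone-regressed
disparities, iterative majorization, multi-start) and a one-way
PERMANOVA (distance-based pseudo-F with a free label-permutation null).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.stats import chi2

from .phytosociology import stratum_tables
from .types import PracticeRecord, QuadratCounts, ValidationError


@dataclass
class CommunityMatrix:
    """Fields × species importance-value matrix with row metadata."""

    values: pd.DataFrame  # index: "site/field", columns: species ids
    meta: pd.DataFrame  # index matching values; columns: site, field, mode[, region]


def community_matrix(
    quadrats: Sequence[QuadratCounts],
    practices: Sequence[PracticeRecord] | None = None,
) -> CommunityMatrix:
    """Per-field IV composition matrix (absent species = 0).

    Each row is one sampled field; each row sums to 3 by the IV
    normalization identity.  Region labels are attached from the
    practice table when given.
    """
    tables = stratum_tables(quadrats, by="field")
    if len(tables) < 2:
        raise ValidationError("ordination needs at least 2 fields")
    iv = pd.DataFrame(
        {label: t["IV"] for label, t in tables.items()}
    ).T.fillna(0.0)
    iv = iv.sort_index(axis=1)
    iv.index.name = "field_label"

    mode_by_site = {}
    for q in quadrats:
        mode_by_site[q.site_id] = q.mode
    region_by_site = {p.site_id: p.region for p in practices} if practices else {}
    meta_rows = []
    for label in iv.index:
        site, fid = label.rsplit("/", 1)
        meta_rows.append(
            {
                "site": site,
                "field": int(fid),
                "mode": mode_by_site[site],
                "region": region_by_site.get(site, ""),
            }
        )
    meta = pd.DataFrame(meta_rows, index=iv.index)
    return CommunityMatrix(values=iv, meta=meta)


def bray_curtis(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarities.

    d_ij = 1 − 2 Σ_k min(x_ik, x_jk) / Σ_k (x_ik + x_jk), in [0, 1].
    Raises if any entry is negative or if a pair of all-zero rows makes
    the denominator vanish.
    """
    if isinstance(matrix, CommunityMatrix):
        matrix = matrix.values
    x = np.asarray(matrix, dtype=float)
    if (x < 0).any():
        raise ValidationError("Bray-Curtis requires non-negative abundances")
    row_sums = x.sum(axis=1)
    denom = row_sums[:, None] + row_sums[None, :]
    if np.any((denom == 0) & ~np.eye(len(x), dtype=bool)):
        raise ValidationError("Bray-Curtis undefined between two all-zero rows")
    shared = np.minimum(x[:, None, :], x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = 1.0 - 2.0 * shared / denom
    np.fill_diagonal(d, 0.0)
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(len(x))
    return pd.DataFrame(d, index=index, columns=index)


def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValidationError("distances must be non-negative")
    if not np.allclose(np.diag(d), 0.0):
        raise ValidationError("distance matrix must have zero diagonal")
    return d


# ---------------------------------------------------------------------------
# non-metric multidimensional scaling


@dataclass
class NMDSResult:
    coords: pd.DataFrame  # n × k, centered, principal-axis rotated
    stress: float  # Kruskal stress-1 of the best run
    n_runs: int
    best_run: int
    best_run_seed: int
    converged: bool
    run_stresses: np.ndarray = field(repr=False, default=None)


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson principal-coordinates start configuration."""
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def _stress_majorization(d: np.ndarray, x0: np.ndarray, max_iter: int, tol: float):
    """One Kruskal NMDS run: isotonic disparities + Guttman transform."""
    n = len(d)
    iu = np.triu_indices(n, k=1)
    delta = d[iu]
    # primary tie treatment: within tied dissimilarities, order by current
    # configuration distance so ties are free to take unequal disparities
    base_order = np.lexsort((np.arange(delta.size), delta))

    x = x0.copy()
    last_stress = np.inf
    converged = False
    for _ in range(max_iter):
        diff = x[:, None, :] - x[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        dvec = dist[iu]
        order = np.lexsort((dvec, delta))
        dhat_sorted = isotonic_regression(dvec[order], increasing=True).x
        dhat = np.empty_like(dvec)
        dhat[order] = dhat_sorted

        denom = (dvec**2).sum()
        if denom == 0:
            break
        stress = np.sqrt(((dvec - dhat) ** 2).sum() / denom)

        if abs(last_stress - stress) < tol:
            converged = True
            last_stress = stress
            break
        last_stress = stress

        # configuration scale is a gauge freedom of stress-1; fix it by
        # normalizing the disparities to the dissimilarity norm before the
        # update, so the configuration stays on the data scale instead of
        # drifting toward the collapse gauge
        dhat_norm = (dhat**2).sum()
        if dhat_norm > 0:
            dhat = dhat * np.sqrt((delta**2).sum() / dhat_norm)

        # Guttman transform toward the disparities
        dhat_mat = np.zeros_like(d)
        dhat_mat[iu] = dhat
        dhat_mat += dhat_mat.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat_mat / dist, 0.0)
        b = -ratio
        b[np.diag_indices(n)] = ratio.sum(axis=1)
        x = (b @ x) / n
    return x, float(last_stress), converged


def nmds(
    d: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_runs: int = 250,
    max_iter: int = 300,
    tol: float = 1e-7,
    rng: np.random.Generator | int | None = None,
) -> NMDSResult:
    """Non-metric MDS with multi-start stress minimization.

    Run 1 starts from classical metric scaling of the distances; the
    remaining runs start from seeded random Gaussian configurations.
    The lowest-stress configuration is returned, centered at the origin
    and rotated to its principal axes (deterministic sign convention).
    """
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(len(d))
    dm = _check_distance_matrix(np.asarray(d, dtype=float))
    n = len(dm)
    if n < k + 2:
        raise ValidationError(f"need at least {k + 2} rows for a {k}-dimensional NMDS")
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    rng = np.random.default_rng(rng)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)

    best = None
    stresses = np.empty(n_runs)
    for run in range(n_runs):
        if run == 0:
            x0 = _classical_mds(dm, k)
        else:
            x0 = np.random.default_rng(run_seeds[run]).normal(size=(n, k))
            x0 *= dm.max() / max(np.abs(x0).max(), 1e-12)
        x, stress, converged = _stress_majorization(dm, x0, max_iter, tol)
        stresses[run] = stress
        if best is None or stress < best[1]:
            best = (x, stress, converged, run)

    x, stress, converged, run = best
    x = x - x.mean(axis=0)
    # principal-axis rotation with a sign convention: the coordinate of
    # largest magnitude on each axis is positive
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for j in range(x.shape[1]):
        i = np.argmax(np.abs(x[:, j]))
        if x[i, j] < 0:
            x[:, j] = -x[:, j]
    coords = pd.DataFrame(x, index=index, columns=[f"NMDS{i+1}" for i in range(k)])
    return NMDSResult(
        coords=coords,
        stress=stress,
        n_runs=n_runs,
        best_run=run,
        best_run_seed=int(run_seeds[run]),
        converged=converged,
        run_stresses=stresses,
    )


# ---------------------------------------------------------------------------
# one-way PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    SS_total: float
    SS_within: float
    SS_between: float
    df_between: int
    df_within: int


def _ss_partition(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray):
    n = len(d2)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total, ss_within


def permanova(
    d: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> PermanovaResult:
    """Distance-based one-way permutational multivariate ANOVA.

    SS_total = Σ_{i<j} d²_ij / n; SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g;
    pseudo-F = (SS_between/(g−1)) / (SS_within/(n−g)).  The p-value is
    (b+1)/(m+1) where b counts free label permutations with F at least
    the observed value, so the attainable minimum is 1/(n_perm+1).
    """
    dm = _check_distance_matrix(np.asarray(d, dtype=float))
    labels = np.asarray(groups)
    n = len(dm)
    if labels.shape[0] != n:
        raise ValidationError("groups must have one label per row of the matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    g = len(uniq)
    if g < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    if g >= n:
        raise ValidationError("all groups are singletons; SS_within is empty")
    if n_perm < 0:
        raise ValidationError("n_perm must be >= 0")
    rng = np.random.default_rng(rng)

    d2 = dm**2
    ss_total, ss_within = _ss_partition(d2, labels, uniq)
    ss_between = ss_total - ss_within
    df_b, df_w = g - 1, n - g

    def f_stat(ss_w):
        ss_b = ss_total - ss_w
        if ss_w <= 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / df_b) / (ss_w / df_w)

    f_obs = f_stat(ss_within)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, ss_w = _ss_partition(d2, labels[perm], uniq)
        if f_stat(ss_w) >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(ss_between / ss_total) if ss_total > 0 else 0.0,
        p_value=float(p),
        n_permutations=n_perm,
        SS_total=float(ss_total),
        SS_within=float(ss_within),
        SS_between=float(ss_between),
        df_between=df_b,
        df_within=df_w,
    )


# ---------------------------------------------------------------------------
# group confidence ellipses for ordination plots


@dataclass
class Ellipse:
    group: str
    center: np.ndarray
    axes: np.ndarray  # semi-axis lengths, descending
    rotation: np.ndarray  # columns: axis directions
    level: float
    degenerate: bool = False


def confidence_ellipse(
    coords: pd.DataFrame | np.ndarray,
    groups: Sequence,
    level: float = 0.95,
) -> dict[str, Ellipse]:
    """Per-group covariance ellipses at a chi-square confidence level.

    Semi-axes are sqrt(eigenvalue × χ²₂(level)) along the covariance
    eigenvectors.  Groups with fewer than 3 members or a rank-deficient
    covariance are flagged degenerate and carry no axes.
    """
    x = np.asarray(coords, dtype=float)
    if x.shape[1] != 2:
        raise ValidationError("confidence ellipses are defined for 2-D coordinates")
    if not 0 <= level < 1:
        raise ValidationError("level must be in [0, 1)")
    labels = np.asarray(groups)
    q = chi2.ppf(level, df=2) if level > 0 else 0.0
    out: dict[str, Ellipse] = {}
    for g in np.unique(labels):
        pts = x[labels == g]
        center = pts.mean(axis=0)
        if len(pts) < 3:
            out[str(g)] = Ellipse(str(g), center, np.zeros(2), np.eye(2), level, True)
            continue
        cov = np.cov(pts, rowvar=False)
        vals, vecs = np.linalg.eigh(cov)
        vals = vals[::-1]
        vecs = vecs[:, ::-1]
        if vals[-1] <= 1e-12 * max(vals[0], 1.0):
            out[str(g)] = Ellipse(str(g), center, np.zeros(2), vecs, level, True)
            continue
        out[str(g)] = Ellipse(str(g), center, np.sqrt(vals * q), vecs, level, False)
    return out
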
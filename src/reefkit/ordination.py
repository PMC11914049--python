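"""Community ordination and permutation tests on robust Aitchison distances.

The community trajectory of a reef is summarized by (i) pairwise robust
Aitchison distances between samples (Euclidean distance between rclr-
transformed cover rows), (ii) a 2-D non-metric multidimensional scaling of
that matrix with Kruskal stress-1, (iii) least-squares environmental vectors
overlaid on the ordination, and (iv) permutational multivariate ANOVA
partitioning the distance matrix by substrate, survey year and depth with
their interactions (sequential sums of squares, free permutation of rows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .composition import rclr_transform

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "robust_aitchison_dist",
    "nmds",
    "fit_env_vectors",
    "permanova",
    "pairwise_permanova",
]


def robust_aitchison_dist(cover_matrix: pd.DataFrame) -> DistanceMatrix:
    """Robust Aitchison distance: Euclidean distance between rclr rows.

    ``cover_matrix`` is samples x parts with zero replacement already applied
    (strictly positive entries); row labels become sample ids.
    """
    rclr = rclr_transform(cover_matrix)
    diffs = rclr[:, None, :] - rclr[None, :, :]
    d = np.sqrt((diffs**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    ids = (
        [str(i) for i in cover_matrix.index]
        if isinstance(cover_matrix, pd.DataFrame)
        else None
    )
    return DistanceMatrix(d, ids=ids)


# ---------------------------------------------------------------------------
# nMDS

@dataclass
class OrdinationResult:
    """Best nMDS configuration (centered, principal-axis rotated)."""

    coords: pd.DataFrame       # samples x dims
    stress: float              # Kruskal stress-1
    converged: bool
    n_restarts: int
    vectors: pd.DataFrame | None = field(default=None)


def kruskal_stress1(dist: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against target dissimilarities."""
    iu = np.triu_indices(dist.shape[0], k=1)
    d_obs = dist[iu]
    d_conf = np.sqrt(((coords[iu[0]] - coords[iu[1]]) ** 2).sum(axis=1))
    order = np.argsort(d_obs, kind="stable")
    disparities = np.empty_like(d_conf)
    disparities[order] = IsotonicRegression().fit_transform(
        np.arange(order.size), d_conf[order]
    )
    denom = float(np.sum(d_conf**2))
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(np.sum((d_conf - disparities) ** 2) / denom))


def nmds(
    dist: DistanceMatrix,
    dims: int = 2,
    restarts: int = 999,
    *,
    seed: int | None = None,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric MDS by monotone-regression stress majorization.

    Runs up to ``restarts`` random initializations (the restart budget) and
    keeps the lowest-stress configuration, centered at the origin and rotated
    to its principal axes.  Stress is Kruskal stress-1.
    """
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for an nMDS")
    coords, _, n_iter = smacof(
        d,
        metric=False,
        n_components=dims,
        n_init=restarts,
        max_iter=max_iter,
        random_state=int(np.random.default_rng(seed).integers(2**31)),
        normalized_stress=True,
        return_n_iter=True,
    )
    coords = coords - coords.mean(axis=0)
    # rotate to principal axes
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    stress = kruskal_stress1(d, coords)
    return OrdinationResult(
        coords=pd.DataFrame(
            coords, index=list(dist.ids), columns=[f"nmds{i+1}" for i in range(dims)]
        ),
        stress=stress,
        converged=bool(n_iter < max_iter),
        n_restarts=restarts,
    )


def fit_env_vectors(
    ordination: OrdinationResult,
    variables: pd.DataFrame,
    perms: int = 999,
    *,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fit least-squares direction vectors of variables in ordination space.

    For each numeric variable: the unit direction in the ordination plane
    maximizing its correlation with the configuration, the squared
    correlation r^2, and a permutation p-value from shuffling sample labels.
    Constant variables are skipped with a warning.
    """
    coords = ordination.coords.to_numpy()
    coords_c = coords - coords.mean(axis=0)
    rng = np.random.default_rng(seed)
    rows = {}
    for name in variables.columns:
        y = variables[name].to_numpy(dtype=float)
        if np.ptp(y) == 0.0:
            logger.warning("env vector %r skipped: constant variable", name)
            continue
        r2_obs, direction = _envfit_r2(coords_c, y)
        exceed = 0
        for _ in range(perms):
            r2_p, _ = _envfit_r2(coords_c, rng.permutation(y))
            exceed += r2_p >= r2_obs
        rows[name] = {
            "dx": direction[0],
            "dy": direction[1] if direction.size > 1 else 0.0,
            "r2": r2_obs,
            "p": (exceed + 1) / (perms + 1),
        }
    table = pd.DataFrame(rows).T
    ordination.vectors = table
    return table


def _envfit_r2(coords_c: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    yc = y - y.mean()
    b, *_ = np.linalg.lstsq(coords_c, yc, rcond=None)
    fitted = coords_c @ b
    ss_tot = float(yc @ yc)
    r2 = float(fitted @ fitted) / ss_tot if ss_tot > 0 else 0.0
    norm = np.linalg.norm(b)
    direction = b / norm if norm > 0 else b
    return r2, direction


# ---------------------------------------------------------------------------
# PERMANOVA

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _term_matrix(design: pd.DataFrame, term: str) -> np.ndarray:
    """Columns for one model term; ':' builds an interaction product."""
    factors = term.split(":")
    blocks = []
    for f in factors:
        if f not in design.columns:
            raise ValueError(f"term {term!r}: column {f!r} not in design")
        col = design[f]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
            if dummies.shape[1] == 0:
                raise ValueError(f"term {term!r} has zero degrees of freedom")
            blocks.append(dummies)
        else:
            blocks.append(col.to_numpy(dtype=float)[:, None])
    out = blocks[0]
    for nxt in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, nxt).reshape(len(design), -1)
    return out


def permanova(
    dist: DistanceMatrix,
    design: pd.DataFrame,
    terms: list[str] | None = None,
    perms: int = 9999,
    *,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA with sequential (Type-I) SS.

    Terms enter in the given order (default ``substrate, year, depth,
    substrate:year, substrate:depth``); each term's sum of squares is the
    increment in explained Gower-centered inner product when it is added.
    p-values come from free permutation of sample rows,
    ``p = (exceedances + 1) / (perms + 1)``.
    """
    if terms is None:
        terms = ["substrate", "year", "depth", "substrate:year", "substrate:depth"]
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    if len(design) != n:
        raise ValueError("design rows do not match distance matrix")
    g = _gower_center(d)

    # cumulative projection (hat) matrices, one per sequential term
    hats = []
    x = np.ones((n, 1))
    dfs: list[int] = []
    prev_rank = 1
    for term in terms:
        x = np.hstack([x, _term_matrix(design.reset_index(drop=True), term)])
        rank = int(np.linalg.matrix_rank(x))
        df = rank - prev_rank
        if df == 0:
            raise ValueError(f"term {term!r} adds zero degrees of freedom")
        dfs.append(df)
        hats.append(x @ np.linalg.pinv(x))
        prev_rank = rank
    df_resid = n - prev_rank
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    dfs_arr = np.array(dfs, dtype=float)

    def partition(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_prev = 0.0
        ss_terms = np.empty(len(terms))
        for k, h in enumerate(hats):
            ss_cum = float(np.sum(h * gmat))   # tr(H G)
            ss_terms[k] = ss_cum - ss_prev
            ss_prev = ss_cum
        ss_resid = float(np.trace(gmat)) - ss_prev
        return ss_terms, ss_resid

    ss_terms, ss_resid = partition(g)
    ss_total = float(np.trace(g))
    f_obs = (ss_terms / dfs_arr) / (ss_resid / df_resid)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(perms):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_r_p = partition(gp)
        f_p = (ss_p / dfs_arr) / (ss_r_p / df_resid)
        exceed += f_p >= f_obs - 1e-8      # ties count as exceedances
    pvals = (exceed + 1) / (perms + 1)

    rows = [
        {
            "term": t,
            "df": dfs[k],
            "ss": ss_terms[k],
            "pseudo_F": f_obs[k],
            "R2": ss_terms[k] / ss_total,
            "p": pvals[k],
        }
        for k, t in enumerate(terms)
    ]
    rows.append(
        {"term": "residual", "df": df_resid, "ss": ss_resid,
         "pseudo_F": np.nan, "R2": ss_resid / ss_total, "p": np.nan}
    )
    rows.append(
        {"term": "total", "df": n - 1, "ss": ss_total,
         "pseudo_F": np.nan, "R2": 1.0, "p": np.nan}
    )
    return pd.DataFrame(rows).set_index("term")


def pairwise_permanova(
    dist: DistanceMatrix,
    group: pd.Series,
    perms: int = 9999,
    *,
    seed: int | None = None,
) -> pd.DataFrame:
    """One-factor PERMANOVA per group pair with Bonferroni adjustment.

    Groups with fewer than 2 samples are skipped with a warning; adjusted
    p = min(1, p x number of tested pairs).
    """
    group = pd.Series(group).reset_index(drop=True)
    levels = [lvl for lvl, cnt in group.value_counts().items() if cnt >= 2]
    skipped = set(group.unique()) - set(levels)
    if skipped:
        logger.warning("pairwise PERMANOVA: groups %s skipped (<2 samples)", skipped)
    if len(levels) < 2:
        raise ValueError("need at least two groups with >= 2 samples")
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    rng = np.random.default_rng(seed)
    d = np.asarray(dist.data)
    rows = []
    for a, b in pairs:
        mask = group.isin([a, b]).to_numpy()
        sub = DistanceMatrix(d[np.ix_(mask, mask)])
        sub_design = pd.DataFrame({"group": group[mask].astype(str).to_numpy()})
        table = permanova(
            sub, sub_design, terms=["group"], perms=perms,
            seed=int(rng.integers(2**31)),
        )
        raw_p = float(table.loc["group", "p"])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "pseudo_F": float(table.loc["group", "pseudo_F"]),
                "p": raw_p,
                "p_adjusted": min(1.0, raw_p * len(pairs)),
            }
        )
    return pd.DataFrame(rows)
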
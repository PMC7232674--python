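"""Decomposable BIC family scores for Gaussian, multinomial, and CG nodes.

The unit of scoring is the *family* (child, parent set).  Every score uses
the maximized-log-likelihood convention

    bic = loglik - (k / 2) * ln(n)

which is *maximized* during search; sticking to one convention everywhere
avoids the classic sign bug.  A DAG's global score is the sum of its family
scores (decomposability), so search only ever needs local recomputation.

Families:

* continuous child, continuous parents — ordinary least squares with an
  intercept, Gaussian log-likelihood at the MLE variance,
  ``k = |parents| + 2`` (slopes + intercept + variance);
* discrete child, discrete parents — conditional probability table rows
  estimated by the Dirichlet(alpha) posterior mean (default alpha = 1, i.e.
  add-one smoothing), log-likelihood evaluated at those estimates,
  ``k = (levels(child) - 1) * prod levels(parents)``;
* continuous child, mixed parents — conditional Gaussian: per
  discrete-configuration intercepts with slopes shared across configurations
  (stable at small n), ``k = #continuous parents + #intercept groups + 1``.

Zero-residual-variance (degenerate) families are flagged and carry an
infinite sentinel; the search layer excludes them rather than propagating
infinities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import xlogy

from .dataset import Dataset
from .exceptions import (
    InsufficientDataError,
    InvalidArgumentError,
    MixedConstraintError,
)
from .network import CONTINUOUS, DISCRETE, TypedDag

_LOG_2PI = math.log(2.0 * math.pi)
# residual variance below this (relative to the child's scale) is "exact fit"
_DEGENERATE_REL_VAR = 1e-12


@dataclass(frozen=True)
class FamilyScore:
    """(child, parent set) with its local BIC and bookkeeping."""

    child: str
    parents: frozenset[str]
    bic: float
    loglik: float
    k: int
    n: int
    degenerate: bool = False
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", frozenset(self.parents))


def _finish(child, parents, loglik, k, n, degenerate=False, flags=()) -> FamilyScore:
    if degenerate:
        return FamilyScore(
            child, frozenset(parents), math.inf, math.inf, k, n, True, tuple(flags)
        )
    bic = loglik - 0.5 * k * math.log(n)
    return FamilyScore(child, frozenset(parents), bic, loglik, k, n, False, tuple(flags))


def _gaussian_loglik(rss: float, n: int) -> float:
    sigma2 = rss / n
    return -0.5 * n * (_LOG_2PI + math.log(sigma2) + 1.0)


# ---------------------------------------------------------------------------
# stand-alone family scorers
# ---------------------------------------------------------------------------

def score_gaussian_family(
    data: Dataset, child: str, parents: Iterable[str] = ()
) -> FamilyScore:
    """OLS fit of ``child`` on ``parents`` (plus intercept), scored by BIC."""
    parents = tuple(sorted(parents))
    if data.kind(child) != CONTINUOUS:
        raise InvalidArgumentError(f"{child!r} is not continuous")
    n = data.n
    m = len(parents)
    if n <= m + 2:
        raise InsufficientDataError(
            f"n={n} too small for a Gaussian family with {m} parents"
        )
    y = data.column(child)
    X = np.column_stack(
        [np.ones(n)] + [data.column(q).astype(np.float64) for q in parents]
    )
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    flags: list[str] = []
    if rank < X.shape[1]:
        flags.append("rank_deficient")  # lstsq gives the pseudoinverse fit
    resid = y - X @ beta
    rss = float(resid @ resid)
    scale = max(1.0, float(np.var(y)))
    if rss / n <= _DEGENERATE_REL_VAR * scale:
        return _finish(child, parents, 0.0, m + 2, n, degenerate=True,
                       flags=flags + ["zero_residual_variance"])
    return _finish(child, parents, _gaussian_loglik(rss, n), m + 2, n, flags=flags)


def _parent_config_index(
    data: Dataset, parents: tuple[str, ...]
) -> tuple[np.ndarray, int, tuple[int, ...]]:
    """Row -> flat discrete-parent configuration index."""
    levels = tuple(data.spec(q).levels for q in parents)
    if not parents:
        return np.zeros(data.n, dtype=np.int64), 1, levels
    cols = [data.column(q) for q in parents]
    idx = np.ravel_multi_index(tuple(cols), dims=levels)
    return idx.astype(np.int64), int(np.prod(levels)), levels


def score_multinomial_family(
    data: Dataset, child: str, parents: Iterable[str] = (), alpha: float = 1.0
) -> FamilyScore:
    """CPT family score with Dirichlet(alpha) posterior-mean estimates.

    Rows with no observations contribute zero log-likelihood; with alpha = 0
    the estimates reduce to the plain MLE (and empty rows are read as
    uniform, which is irrelevant to the likelihood).
    """
    parents = tuple(sorted(parents))
    if data.kind(child) != DISCRETE:
        raise InvalidArgumentError(f"{child!r} is not discrete")
    for q in parents:
        if data.kind(q) != DISCRETE:
            raise MixedConstraintError(
                f"continuous parent {q!r} of discrete child {child!r}"
            )
    if alpha < 0:
        raise InvalidArgumentError("alpha must be >= 0")
    n = data.n
    r = data.spec(child).levels
    cfg_idx, n_cfg, _ = _parent_config_index(data, parents)
    counts = np.zeros((n_cfg, r), dtype=np.float64)
    np.add.at(counts, (cfg_idx, data.column(child)), 1.0)
    row_tot = counts.sum(axis=1, keepdims=True)
    if alpha == 0.0:
        # plain MLE; empty rows read as uniform (they contribute 0 anyway)
        theta = np.where(row_tot > 0, counts / np.where(row_tot > 0, row_tot, 1.0), 1.0 / r)
    else:
        theta = (counts + alpha) / (row_tot + alpha * r)
    loglik = float(xlogy(counts, theta).sum())
    k = (r - 1) * n_cfg
    return _finish(child, parents, loglik, k, n)


def score_cgaussian_family(
    data: Dataset,
    child: str,
    parents: Iterable[str] = (),
    shared_slopes: bool = True,
) -> FamilyScore:
    """Conditional-Gaussian family: continuous child, mixed parent kinds.

    Rows are partitioned by the discrete-parent configuration.  The default
    model shares the continuous-parent slopes across configurations and fits
    one intercept per observed configuration; configurations with fewer rows
    than (#continuous parents + 1) are pooled into a single fallback
    intercept group (flagged).  With no discrete parents this reduces
    exactly to :func:`score_gaussian_family`.
    """
    parents = tuple(sorted(parents))
    if data.kind(child) != CONTINUOUS:
        raise InvalidArgumentError(f"{child!r} is not continuous")
    disc = tuple(q for q in parents if data.kind(q) == DISCRETE)
    cont = tuple(q for q in parents if data.kind(q) == CONTINUOUS)
    if not disc:
        return score_gaussian_family(data, child, cont)
    n = data.n
    c = len(cont)
    cfg_idx, _, _ = _parent_config_index(data, disc)
    observed, inverse, sizes = np.unique(cfg_idx, return_inverse=True, return_counts=True)
    flags: list[str] = []
    # pool configurations too thin to support their own intercept
    thin = sizes < (c + 1)
    groups = inverse.copy()
    if thin.any() and (~thin).any():
        pooled_id = len(observed)
        groups[np.isin(inverse, np.nonzero(thin)[0])] = pooled_id
        flags.append("pooled_fallback")
    uniq_groups, groups = np.unique(groups, return_inverse=True)
    g = len(uniq_groups)
    if n <= c + g + 1:
        raise InsufficientDataError(
            f"n={n} too small for a CG family with {c} continuous parents and {g} groups"
        )
    y = data.column(child)
    dummies = np.zeros((n, g))
    dummies[np.arange(n), groups] = 1.0
    if shared_slopes:
        X = np.column_stack([dummies] + [data.column(q) for q in cont])
        k = c + g + 1
    else:
        blocks = [dummies]
        for q in cont:
            col = data.column(q)
            blocks.append(dummies * col[:, None])
        X = np.column_stack(blocks)
        k = g * (c + 1) + 1
        flags.append("per_config_slopes")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        flags.append("rank_deficient")
    resid = y - X @ beta
    rss = float(resid @ resid)
    scale = max(1.0, float(np.var(y)))
    if rss / n <= _DEGENERATE_REL_VAR * scale:
        return _finish(child, parents, 0.0, k, n, degenerate=True,
                       flags=flags + ["zero_residual_variance"])
    return _finish(child, parents, _gaussian_loglik(rss, n), k, n, flags=flags)


def score_family(
    data: Dataset, child: str, parents: Iterable[str] = (), alpha: float = 1.0
) -> FamilyScore:
    """Dispatch on child/parent kinds to the appropriate family scorer."""
    parents = tuple(sorted(parents))
    if data.kind(child) == DISCRETE:
        return score_multinomial_family(data, child, parents, alpha=alpha)
    if any(data.kind(q) == DISCRETE for q in parents):
        return score_cgaussian_family(data, child, parents)
    return score_gaussian_family(data, child, parents)


# ---------------------------------------------------------------------------
# cached scorer with a Gram-matrix fast path
# ---------------------------------------------------------------------------

class Scorer:
    """Pure, cached family scoring bound to one dataset.

    For all-continuous families the score is computed from a precomputed
    moment (Gram) matrix over ``[1 | continuous columns sorted by name]``:
    solving the normal equations on the relevant submatrix gives the OLS
    residual sum of squares without touching the raw rows again.  Besides
    speed, fixing the column order by *name* makes every score — and hence
    the whole search — independent of the dataset's column order.

    Lookups are pure: repeated queries return the identical FamilyScore
    object from the cache.
    """

    def __init__(self, data: Dataset, alpha: float = 1.0):
        self.data = data
        self.alpha = alpha
        self._cache: dict[tuple[str, frozenset[str]], FamilyScore] = {}
        names = sorted(data.continuous_names)
        self._cont_index = {name: i + 1 for i, name in enumerate(names)}
        if names:
            B = np.column_stack(
                [np.ones(data.n)] + [data.column(q) for q in names]
            )
            self._gram = B.T @ B
        else:
            self._gram = np.ones((1, 1)) * data.n

    def family_score(self, child: str, parents: Iterable[str] = ()) -> FamilyScore:
        parents_fs = frozenset(parents)
        key = (child, parents_fs)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if self.data.kind(child) == CONTINUOUS and all(
            self.data.kind(q) == CONTINUOUS for q in parents_fs
        ):
            score = self._gaussian_from_gram(child, tuple(sorted(parents_fs)))
        else:
            score = score_family(self.data, child, parents_fs, alpha=self.alpha)
        self._cache[key] = score
        return score

    def _gaussian_from_gram(self, child: str, parents: tuple[str, ...]) -> FamilyScore:
        n = self.data.n
        m = len(parents)
        if n <= m + 2:
            raise InsufficientDataError(
                f"n={n} too small for a Gaussian family with {m} parents"
            )
        yi = self._cont_index[child]
        idx = [0] + [self._cont_index[q] for q in parents]
        G = self._gram
        A = G[np.ix_(idx, idx)]
        b = G[idx, yi]
        yy = G[yi, yi]
        flags: list[str] = []
        try:
            coef = np.linalg.solve(A, b)
            rss = float(yy - b @ coef)
        except np.linalg.LinAlgError:
            coef, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
            rss = float(yy - b @ coef)
            flags.append("rank_deficient")
        # float cancellation can push an exact fit slightly negative
        rss = max(rss, 0.0)
        y_mean_sq = G[0, yi] / n
        var_y = max(yy / n - y_mean_sq**2, 0.0)
        scale = max(1.0, var_y)
        if rss / n <= _DEGENERATE_REL_VAR * scale:
            return _finish(child, parents, 0.0, m + 2, n, degenerate=True,
                           flags=flags + ["zero_residual_variance"])
        return _finish(child, parents, _gaussian_loglik(rss, n), m + 2, n, flags=flags)

    def score_all_continuous_subsets(
        self, child: str, pool: Sequence[str], max_size: int
    ) -> tuple[list[tuple[str, ...]], np.ndarray, np.ndarray]:
        """Score every parent subset of ``pool`` (size <= max_size) at once.

        Fast path for a continuous child with an all-continuous pool: for
        each subset size the normal-equation systems of all subsets are
        stacked and solved in one batched LAPACK call against the Gram
        matrix.  Returns parent-name tuples in enumeration order (sizes
        ascending, lexicographic within a size), the BIC array, and the
        degenerate-fit mask (degenerate entries carry an inf sentinel).
        """
        pool = sorted(pool)
        if self.data.kind(child) != CONTINUOUS or any(
            self.data.kind(q) != CONTINUOUS for q in pool
        ):
            raise InvalidArgumentError("bulk scoring needs continuous child and pool")
        n = self.data.n
        if n <= max_size + 2:
            raise InsufficientDataError(f"n={n} too small for subsets of size {max_size}")
        G = self._gram
        yi = self._cont_index[child]
        pidx = np.array([self._cont_index[q] for q in pool], dtype=np.int64)
        yy = G[yi, yi]
        var_y = max(yy / n - (G[0, yi] / n) ** 2, 0.0)
        scale = max(1.0, var_y)
        tuples: list[tuple[str, ...]] = []
        bic_parts: list[np.ndarray] = []
        deg_parts: list[np.ndarray] = []
        log_n = math.log(n)
        for s in range(min(max_size, len(pool)) + 1):
            combos = list(itertools.combinations(range(len(pool)), s))
            C = np.array(combos, dtype=np.int64).reshape(len(combos), s)
            cols = np.concatenate(
                [np.zeros((len(C), 1), dtype=np.int64), pidx[C]], axis=1
            )
            A = G[cols[:, :, None], cols[:, None, :]]
            b = G[cols, yi]
            try:
                coef = np.linalg.solve(A, b[..., None])[..., 0]
            except np.linalg.LinAlgError:
                coef = np.empty_like(b)
                for i in range(len(C)):
                    try:
                        coef[i] = np.linalg.solve(A[i], b[i])
                    except np.linalg.LinAlgError:
                        coef[i] = np.linalg.lstsq(A[i], b[i], rcond=None)[0]
            rss = np.maximum(yy - np.einsum("bi,bi->b", b, coef), 0.0)
            deg = (rss / n) <= _DEGENERATE_REL_VAR * scale
            with np.errstate(divide="ignore"):
                loglik = -0.5 * n * (_LOG_2PI + np.log(rss / n) + 1.0)
            bic = loglik - 0.5 * (s + 2) * log_n
            bic[deg] = np.inf
            tuples.extend(tuple(pool[j] for j in combo) for combo in combos)
            bic_parts.append(bic)
            deg_parts.append(deg)
        return tuples, np.concatenate(bic_parts), np.concatenate(deg_parts)

    def __len__(self) -> int:
        return len(self._cache)


# kept as the spec-facing name for the cache-bearing object
ScoreCache = Scorer


def global_bic(
    dag: TypedDag, data: Dataset, scorer: Scorer | None = None, alpha: float = 1.0
) -> float:
    """Global network score: the sum of the per-node family BICs."""
    if set(dag.names) != set(data.names):
        raise InvalidArgumentError("dag nodes and data columns differ")
    scorer = scorer or Scorer(data, alpha=alpha)
    return float(
        sum(scorer.family_score(node, dag.parents(node)).bic for node in dag.names)
    )
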
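"""Filter-based feature selection: Relief-F, Pearson correlation,
neighborhood component analysis (diagonal), and term variance.

All four methods produce a :class:`FeatureRanking` — a descending-score
permutation of the feature indices — from which top-k subsets are taken.
Features are z-scored before selection by default (configurable); the class
coding is benign = 0, malignant = 1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist

from .io import FeatureTable


@dataclasses.dataclass
class FeatureRanking:
    """Ordered feature indices (best first) with their per-feature scores."""

    method: str
    order: np.ndarray  # permutation of 0..n_features-1
    scores: np.ndarray  # aligned to the input feature order

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if sorted(self.order.tolist()) != list(range(len(self.scores))):
            raise ValueError("order must be a permutation of the feature indices")
        ranked = self.scores[self.order]
        if np.any(np.diff(ranked) > 1e-12):
            raise ValueError("order must sort scores in descending order")


@dataclasses.dataclass
class SelectorConfig:
    """Tunables shared by the selectors.

    relief_m = None means "use every sample as a target", the choice that
    gives the most stable Relief-F weight estimates.  nca_regularization =
    None defaults to 1/n.
    """

    relief_k: int = 10
    relief_m: int | None = None
    nca_learning_rate: float = 0.1
    nca_iterations: int = 200
    nca_regularization: float | None = None
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relief_k < 1:
            raise ValueError("relief_k must be >= 1")


def _prepare(table: FeatureTable, standardize: bool) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(table.values, dtype=float)
    y = table.y
    if standardize:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    return x, y


def _ranking(method: str, scores: np.ndarray) -> FeatureRanking:
    order = np.argsort(-scores, kind="stable")  # score ties -> lower index first
    return FeatureRanking(method=method, order=order, scores=scores)


# --------------------------------------------------------------------------- #
# Relief-F
# --------------------------------------------------------------------------- #


def relief_f_rank(table: FeatureTable, cfg: SelectorConfig | None = None) -> FeatureRanking:
    """Two-class Relief-F.

    For each of m target instances the k nearest same-class hits and k
    nearest other-class misses (Euclidean distance) are found, and each
    feature's weight is raised by the miss differences and lowered by the
    hit differences:

        W[f] += (sum_miss diff - sum_hit diff) / (m * k),
        diff(f, a, b) = |a_f - b_f| / (max_f - min_f).

    A feature differing across classes but not within them maximizes the
    weight; constant features keep weight exactly 0.  Weights lie in [-1, 1].
    """
    cfg = cfg or SelectorConfig()
    x, y = _prepare(table, cfg.standardize)
    n, n_feat = x.shape
    for cls in (0, 1):
        if np.sum(y == cls) < 2:
            raise ValueError("Relief-F needs at least 2 samples per class")

    span = x.max(axis=0) - x.min(axis=0)
    span[span == 0] = 1.0  # constant feature: diff := 0 regardless

    rng = np.random.default_rng(cfg.seed)
    if cfg.relief_m is None or cfg.relief_m >= n:
        targets = np.arange(n)
    else:
        targets = rng.choice(n, size=cfg.relief_m, replace=False)
    m = len(targets)

    dist = cdist(x, x, metric="euclidean")
    weights = np.zeros(n_feat)
    for t in targets:
        same = (y == y[t])
        for is_hit in (True, False):
            pool = np.flatnonzero(same if is_hit else ~same)
            if is_hit:
                pool = pool[pool != t]
            k = min(cfg.relief_k, len(pool))
            # stable sort on distance: ties broken by sample index
            nearest = pool[np.argsort(dist[t, pool], kind="stable")[:k]]
            diffs = np.abs(x[nearest] - x[t]) / span  # (k, n_feat)
            contrib = diffs.sum(axis=0) / (m * cfg.relief_k)
            weights += -contrib if is_hit else contrib
    # the update rule bounds weights in [-1, 1]; clip float accumulation dust
    return _ranking("relief_f", np.clip(weights, -1.0, 1.0))


# --------------------------------------------------------------------------- #
# Pearson correlation
# --------------------------------------------------------------------------- #


def pearson_rank(table: FeatureTable, cfg: SelectorConfig | None = None) -> FeatureRanking:
    """Score = |Pearson r| between each feature and the 0/1 class coding.
    Zero-variance features score 0."""
    cfg = cfg or SelectorConfig()
    x, y = _prepare(table, cfg.standardize)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / denom
    scores = np.abs(np.where(denom > 0, r, 0.0))
    return _ranking("pearson", scores)


# --------------------------------------------------------------------------- #
# Neighborhood component analysis (diagonal)
# --------------------------------------------------------------------------- #


def nca_rank(table: FeatureTable, cfg: SelectorConfig | None = None) -> FeatureRanking:
    """Diagonal NCA feature weighting.

    Maximizes the expected leave-one-out correct-assignment probability
    under the soft-neighbor kernel exp(-d_w), d_w(a, b) = sum_f w_f^2
    (a_f - b_f)^2, minus an L2 penalty lambda * sum_f w_f^2, by plain
    gradient ascent from w = 1 for a fixed number of iterations.  Scores
    are the final squared weights.
    """
    cfg = cfg or SelectorConfig()
    x, y = _prepare(table, cfg.standardize)
    n, n_feat = x.shape
    for cls in (0, 1):
        if np.sum(y == cls) < 2:
            raise ValueError("NCA needs at least 2 samples per class")
    lam = cfg.nca_regularization if cfg.nca_regularization is not None else 1.0 / n
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)

    w = np.ones(n_feat)
    xsq = x**2
    for _ in range(cfg.nca_iterations):
        xw = x * w  # distances under diag(w^2)
        d = cdist(xw, xw, metric="sqeuclidean")
        np.fill_diagonal(d, np.inf)
        logits = -d
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        p_i = (p * same).sum(axis=1)

        # coefficient matrix of D_ikf = (x_if - x_kf)^2 in the gradient
        coeff = p_i[:, None] * p - p * same
        r = coeff.sum(axis=1)
        c = coeff.sum(axis=0)
        quad = r @ xsq + c @ xsq - 2.0 * np.einsum("if,if->f", x, coeff @ x)
        # explicit ascent on the neighbor term, implicit (proximal) step on
        # the L2 penalty: stable for arbitrarily large lambda
        w = (w + cfg.nca_learning_rate * 2.0 * w * quad) / (
            1.0 + 2.0 * cfg.nca_learning_rate * lam
        )
    return _ranking("nca", w**2)


# --------------------------------------------------------------------------- #
# Term variance
# --------------------------------------------------------------------------- #


def variance_rank(table: FeatureTable, cfg: SelectorConfig | None = None) -> FeatureRanking:
    """Sample variance of each feature after min-max scaling to [0, 1].
    The min-max step makes the ranking invariant to per-feature affine
    rescaling of the raw inputs; constant features score 0."""
    x = np.asarray(table.values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    scores = np.zeros(x.shape[1])
    live = span > 0
    scaled = (x[:, live] - lo[live]) / span[live]
    scores[live] = scaled.var(axis=0, ddof=1)
    return _ranking("term_variance", scores)


# --------------------------------------------------------------------------- #
# Dispatch + subsets
# --------------------------------------------------------------------------- #

RANKERS = {
    "relief_f": relief_f_rank,
    "pearson": pearson_rank,
    "nca": nca_rank,
    "term_variance": variance_rank,
}


def rank_features(
    table: FeatureTable, method: str, cfg: SelectorConfig | None = None
) -> FeatureRanking:
    try:
        ranker = RANKERS[method]
    except KeyError:
        raise ValueError(f"unknown selection method {method!r}") from None
    return ranker(table, cfg)


def select_top_k(ranking: FeatureRanking, k: int) -> np.ndarray:
    """The first k feature indices of the ranking (stable)."""
    if not 1 <= k <= len(ranking.order):
        raise ValueError(f"k must be in [1, {len(ranking.order)}]")
    return ranking.order[:k].copy()
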
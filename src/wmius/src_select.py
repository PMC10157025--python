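"""Sparse-representation feature ranking with bootstrap aggregation.

The selector treats the standardized feature columns as dictionary atoms
and represents the class-label vector (coded -1/+1) as a sparse linear
combination of them: an L1-penalized linear fit.  The absolute
representation coefficient of an atom is its importance in that fit.  The
fit is repeated on B bootstrap resamples of the rows (stratified by class
to protect the minority), and the per-feature importance index is the mean
absolute coefficient over the B iterations.  Features are ranked by this
index; the retention rule keeps the top fraction (default 20%) or a fixed
top-k.

The L1 penalty is chosen once per call from a regularization path on the
full data so that roughly ``target_density`` of the coefficients are
nonzero per fit; a greedy orthogonal-matching-pursuit solver is available
as an alternative representation engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, OrthogonalMatchingPursuit, lasso_path

from .errors import ConfigurationError, DegenerateLabelError


@dataclass
class SparsityConfig:
    """Representation-engine settings.

    target_density
        Desired fraction of nonzero coefficients per bootstrap fit; the L1
        penalty is picked from a one-time path fit to approach it.
    solver
        "lasso" (default) or "omp" (greedy matching pursuit, which uses
        ``target_density`` to set the atom budget directly).
    """

    target_density: float = 0.15
    solver: str = "lasso"


@dataclass
class ImportanceRanking:
    feature_names: list[str]
    importance: np.ndarray  # mean |coefficient| over bootstraps, >= 0
    rank: np.ndarray  # 1 = most important; permutation of 1..n
    n_bootstrap: int
    seed: int

    def order(self) -> np.ndarray:
        """Feature indices from most to least important."""
        return np.argsort(self.rank)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant columns carry no signal; leave centered
    return (X - mu) / sd


def _pick_alpha(Xz: np.ndarray, y: np.ndarray, target_density: float) -> float:
    """Alpha on the lasso path whose active set is closest to the target."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        alphas, coefs, _ = lasso_path(Xz, y, alphas=60)
    density = (np.abs(coefs) > 1e-12).mean(axis=0)
    return float(alphas[int(np.argmin(np.abs(density - target_density)))])


def rank_features(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 100,
    sparsity_cfg: SparsityConfig | None = None,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> ImportanceRanking:
    """Bootstrap-aggregated sparse-representation importance ranking.

    Parameters
    ----------
    X
        samples x features matrix.
    y
        Binary labels (0/1 or bool); coded -1/+1 internally.
    B
        Bootstrap iterations (default 100).
    """
    cfg = sparsity_cfg or SparsityConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int).ravel()
    n, p = X.shape
    classes = np.unique(y)
    if len(classes) != 2:
        raise DegenerateLabelError(f"need two classes, got {classes}")
    if min((y == c).sum() for c in classes) < 2:
        raise DegenerateLabelError("need at least 2 samples per class")
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    ycode = np.where(y == classes.max(), 1.0, -1.0)
    Xz = _standardize(X)
    # canonicalize row order with column-order-free keys, so importance is
    # invariant to row permutations and equivariant to column permutations
    row_sum = Xz.sum(axis=1)
    row_sq = (Xz**2).sum(axis=1)
    order = np.lexsort((row_sq, row_sum, ycode))
    Xz, ycode = Xz[order], ycode[order]

    n_atoms = max(1, int(round(cfg.target_density * p)))
    if cfg.solver == "lasso":
        alpha = _pick_alpha(Xz, ycode, cfg.target_density)
        model = Lasso(alpha=alpha, max_iter=10000, tol=1e-8)
    elif cfg.solver == "omp":
        if n_atoms > n:
            raise ConfigurationError(
                f"OMP atom budget {n_atoms} exceeds sample count {n}"
            )
        model = OrthogonalMatchingPursuit(n_nonzero_coefs=n_atoms)
    else:
        raise ConfigurationError(f"unknown solver {cfg.solver!r}")

    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(ycode > 0)
    idx_neg = np.flatnonzero(ycode < 0)
    importance = np.zeros(p)
    with warnings.catch_warnings():
        # coefficients are used only through |coef| at ~1e-6 resolution, so
        # a residual duality gap below that is immaterial
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(B):
            rows = np.concatenate(
                [
                    rng.choice(idx_pos, size=len(idx_pos), replace=True),
                    rng.choice(idx_neg, size=len(idx_neg), replace=True),
                ]
            )
            model.fit(Xz[rows], ycode[rows])
            importance += np.abs(model.coef_)
    importance /= B
    # descending importance, ties broken by ascending feature index
    order_desc = np.lexsort((np.arange(p), -importance))
    rank = np.empty(p, dtype=int)
    rank[order_desc] = np.arange(1, p + 1)
    names = feature_names if feature_names is not None else [f"f{i}" for i in range(p)]
    return ImportanceRanking(
        feature_names=list(names),
        importance=importance,
        rank=rank,
        n_bootstrap=B,
        seed=seed,
    )


def select_top(
    ranking: ImportanceRanking,
    fraction: float | None = None,
    k: int | None = None,
) -> np.ndarray:
    """Indices of the best-ranked features, in rank order.

    Exactly one of ``fraction`` (retain round(fraction * n)) or ``k`` must
    be given.  The 20%-of-350 rule yields 70 features; the 52-feature
    operating point is reached with ``k=52``.
    """
    if (fraction is None) == (k is None):
        raise ConfigurationError("give exactly one of fraction or k")
    n = len(ranking.rank)
    if fraction is not None:
        if not 0.0 < fraction <= 1.0:
            raise ConfigurationError(f"fraction {fraction} outside (0,1]")
        k = int(round(fraction * n))
    if not 1 <= k <= n:
        raise ConfigurationError(f"k={k} outside [1, {n}]")
    return ranking.order()[:k]
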
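"""Low-rank completion of the endpoint matrix by iterative soft-thresholded SVD.

The endpoint matrix is observed only where a drug was assayed. To obtain a
reduced-rank drug representation in the presence of that missingness we use
the soft-impute scheme: repeatedly fill the unobserved cells from the
current low-rank reconstruction, take an SVD, and shrink the singular
values by a soft threshold ``lambda``. The goal here is a stable low-rank
factorization ``D ~ U S V^t`` (drugs are subsequently represented by
``U S``), not imputation for its own sake.

Rank and ``lambda`` are chosen by an entry-holdout procedure: a random
fraction of the *observed* cells is hidden, every candidate pair is fitted,
and the pair with the lowest mean squared error on the hidden cells wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceWarning, InvalidInputError
from .matrices import EndpointMatrix

#: Operating point used for the full-scale endpoint screen in the original
#: analysis; kept as a documented default configuration for that data size.
FULL_SCALE_RANK = 246
FULL_SCALE_LAMBDA = 0.34


@dataclass
class Decomposition:
    """Truncated soft-thresholded SVD ``M ~ U diag(S) V^t``.

    ``U`` (rows x r) and ``V`` (cols x r) have orthonormal columns; ``S``
    is positive and non-increasing. ``lam`` records the soft threshold that
    produced ``S``.
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    rank: int
    lam: float = 0.0
    #: per-iteration value of 0.5*||observed residual||^2 + lam*||S||_*
    objective_trace: list[float] = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        r = self.rank
        if self.U.shape[1] != r or self.V.shape[1] != r or self.S.shape != (r,):
            raise InvalidInputError("inconsistent decomposition dimensions")
        if r > 0:
            if not (self.S > 0).all():
                raise InvalidInputError("singular values must be positive")
            if not (np.diff(self.S) <= 1e-12).all():
                raise InvalidInputError("singular values must be non-increasing")
            for M, name in ((self.U, "U"), (self.V, "V")):
                gram = M.T @ M
                if not np.allclose(gram, np.eye(r), atol=1e-8):
                    raise InvalidInputError(f"{name} columns are not orthonormal")

    def reconstruction(self) -> np.ndarray:
        return (self.U * self.S) @ self.V.T


@dataclass
class CvGrid:
    """Holdout cross-validation grid for rank/lambda selection."""

    ranks: list[int]
    lambdas: list[float]
    holdout_fraction: float = 0.05
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ranks or not self.lambdas:
            raise InvalidInputError("grid must be non-empty")
        if any(r < 1 for r in self.ranks):
            raise InvalidInputError("ranks must be >= 1")
        if not (0 < self.holdout_fraction < 0.5):
            raise InvalidInputError("holdout_fraction must lie in (0, 0.5)")


def _objective(values, mask, recon, lam, s) -> float:
    resid = np.where(mask, values - recon, 0.0)
    return 0.5 * float((resid**2).sum()) + lam * float(s.sum())


def soft_impute(
    M: EndpointMatrix,
    rank: int,
    lam: float,
    *,
    tol: float = 1e-5,
    max_iter: int = 500,
    init: str = "zero",
) -> Decomposition:
    """Soft-thresholded truncated SVD of a partially observed matrix.

    Unobserved entries start at 0 (``init='mean'`` uses column means of the
    observed cells instead) and are iteratively refilled from the current
    reconstruction. Each iteration shrinks singular values by ``lam`` and
    truncates to ``rank``; components whose shrunk value hits zero are
    dropped, so the returned rank can be smaller than requested.
    """
    n, m = M.shape
    if rank < 1 or rank > min(n, m):
        raise InvalidInputError(f"rank must lie in [1, {min(n, m)}]")
    if lam < 0:
        raise InvalidInputError("lambda must be >= 0")
    if (~M.mask).all(axis=0).any():
        j = int(np.flatnonzero((~M.mask).all(axis=0))[0])
        raise InvalidInputError(
            f"endpoint column {M.endpoint_ids[j]!r} has no observed entry"
        )
    mask = M.mask
    observed = M.filled(0.0)
    if init == "mean":
        col_means = np.nansum(M.values, axis=0) / mask.sum(axis=0)
        fill = np.broadcast_to(col_means, (n, m))
    elif init == "zero":
        fill = np.zeros((n, m))
    else:
        raise InvalidInputError(f"unknown init {init!r}")
    X = np.where(mask, observed, fill)

    prev_recon = None
    rel_change = np.inf
    trace: list[float] = []
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        s_shrunk = np.maximum(s - lam, 0.0)
        tiny = 1e-9 * max(s_shrunk[0], 1.0) if s_shrunk.size else 0.0
        r = int(min(rank, np.count_nonzero(s_shrunk > tiny)))
        recon = (U[:, :r] * s_shrunk[:r]) @ Vt[:r]
        trace.append(_objective(observed, mask, recon, lam, s_shrunk[:r]))
        if prev_recon is not None:
            denom = np.linalg.norm(prev_recon)
            rel_change = np.linalg.norm(recon - prev_recon) / max(denom, 1e-12)
            if rel_change < tol:
                prev_recon = recon
                break
        prev_recon = recon
        X = np.where(mask, observed, recon)
    else:
        warnings.warn(
            f"soft_impute stopped at max_iter={max_iter} "
            f"(last relative change {rel_change:.3g})",
            ConvergenceWarning,
        )

    U, s, Vt = np.linalg.svd(np.where(mask, observed, prev_recon), full_matrices=False)
    s_shrunk = np.maximum(s - lam, 0.0)
    tiny = 1e-9 * max(s_shrunk[0], 1.0) if s_shrunk.size else 0.0
    r = int(min(rank, np.count_nonzero(s_shrunk > tiny)))
    return Decomposition(
        U=U[:, :r], S=s_shrunk[:r], V=Vt[:r].T, rank=r, lam=lam,
        objective_trace=trace,
    )


def drug_factors(dec: Decomposition) -> np.ndarray:
    """Per-drug coordinates in the reduced space: ``U diag(S)``."""
    return dec.U * dec.S


def _draw_holdout(
    mask: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean matrix marking observed cells to hide; every row keeps >=1
    observed cell, redrawing up to 100 times."""
    obs_idx = np.flatnonzero(mask.ravel())
    n_hold = max(1, int(round(fraction * obs_idx.size)))
    for _ in range(100):
        chosen = rng.choice(obs_idx, size=n_hold, replace=False)
        hold = np.zeros(mask.size, dtype=bool)
        hold[chosen] = True
        hold = hold.reshape(mask.shape)
        if ((mask & ~hold).sum(axis=1) >= 1).all():
            return hold
    raise InvalidInputError(
        "could not draw a holdout leaving every drug with an observed entry"
    )


def cv_select(
    M: EndpointMatrix, grid: CvGrid
) -> tuple[int, float, pd.DataFrame]:
    """Choose (rank, lambda) by entry-holdout imputation error.

    For each repeat, a seeded random ``holdout_fraction`` of the observed
    cells is hidden; every grid pair is fitted on the remaining cells and
    scored by MSE on the hidden ones. Returns the pair minimizing the mean
    MSE plus the full per-repeat table.
    """
    rows = []
    for rep in range(grid.n_repeats):
        rng = np.random.default_rng([grid.seed, rep])
        hold = _draw_holdout(M.mask, grid.holdout_fraction, rng)
        train = EndpointMatrix(
            values=np.where(hold, np.nan, M.values),
            drug_ids=list(M.drug_ids),
            endpoint_ids=list(M.endpoint_ids),
        )
        truth = M.values[hold]
        for rank in grid.ranks:
            for lam in grid.lambdas:
                dec = soft_impute(train, rank=rank, lam=lam)
                mse = float(np.mean((dec.reconstruction()[hold] - truth) ** 2))
                rows.append(
                    {"repeat": rep, "rank": rank, "lam": lam, "mse": mse}
                )
    table = pd.DataFrame(rows)
    means = (
        table.groupby(["rank", "lam"], sort=False)["mse"].mean().reset_index()
    )
    best = means.loc[means["mse"].idxmin()]
    return int(best["rank"]), float(best["lam"]), table
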
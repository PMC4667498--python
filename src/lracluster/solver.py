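"""Nuclear-norm-regularized model fitting by singular value thresholding.

Minimizes ``L(Theta) + mu * ||Theta||_*`` where ``L`` is the stacked minus
log-likelihood over all omics blocks and ``||.||_*`` is the nuclear norm, by
alternating a gradient step with the singular value shrinkage operator
(the proximal map of the nuclear norm):

    Theta <- Theta - delta * grad L(Theta)
    Theta <- D_mu(Theta)

Instead of asking the user for the penalty weight ``mu``, the target rank
``r`` is the tuning parameter: at every iteration ``mu`` is set to the
(r+1)-th largest singular value of the post-gradient-step matrix, which
guarantees the shrunk matrix has rank at most ``r`` while perturbing the
retained components as little as possible.  Theta starts at zero; the
objective is convex, so the iteration is insensitive to initialization.

Model fit across ranks is summarized by the *explained variation*

    (LL_r - LL_0) / (LL_inf - LL_0)   in [0, 1],

where ``LL_0`` is the log-likelihood of the rank-0 model (Theta = 0) and
``LL_inf`` the saturated (unconstrained) optimum; the rank is chosen at the
elbow of this curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import scipy.sparse.linalg

from .likelihoods import (
    OmicsBlock,
    ParameterMatrix,
    null_log_likelihood,
    saturated_log_likelihood,
    stack_blocks,
    stacked_gradient,
    total_neg_log_likelihood,
)

__all__ = [
    "SolverConfig",
    "FitResult",
    "singular_value_shrink",
    "select_mu",
    "fit",
    "explained_variation",
    "scan_rank",
    "RankScanEntry",
]

# above this min(p, n), only the leading r+1 singular triplets are computed
_TRUNCATED_SVD_MIN_DIM = 200


@dataclass
class SolverConfig:
    """Settings for the shrinkage solver.

    Parameters
    ----------
    rank : int
        Target dimension r of the reduced subspace (the only model parameter).
    step : float
        Gradient step length delta. The default 0.5 lies at the bottom of the
        (0.5, 2) window with guaranteed convergence for unit-curvature losses;
        values outside [0.5, 2] trigger a warning.
    max_iter : int
        Iteration cap.
    tol : float
        Convergence threshold on the relative change of the penalized
        objective between iterations.
    svd_method : {"auto", "full", "truncated"}
        "auto" uses a truncated top-(r+1) SVD for large problems.
    verbose : bool
        Print the per-iteration objective and mu.
    """

    rank: int
    step: float = 0.5
    max_iter: int = 100
    tol: float = 1e-6
    svd_method: str = "auto"
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if not (0.5 <= self.step <= 2.0):
            warnings.warn(
                f"step {self.step} outside [0.5, 2], the window with "
                "guaranteed convergence",
                UserWarning,
            )
        if self.svd_method not in ("auto", "full", "truncated"):
            raise ValueError(f"unknown svd_method {self.svd_method!r}")


@dataclass
class FitResult:
    """Converged model state and diagnostics."""

    theta: ParameterMatrix
    objective_trace: np.ndarray  # penalized objective per iteration
    mu_trace: np.ndarray  # shrinkage threshold per iteration
    ev_trace: np.ndarray  # explained variation per iteration
    loglik: float  # -L(Theta*) at convergence, unpenalized
    explained_variation: float
    singular_values: np.ndarray  # top r+1 singular values of Theta*
    n_iter: int
    converged: bool
    rank: int = field(default=0)


def singular_value_shrink(M: np.ndarray, mu: float) -> np.ndarray:
    """Apply the singular value shrinkage operator D_mu to a matrix.

    Every singular value ``lam`` of ``M`` is replaced by ``lam - mu`` if
    ``lam > mu`` and by 0 otherwise, keeping the singular vectors. This is the
    proximal operator of ``mu * ||.||_*``.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix contains non-finite entries")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    try:
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise np.linalg.LinAlgError(f"SVD failed during shrinkage: {exc}") from exc
    keep = s > mu
    return (U[:, keep] * (s[keep] - mu)) @ Vt[keep]


def select_mu(singular_values: Sequence[float], rank: int) -> float:
    """Shrinkage threshold: the (rank+1)-th largest singular value, else 0.

    Ties (``sigma_r == sigma_{r+1}``) are allowed; the shrunk matrix may then
    have rank below ``rank``.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    s = np.asarray(singular_values, dtype=float)
    if s.size and (np.any(s < 0) or np.any(np.diff(s) > 1e-12 * max(s[0], 1.0))):
        raise ValueError("singular_values must be sorted descending and >= 0")
    if s.size <= rank:
        return 0.0
    mu = float(s[rank])
    if s.size and mu <= 1e-12 * max(float(s[0]), 1.0):
        return 0.0
    return mu


def _svd_for_shrink(M: np.ndarray, rank: int, method: str):
    """Leading singular triplets of M, enough to shrink with mu = sigma_{r+1}.

    Because mu is the (r+1)-th singular value, every retained component lies
    within the top r+1 triplets, so a truncated SVD is exact for this step.
    """
    k = rank + 1
    p, n = M.shape
    use_truncated = method == "truncated" or (
        method == "auto" and min(p, n) > _TRUNCATED_SVD_MIN_DIM and k < min(p, n)
    )
    if use_truncated and k < min(p, n):
        U, s, Vt = scipy.sparse.linalg.svds(M, k=k)
        order = np.argsort(s)[::-1]
        return U[:, order], s[order], Vt[order], True
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return U, s, Vt, False


def explained_variation(
    loglik_r: float, loglik_sat: float, loglik_null: float
) -> float:
    """Normalized likelihood gain of the rank-r model, in [0, 1].

    Returns ``(LL_r - LL_0) / (LL_inf - LL_0)``: 0 at the rank-0 anchor, 1 at
    saturation.  A degenerate denominator (constant data: the null model is
    already saturated) is defined as 1.
    """
    vals = (loglik_r, loglik_sat, loglik_null)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError(f"non-finite log-likelihood inputs: {vals}")
    denom = loglik_sat - loglik_null
    if denom <= 1e-12 * max(1.0, abs(loglik_sat)):
        return 1.0
    ev = (loglik_r - loglik_null) / denom
    if ev < -1e-6 or ev > 1 + 1e-6:
        raise ValueError(
            f"log-likelihood ordering violated: null={loglik_null}, "
            f"r={loglik_r}, sat={loglik_sat}"
        )
    return float(min(max(ev, 0.0), 1.0))


def fit(
    blocks: list[OmicsBlock],
    config: SolverConfig,
    callback=None,
) -> FitResult:
    """Fit the low-rank model to sample-aligned omics blocks.

    Iterates gradient steps on the stacked likelihood and singular value
    shrinkage with the rank-adaptive threshold until the relative change of
    the penalized objective drops below ``config.tol``.  If given,
    ``callback(iteration, theta)`` is invoked after every shrinkage step.
    """
    pm = stack_blocks(blocks)
    p, n = pm.theta.shape
    if config.rank > min(p, n):
        raise ValueError(
            f"rank {config.rank} exceeds min(features, samples) = {min(p, n)}"
        )

    loglik_sat = sum(saturated_log_likelihood(b) for b in blocks)
    loglik_null = sum(null_log_likelihood(b) for b in blocks)

    objective_trace: list[float] = []
    mu_trace: list[float] = []
    ev_trace: list[float] = []
    converged = False
    n_iter = 0
    s_shrunk = np.zeros(config.rank + 1)

    for it in range(config.max_iter):
        grad = stacked_gradient(blocks, pm)
        M = pm.theta - config.step * grad
        U, s, Vt, _ = _svd_for_shrink(M, config.rank, config.svd_method)
        mu = select_mu(s, config.rank)
        keep = s > mu
        pm.theta = (U[:, keep] * (s[keep] - mu)) @ Vt[keep]

        nll = total_neg_log_likelihood(blocks, pm)
        shrunk = np.maximum(s - mu, 0.0)
        obj = nll + mu * float(shrunk.sum())
        s_shrunk = np.sort(shrunk)[::-1][: config.rank + 1]

        objective_trace.append(obj)
        mu_trace.append(mu)
        ev_trace.append(explained_variation(-nll, loglik_sat, loglik_null))
        n_iter = it + 1
        if callback is not None:
            callback(n_iter, pm.theta)
        if config.verbose:
            print(f"iter {n_iter:4d}  obj {obj:.6e}  mu {mu:.4e}")
        if it > 0:
            prev = objective_trace[-2]
            if abs(obj - prev) / max(1.0, abs(prev)) < config.tol:
                converged = True
                break

    loglik = -total_neg_log_likelihood(blocks, pm)
    if not converged:
        warnings.warn(
            f"solver did not reach tol={config.tol} within "
            f"{config.max_iter} iterations",
            UserWarning,
        )
    if len(s_shrunk) < config.rank + 1:
        s_shrunk = np.pad(s_shrunk, (0, config.rank + 1 - len(s_shrunk)))
    return FitResult(
        theta=pm,
        objective_trace=np.asarray(objective_trace),
        mu_trace=np.asarray(mu_trace),
        ev_trace=np.asarray(ev_trace),
        loglik=loglik,
        explained_variation=explained_variation(loglik, loglik_sat, loglik_null),
        singular_values=s_shrunk,
        n_iter=n_iter,
        converged=converged,
        rank=config.rank,
    )


class RankScanEntry(NamedTuple):
    rank: int
    explained_variation: float
    loglik: float


def scan_rank(
    blocks: list[OmicsBlock],
    ranks: Sequence[int],
    config: SolverConfig | None = None,
    **config_kwargs,
) -> list[RankScanEntry]:
    """Fit once per rank and return the explained-variation curve.

    The curve is meant for elbow inspection: the sensible rank is where the
    gain in explained variation flattens.  No automatic elbow detection is
    applied here; see :func:`elbow_rank` for the max-curvature heuristic.
    """
    ranks = list(ranks)
    if any(r < 1 for r in ranks):
        raise ValueError("ranks must be positive")
    if sorted(ranks) != ranks:
        raise ValueError("ranks must be sorted ascending")
    out = []
    for r in ranks:
        if config is not None:
            cfg = SolverConfig(
                rank=r,
                step=config.step,
                max_iter=config.max_iter,
                tol=config.tol,
                svd_method=config.svd_method,
                verbose=config.verbose,
            )
        else:
            cfg = SolverConfig(rank=r, **config_kwargs)
        try:
            res = fit(blocks, cfg)
        except Exception as exc:
            raise RuntimeError(f"fit failed at rank {r}: {exc}") from exc
        out.append(RankScanEntry(r, res.explained_variation, res.loglik))
    return out


def elbow_rank(curve: Sequence[RankScanEntry]) -> int:
    """Max-curvature elbow of an explained-variation curve over ranks 1..R.

    Prepends the exact rank-0 anchor (explained variation 0) and returns the
    rank with the most negative discrete second difference, i.e. where the
    curve bends hardest from rising to flat.  Requires a contiguous scan
    starting at rank 1 with at least two ranks.
    """
    ranks = [e.rank for e in curve]
    if ranks != list(range(1, len(ranks) + 1)) or len(ranks) < 2:
        raise ValueError("elbow detection needs a contiguous scan 1..R, R >= 2")
    ev = np.concatenate([[0.0], [e.explained_variation for e in curve]])
    second = ev[:-2] - 2.0 * ev[1:-1] + ev[2:]  # at ranks 1..R-1
    return int(np.argmin(second)) + 1
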
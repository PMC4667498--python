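"""Per-data-type probabilistic models for multi-omics blocks.

Each observed matrix entry ``X_ij`` is a random variable conditional on a
matching natural parameter ``theta_ij``.  Three exponential-family models are
supported, keyed by the block's ``dtype``:

``gaussian``
    ``X ~ N(theta, 1)`` — continuous values such as copy-number log ratios or
    methylation levels; minus log density (constants dropped)
    ``(1/2)(X - theta)^2``.
``binary``
    ``X ~ Bernoulli(sigma(theta))`` with the logistic link — e.g. somatic
    mutation indicators; minus log mass ``ln(1 + e^theta) - X*theta``.
``poisson``
    ``X ~ Poisson(e^theta)`` — non-negative counts such as normalized RNA-seq
    counts; minus log mass (dropping ``ln X!``) ``e^theta - X*theta``.

Normalization constants that do not depend on ``theta`` are dropped
consistently; the saturated/null anchors below use the same convention, so
quantities normalized between them (explained variation) are unaffected.

Missing observations are marginalized out: a masked entry contributes zero to
every likelihood value and gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "DTYPES",
    "OmicsBlock",
    "ParameterMatrix",
    "neg_log_likelihood",
    "gradient",
    "saturated_log_likelihood",
    "null_log_likelihood",
    "dummy_encode",
    "stack_blocks",
    "total_neg_log_likelihood",
    "stacked_gradient",
]

DTYPES = ("gaussian", "binary", "poisson")

# Beyond this value of theta, exp(theta) overflows float64 headroom long
# before; the solver keeps theta moderate, so hitting the clip is a symptom.
_POISSON_THETA_CLIP = 50.0


def _as_2d_float(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {a.shape}")
    return a


@dataclass
class OmicsBlock:
    """One feature-by-sample omics matrix with its data-type tag.

    Parameters
    ----------
    name : str
        Label for the block (e.g. ``"expression"``).
    data : (p, n) ndarray
        Observations, features in rows and samples in columns.
    dtype : {"gaussian", "binary", "poisson"}
        Observation model.
    mask : (p, n) bool ndarray, optional
        True where the observation is present. Defaults to all present.
        Masked entries of ``data`` are ignored (may hold NaN).
    feature_ids, sample_ids : sequence of str, optional
        Row / column labels; generated if omitted.
    """

    name: str
    data: np.ndarray
    dtype: str
    mask: np.ndarray | None = None
    feature_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = _as_2d_float(self.data, "data")
        if self.dtype not in DTYPES:
            raise ValueError(f"dtype must be one of {DTYPES}, got {self.dtype!r}")
        p, n = self.data.shape
        if self.mask is None:
            self.mask = ~np.isnan(self.data)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != data shape {self.data.shape}"
                )
        if not self.feature_ids:
            self.feature_ids = [f"{self.name}_f{i}" for i in range(p)]
        if not self.sample_ids:
            self.sample_ids = [f"S{j}" for j in range(n)]
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length does not match row count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match column count")

        vals = self.data[self.mask]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"block {self.name!r}: non-finite unmasked entries")
        if self.dtype == "binary" and not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError(f"block {self.name!r}: binary entries must be 0 or 1")
        if self.dtype == "poisson":
            if (vals < 0).any() or not np.array_equal(vals, np.round(vals)):
                raise ValueError(
                    f"block {self.name!r}: poisson entries must be "
                    "non-negative integers"
                )

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ParameterMatrix:
    """Stacked natural-parameter matrix Theta with per-block row ranges.

    ``theta`` vertically concatenates one parameter block per omics block, in
    block order; ``block_offsets`` maps block names to ``(start, stop)`` row
    ranges.  The column order is the shared sample order.
    """

    theta: np.ndarray
    block_offsets: dict[str, tuple[int, int]]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theta = _as_2d_float(self.theta, "theta")
        stops = sorted(self.block_offsets.values())
        covered = 0
        for start, stop in stops:
            if start != covered or stop <= start:
                raise ValueError("block_offsets must be contiguous and disjoint")
            covered = stop
        if covered != self.theta.shape[0]:
            raise ValueError("block_offsets do not cover every row of theta")
        if self.sample_ids and len(self.sample_ids) != self.theta.shape[1]:
            raise ValueError("sample_ids length does not match column count")

    def block_view(self, name: str) -> np.ndarray:
        """Row slice of ``theta`` belonging to the named block (a view)."""
        start, stop = self.block_offsets[name]
        return self.theta[start:stop]


def _check_theta(block: OmicsBlock, theta_block: np.ndarray) -> np.ndarray:
    theta_block = _as_2d_float(theta_block, "theta_block")
    if theta_block.shape != block.data.shape:
        raise ValueError(
            f"theta shape {theta_block.shape} != data shape {block.data.shape}"
        )
    if not np.all(np.isfinite(theta_block)):
        raise ValueError("theta contains non-finite entries")
    return theta_block


def _safe_exp(theta: np.ndarray) -> np.ndarray:
    if np.any(theta > _POISSON_THETA_CLIP):
        warnings.warn(
            "poisson natural parameter exceeds %.0f; clipping exp(theta)"
            % _POISSON_THETA_CLIP,
            RuntimeWarning,
            stacklevel=3,
        )
        theta = np.minimum(theta, _POISSON_THETA_CLIP)
    return np.exp(theta)


def neg_log_likelihood(block: OmicsBlock, theta_block: np.ndarray) -> float:
    """Minus log-likelihood of one block, constants dropped, masked entries 0."""
    theta = _check_theta(block, theta_block)
    x = np.where(block.mask, block.data, 0.0)
    if block.dtype == "gaussian":
        terms = 0.5 * (x - theta) ** 2
    elif block.dtype == "binary":
        # ln(1 + e^t) - x t, computed stably via logaddexp
        terms = np.logaddexp(0.0, theta) - x * theta
    else:  # poisson
        terms = _safe_exp(theta) - x * theta
    return float(np.where(block.mask, terms, 0.0).sum())


def gradient(block: OmicsBlock, theta_block: np.ndarray) -> np.ndarray:
    """Entry-wise d/dtheta of :func:`neg_log_likelihood`; zero where masked."""
    theta = _check_theta(block, theta_block)
    x = np.where(block.mask, block.data, 0.0)
    if block.dtype == "gaussian":
        g = theta - x
    elif block.dtype == "binary":
        g = expit(theta) - x
    else:
        g = _safe_exp(theta) - x
    return np.where(block.mask, g, 0.0)


def saturated_log_likelihood(block: OmicsBlock) -> float:
    """Unconstrained maximum of the (constant-dropped) log-likelihood.

    Entry-wise optima: gaussian 0 at theta = X; binary 0 in the limit
    theta -> +/- inf matching X; poisson ``X ln X - X`` at theta = ln X for
    X > 0 and 0 in the limit theta -> -inf for X = 0.
    """
    if block.dtype in ("gaussian", "binary"):
        return 0.0
    x = np.where(block.mask, block.data, 0.0)
    pos = x > 0
    terms = np.where(pos, x * np.log(np.where(pos, x, 1.0)) - x, 0.0)
    return float(np.where(block.mask, terms, 0.0).sum())


def null_log_likelihood(block: OmicsBlock) -> float:
    """Log-likelihood at theta = 0 (the rank-0 model), masked entries excluded."""
    n_obs = int(block.mask.sum())
    if block.dtype == "gaussian":
        x = np.where(block.mask, block.data, 0.0)
        return float(-0.5 * (x**2).sum())
    if block.dtype == "binary":
        return -n_obs * float(np.log(2.0))
    return -float(n_obs)  # poisson: each entry contributes 0 - e^0


def dummy_encode(
    categorical_matrix,
    levels,
    name: str = "categorical",
    feature_ids=None,
    sample_ids=None,
    mask=None,
) -> OmicsBlock:
    """One-hot encode a categorical feature-by-sample matrix as a binary block.

    Each input feature becomes ``len(levels)`` binary rows (full one-hot, no
    reference level dropped — levels stay symmetric under the low-rank prior).
    Derived feature ids are ``"<feature>:<level>"``.  A masked input entry
    masks all derived rows at that sample.
    """
    cat = np.asarray(categorical_matrix, dtype=object)
    if cat.ndim != 2:
        raise ValueError("categorical_matrix must be 2-dimensional")
    p, n = cat.shape
    levels = list(levels)
    if mask is None:
        mask = np.ones((p, n), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != cat.shape:
            raise ValueError("mask shape does not match categorical_matrix")
    if feature_ids is None:
        feature_ids = [f"{name}_f{i}" for i in range(p)]

    level_index = {lev: k for k, lev in enumerate(levels)}
    data = np.zeros((p * len(levels), n))
    out_mask = np.zeros((p * len(levels), n), dtype=bool)
    out_ids = []
    for i in range(p):
        for k, lev in enumerate(levels):
            out_ids.append(f"{feature_ids[i]}:{lev}")
        for j in range(n):
            if not mask[i, j]:
                continue
            entry = cat[i, j]
            if entry not in level_index:
                raise ValueError(
                    f"entry {entry!r} at ({feature_ids[i]}, column {j}) "
                    f"not in levels {levels}"
                )
            rows = slice(i * len(levels), (i + 1) * len(levels))
            out_mask[rows, j] = True
            data[i * len(levels) + level_index[entry], j] = 1.0
    return OmicsBlock(
        name=name,
        data=data,
        dtype="binary",
        mask=out_mask,
        feature_ids=out_ids,
        sample_ids=list(sample_ids) if sample_ids is not None else [],
    )


def _validate_aligned(blocks: list[OmicsBlock]) -> None:
    if not blocks:
        raise ValueError("need at least one block")
    ref = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ref:
            raise ValueError(
                f"block {b.name!r} sample ids differ from block "
                f"{blocks[0].name!r}; align the blocks first"
            )


def stack_blocks(blocks: list[OmicsBlock]) -> ParameterMatrix:
    """Zero-initialized stacked parameter matrix for sample-aligned blocks."""
    _validate_aligned(blocks)
    offsets: dict[str, tuple[int, int]] = {}
    row = 0
    for b in blocks:
        if b.name in offsets:
            raise ValueError(f"duplicate block name {b.name!r}")
        offsets[b.name] = (row, row + b.n_features)
        row += b.n_features
    theta = np.zeros((row, blocks[0].n_samples))
    return ParameterMatrix(theta, offsets, list(blocks[0].sample_ids))


def total_neg_log_likelihood(blocks: list[OmicsBlock], pm: ParameterMatrix) -> float:
    """Stacked minus log-likelihood: the sum over blocks."""
    return sum(neg_log_likelihood(b, pm.block_view(b.name)) for b in blocks)


def stacked_gradient(blocks: list[OmicsBlock], pm: ParameterMatrix) -> np.ndarray:
    """Gradient of the stacked minus log-likelihood w.r.t. the full theta."""
    return np.vstack([gradient(b, pm.block_view(b.name)) for b in blocks])
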
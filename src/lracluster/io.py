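"""Delimited-matrix input/output, sample alignment and the pipeline driver.

Matrices are feature-by-sample delimited text: first row sample ids, first
column feature ids.  ``NA`` or empty cells are treated as missing and enter
the block's mask.  The end-to-end :func:`run_pipeline` writes every result
as TSV plus a JSON config/provenance sidecar so a run can be reproduced from
its own output directory.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .likelihoods import DTYPES, OmicsBlock
from .reduce_cluster import (
    best_k,
    kmeans_cluster,
    reduce,
    scan_clusters,
    signature_features,
)
from .solver import SolverConfig, elbow_rank, fit, scan_rank

__all__ = ["RunConfig", "read_block", "write_block", "align_samples", "run_pipeline"]

logger = logging.getLogger("lracluster")

_NA_STRINGS = {"", "NA", "NaN", "nan"}


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_block(
    path,
    dtype: str,
    delimiter: str | None = None,
    name: str | None = None,
    transpose: bool = False,
) -> OmicsBlock:
    """Read one feature-by-sample matrix as an :class:`OmicsBlock`.

    ``NA``/empty cells become masked entries.  Binary blocks must contain
    only 0/1, poisson blocks only non-negative integers; violations are
    reported with the offending feature and sample.
    """
    path = Path(path)
    if dtype not in DTYPES:
        raise ValueError(f"dtype must be one of {DTYPES}, got {dtype!r}")
    df = pd.read_csv(
        path,
        sep=_delimiter_for(path, delimiter),
        index_col=0,
        na_values=list(_NA_STRINGS),
        keep_default_na=False,
        dtype=str,
    )
    if transpose:
        df = df.T
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate feature ids {dups[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {df.iat[i, j]!r} at feature "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    data = numeric.to_numpy(dtype=float)
    mask = ~np.isnan(data)
    try:
        return OmicsBlock(
            name=name or path.stem,
            data=data,
            dtype=dtype,
            mask=mask,
            feature_ids=[str(f) for f in df.index],
            sample_ids=[str(s) for s in df.columns],
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_block(block: OmicsBlock, path, delimiter: str | None = None) -> None:
    """Write a block back to delimited text; masked entries become ``NA``."""
    path = Path(path)
    data = block.data.astype(object)
    vals = np.where(block.mask, data, "NA")
    df = pd.DataFrame(vals, index=block.feature_ids, columns=block.sample_ids)
    df.to_csv(path, sep=_delimiter_for(path, delimiter))


def align_samples(blocks: list[OmicsBlock], policy: str = "strict") -> list[OmicsBlock]:
    """Bring every block onto one shared, identically ordered sample set.

    ``strict`` requires identical sample id sets (any order) and reorders all
    blocks to the first block's order; ``intersect`` subsets every block to
    the sorted common sample set, logging what was dropped.
    """
    if not blocks:
        raise ValueError("need at least one block")
    if policy not in ("strict", "intersect"):
        raise ValueError(f"unknown policy {policy!r}")
    sets = [set(b.sample_ids) for b in blocks]
    common = set.intersection(*sets)
    if policy == "strict":
        for b, s in zip(blocks, sets):
            if s != sets[0]:
                raise ValueError(
                    f"sample sets differ (block {b.name!r}); use policy="
                    "'intersect' to take the common subset"
                )
        order = list(blocks[0].sample_ids)
    else:
        if not common:
            raise ValueError("sample sets have an empty intersection")
        order = sorted(common)
        for b, s in zip(blocks, sets):
            dropped = sorted(s - common)
            if dropped:
                logger.info("block %r: dropping %d samples", b.name, len(dropped))
    out = []
    for b in blocks:
        idx = [b.sample_ids.index(sid) for sid in order]
        out.append(
            OmicsBlock(
                name=b.name,
                data=b.data[:, idx],
                dtype=b.dtype,
                mask=b.mask[:, idx],
                feature_ids=list(b.feature_ids),
                sample_ids=order,
            )
        )
    return out


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    block_paths: list[str]
    block_dtypes: list[str]
    output_dir: str
    rank: int | None = None
    rank_scan: list[int] = field(default_factory=list)
    cluster_scan: list[int] = field(default_factory=lambda: list(range(2, 7)))
    step: float = 0.5
    tol: float = 1e-6
    max_iter: int = 100
    restarts: int = 20
    seed: int = 0
    align_policy: str = "strict"
    delimiter: str | None = None
    transpose: bool = False
    signatures: bool = True

    def __post_init__(self) -> None:
        if not self.block_paths:
            raise ValueError("need at least one block path")
        if len(self.block_paths) != len(self.block_dtypes):
            raise ValueError("block_paths and block_dtypes lengths differ")
        for d in self.block_dtypes:
            if d not in DTYPES:
                raise ValueError(f"unknown dtype {d!r}")
        if self.rank is None and not self.rank_scan:
            raise ValueError("give either a rank or a rank-scan range")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> Path:
    """Read -> align -> fit (or rank scan) -> reduce -> cluster -> signatures.

    Writes, under ``config.output_dir``: the verbatim config and a run log,
    per-iteration fit diagnostics (objective, mu, explained variation),
    the rank-scan curve when requested, sample coordinates, the silhouette
    curve, cluster labels at the recommended k, and per-cluster signature
    tables.  Returns the output directory path.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info(
            "lracluster %s | python %s | numpy %s",
            __version__,
            sys.version.split()[0],
            np.__version__,
        )
        logger.info("config: %s", json.dumps(asdict(config)))
        (out / "config.json").write_text(json.dumps(asdict(config), indent=2))

        read = _stage("read")(
            lambda: [
                read_block(p, d, config.delimiter, transpose=config.transpose)
                for p, d in zip(config.block_paths, config.block_dtypes)
            ]
        )
        blocks = read()
        blocks = _stage("align")(align_samples)(blocks, config.align_policy)
        logger.info(
            "blocks: %s",
            ", ".join(f"{b.name}({b.dtype} {b.n_features}x{b.n_samples})" for b in blocks),
        )

        solver_kwargs = dict(step=config.step, tol=config.tol, max_iter=config.max_iter)
        rank = config.rank
        if config.rank_scan:
            curve = _stage("rank-scan")(scan_rank)(
                blocks, sorted(config.rank_scan), **solver_kwargs
            )
            pd.DataFrame(curve).to_csv(out / "rank_scan.tsv", sep="\t", index=False)
            if rank is None:
                rank = elbow_rank(curve)
                logger.info("elbow rank: %d", rank)

        cfg = SolverConfig(rank=rank, **solver_kwargs)
        res = _stage("fit")(fit)(blocks, cfg)
        logger.info(
            "fit: %d iterations, converged=%s, explained variation %.4f",
            res.n_iter,
            res.converged,
            res.explained_variation,
        )
        pd.DataFrame(
            {
                "iteration": np.arange(1, res.n_iter + 1),
                "objective": res.objective_trace,
                "mu": res.mu_trace,
                "explained_variation": res.ev_trace,
            }
        ).to_csv(out / "fit_trace.tsv", sep="\t", index=False)

        rep = _stage("reduce")(reduce)(res.theta, rank)
        pd.DataFrame(
            rep.coords.T,
            index=rep.sample_ids,
            columns=[f"dim{i+1}" for i in range(rep.rank)],
        ).to_csv(out / "coordinates.tsv", sep="\t", index_label="sample")

        ks = [k for k in config.cluster_scan if k <= rep.n_samples]
        curve_k = _stage("cluster-scan")(scan_clusters)(
            rep, ks, config.restarts, config.seed
        )
        pd.DataFrame(
            [(e.k, e.silhouette) for e in curve_k], columns=["k", "silhouette"]
        ).to_csv(out / "silhouette_scan.tsv", sep="\t", index=False)
        k = best_k(curve_k)
        cres = next(e.result for e in curve_k if e.k == k)
        logger.info("chosen k: %d (silhouette %.4f)", k, cres.silhouette)
        pd.DataFrame(
            {
                "sample": rep.sample_ids,
                "cluster": cres.labels,
                "silhouette": cres.per_sample_silhouette,
            }
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)

        if config.signatures:
            sig = _stage("signatures")(
                lambda: {
                    c: signature_features(blocks, cres.labels, c)
                    for c in range(1, k + 1)
                }
            )()
            for c, table in sig.items():
                table.to_csv(out / f"signatures_cluster{c}.tsv", sep="\t", index=False)

        summary = {
            "rank": rank,
            "k": k,
            "silhouette": cres.silhouette,
            "explained_variation": res.explained_variation,
            "n_iter": res.n_iter,
            "converged": bool(res.converged),
            "seed": config.seed,
            "version": __version__,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
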
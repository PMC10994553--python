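"""Omics-block data model and preprocessing.

The pipeline expects abundance matrices on log2 scale with unit-variance
scaled columns. Standardization has explicit fit/apply semantics so that
held-out data is always scaled with training-set parameters (no leakage).
Missing values are filled by iterative low-rank (SVD) imputation on the
log scale, before standardization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("pathblend")

__all__ = [
    "OmicsBlock",
    "Standardizer",
    "OutcomeVector",
    "read_abundance_table",
    "write_abundance_table",
    "log2_transform",
    "fit_standardizer",
    "apply_standardizer",
    "svd_impute",
    "filter_low_variance",
    "align_blocks",
]


@dataclass
class OmicsBlock:
    """One samples-by-molecules abundance matrix.

    `data` holds the values with sample ids as index and molecule
    identifiers as columns. Flags record where the block sits in the
    preprocessing sequence.
    """

    data: pd.DataFrame
    omics_label: str = ""
    is_log_scale: bool = False
    is_standardized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "OmicsBlock":
        return replace(self, data=self.data.loc[list(sample_ids)])


@dataclass
class Standardizer:
    """Per-feature mean/sd learned from a fitting set (n-1 sd convention)."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        bad = self.sd.index[~(self.sd > 0)].tolist()
        if bad:
            raise ValueError(f"zero-variance features at fit: {bad[:10]}")


@dataclass
class OutcomeVector:
    """Outcome y aligned to the blocks' samples; binary or continuous."""

    values: pd.Series
    binary: bool = True

    def __post_init__(self) -> None:
        if self.binary:
            levels = pd.unique(self.values)
            if len(levels) != 2:
                raise ValueError(
                    f"binary outcome must have exactly 2 levels, got {len(levels)}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def encoded(self) -> np.ndarray:
        """Numeric encoding: binary outcomes as {0,1} (levels sorted)."""
        if self.binary:
            levels = sorted(pd.unique(self.values))
            return (self.values == levels[1]).to_numpy(dtype=float)
        return self.values.to_numpy(dtype=float)

    def subset(self, sample_ids) -> "OutcomeVector":
        return OutcomeVector(values=self.values.loc[list(sample_ids)], binary=self.binary)


# ---------------------------------------------------------------- file I/O


def read_abundance_table(path, omics_label: str = "", **flags) -> OmicsBlock:
    """Read a delimited abundance table: first column sample id, header row
    feature ids. Delimiter auto-detected among tab/comma."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return OmicsBlock(data=df, omics_label=omics_label or str(path), **flags)


def write_abundance_table(block: OmicsBlock, path, sep: str = "\t") -> None:
    block.data.to_csv(path, sep=sep)


# ------------------------------------------------------------- transforms


def log2_transform(block: OmicsBlock) -> OmicsBlock:
    if block.is_log_scale:
        raise ValueError("block is already on log scale")
    vals = block.values
    nonpos = block.data.columns[(vals <= 0).any(axis=0)].tolist()
    if nonpos:
        raise ValueError(f"non-positive values in features: {nonpos[:10]}")
    return replace(
        block,
        data=pd.DataFrame(
            np.log2(vals), index=block.data.index, columns=block.data.columns
        ),
        is_log_scale=True,
    )


def fit_standardizer(block: OmicsBlock) -> Standardizer:
    if block.n_samples < 2:
        raise ValueError("need >= 2 samples to fit a standardizer")
    mean = block.data.mean(axis=0)
    sd = block.data.std(axis=0, ddof=1)
    return Standardizer(mean=mean, sd=sd)


def apply_standardizer(std: Standardizer, block: OmicsBlock) -> OmicsBlock:
    missing = [f for f in std.mean.index if f not in block.data.columns]
    if missing:
        raise ValueError(f"block lacks fitted features: {missing[:10]}")
    data = (block.data[std.mean.index] - std.mean) / std.sd
    return replace(block, data=data, is_standardized=True)


def svd_impute(
    block: OmicsBlock,
    rank: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> OmicsBlock:
    """Fill missing entries by iterative low-rank SVD reconstruction.

    Missing entries are initialised at column means, then repeatedly
    replaced by the rank-`rank` truncated-SVD reconstruction until
    successive imputations differ by less than `tol` in relative
    Frobenius norm. Observed entries are never altered.
    """
    X = block.values.copy()
    mask = np.isnan(X)
    if not mask.any():
        return block
    n, m = X.shape
    if mask.all(axis=0).any():
        bad = block.data.columns[mask.all(axis=0)].tolist()
        raise ValueError(f"all-missing features: {bad[:10]}")
    if mask.all(axis=1).any():
        raise ValueError("some samples have no observed values")
    if rank is None:
        rank = min(10, n - 1, m - 1)
    if rank >= min(n, m):
        raise ValueError(f"rank {rank} must be < min(N, M) = {min(n, m)}")

    col_means = np.nanmean(X, axis=0)
    filled = X.copy()
    filled[mask] = np.take(col_means, np.nonzero(mask)[1])
    for _ in range(max_iter):
        u, s, vt = np.linalg.svd(filled, full_matrices=False)
        recon = (u[:, :rank] * s[:rank]) @ vt[:rank]
        new = X.copy()
        new[mask] = recon[mask]
        denom = max(np.linalg.norm(filled[mask]), 1e-12)
        delta = np.linalg.norm(new[mask] - filled[mask]) / denom
        filled = new
        if delta < tol:
            break
    else:
        warnings.warn(
            f"svd_impute did not converge in {max_iter} iterations", stacklevel=2
        )
    return replace(
        block,
        data=pd.DataFrame(filled, index=block.data.index, columns=block.data.columns),
    )


def filter_low_variance(block: OmicsBlock, percentile: float) -> OmicsBlock:
    """Drop features whose variance falls below the given percentile of
    the per-feature variance distribution."""
    if not 0 <= percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    if percentile == 0:
        return block
    var = block.data.var(axis=0, ddof=1)
    cutoff = np.percentile(var.to_numpy(), percentile)
    keep = block.data.columns[var.to_numpy() >= cutoff]
    return replace(block, data=block.data[keep])


def align_blocks(
    blocks: list[OmicsBlock], y: OutcomeVector | None = None
) -> tuple[list[OmicsBlock], OutcomeVector | None]:
    """Intersect samples across blocks (and y), order from the first block.

    Samples missing from any block are dropped with a logged count: the
    models require every omics to be measured on the same individuals.
    """
    common = set(blocks[0].sample_ids)
    for b in blocks[1:]:
        common &= set(b.sample_ids)
    if y is not None:
        common &= set(y.sample_ids)
    order = [s for s in blocks[0].sample_ids if s in common]
    dropped = len(blocks[0].sample_ids) - len(order)
    if dropped:
        logger.info("align_blocks: dropped %d samples missing from some block", dropped)
    out = [b.subset_samples(order) for b in blocks]
    return out, (y.subset(order) if y is not None else None)
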
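"""Mid-level MS-NMR data fusion by SD-sum block scaling.

Each instrument block (samples x variables) is scaled by the sum of its
per-variable standard deviations so that neither block dominates the fused
matrix: s_j = SD of variable j across samples, S = sum_j s_j, and every cell
is divided by S.  After scaling the per-variable SDs of a block sum to one,
so both blocks contribute equal total variation to the concatenated matrix.

Two auxiliary single-matrix filters used by the web-platform re-analysis
recipe are provided: row sum-normalization and a mean-intensity variable
filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateInputError


@dataclass
class Block:
    """One instrument's samples x variables matrix."""

    data: pd.DataFrame  # rows: samples, columns: variable ids
    block_id: str  # "MS" or "NMR"

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError(f"block {self.block_id} contains missing cells")
        if len(self.data) < 2:
            raise ValueError("a block needs >= 2 samples for SDs to be defined")


@dataclass
class FusedMatrix:
    """Column-concatenated scaled blocks with per-column block membership."""

    data: pd.DataFrame
    block_ids: pd.Series  # one block label per column
    scale_factors: dict[str, float]  # block id -> S (sum of raw per-variable SDs)


def block_scale(block: Block, ddof: int = 1) -> tuple[Block, float]:
    """Divide every cell of a block by the sum S of its per-variable SDs.

    After scaling the per-variable SDs sum to 1.  Raises on an all-constant
    block (S = 0).  The sample SD uses the n-1 denominator by default.
    """
    sds = block.data.std(axis=0, ddof=ddof)
    s_total = float(sds.sum())
    if s_total <= 0:
        raise DegenerateInputError(
            f"block {block.block_id} is constant; SD-sum scale is zero")
    return Block(block.data / s_total, block.block_id), s_total


def fuse(ms: Block, nmr: Block, scale: bool = True, ddof: int = 1) -> FusedMatrix:
    """Scale (optionally) and column-concatenate the MS and NMR blocks.

    Both blocks must carry identical sample ids in identical order; the fused
    matrix keeps each scaled cell exactly (no re-scaling at concatenation).
    """
    if list(ms.data.index) != list(nmr.data.index):
        offenders = sorted(set(ms.data.index).symmetric_difference(nmr.data.index))
        raise AlignmentError(
            "blocks have mismatched or reordered samples"
            + (f"; unshared ids: {offenders[:10]}" if offenders else " (order differs)"))
    factors: dict[str, float] = {}
    scaled = []
    for b in (ms, nmr):
        if scale:
            b, s = block_scale(b, ddof=ddof)
        else:
            s = 1.0
        factors[b.block_id] = s
        scaled.append(b)
    data = pd.concat([b.data for b in scaled], axis=1)
    membership = pd.Series(
        np.repeat([b.block_id for b in scaled],
                  [b.data.shape[1] for b in scaled]),
        index=data.columns)
    return FusedMatrix(data, membership, factors)


def sum_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Divide each row (sample) by its own total; row sums become 1."""
    totals = m.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise DegenerateInputError(f"rows with nonpositive sum: {bad[:10]}")
    return m.div(totals, axis=0)


def mean_intensity_filter(m: pd.DataFrame, keep_fraction: float = 0.75) -> pd.DataFrame:
    """Retain the top fraction of variables by column mean, preserving order.

    Ties at the cutoff are all retained, so slightly more than the nominal
    fraction can survive.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    means = m.mean(axis=0)
    k = max(1, int(np.ceil(keep_fraction * m.shape[1])))
    cutoff = np.sort(means.to_numpy())[::-1][k - 1]
    keep = means >= cutoff
    return m.loc[:, keep]
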
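"""Aligned LC-HRMS feature tables and blank/background removal.

A feature table (MZmine-export dialect) holds one row per aligned feature
with its m/z, retention time, ionization polarity, per-sample peak areas and
one solvent-blank column.  Background features are removed with a
sample-to-blank intensity-ratio rule: a feature is kept only when its mean
sample area exceeds ``ratio_threshold`` times the blank area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

REQUIRED_COLUMNS = ("feature_id", "mz", "rt_min", "polarity", "blank")

#: Conventional blank-fold-change cutoff in untargeted metabolomics.
DEFAULT_BLANK_RATIO = 3.0


@dataclass
class FeatureMatrix:
    """Samples x MS features container.

    ``features`` has columns feature_id, mz, rt_min, polarity, one column per
    sample id and a final ``blank`` column; ``sample_ids`` fixes sample order.
    """

    features: pd.DataFrame
    sample_ids: list[str]
    n_rejected: int = 0

    def __post_init__(self) -> None:
        ids = self.features["feature_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dupes[:5]}")
        missing = [s for s in self.sample_ids if s not in self.features.columns]
        if missing:
            raise FormatError(f"feature table lacks sample columns: {missing}")

    @property
    def n_features(self) -> int:
        return len(self.features)

    def areas(self) -> pd.DataFrame:
        """Samples x features area matrix (rows ordered by sample_ids)."""
        block = self.features.set_index("feature_id")[self.sample_ids]
        return block.T.loc[self.sample_ids]

    def to_csv(self, path: str | Path) -> None:
        self.features.to_csv(path, index=False)


def load_feature_table(path: str | Path, polarity: str = "positive") -> FeatureMatrix:
    """Read an aligned feature table CSV exported by the upstream processor.

    Rows with non-numeric m/z or any negative area are rejected; the count of
    rejected rows is kept on the returned matrix.  A ``polarity`` column in
    the file wins over the argument.
    """
    if polarity not in ("positive", "negative"):
        raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
    try:
        raw = pd.read_csv(path, dtype=str, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty feature table: {path}") from exc
    if raw.empty:
        raise FormatError(f"feature table has a header but no rows: {path}")
    for col in ("feature_id", "mz", "rt_min", "blank"):
        if col not in raw.columns:
            raise FormatError(f"feature table missing required column {col!r}")
    has_polarity = "polarity" in raw.columns
    sample_cols = [c for c in raw.columns if c not in REQUIRED_COLUMNS]
    if not sample_cols:
        raise FormatError("feature table has no sample columns")

    numeric_cols = ["mz", "rt_min", *sample_cols, "blank"]
    numeric = raw[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric["mz"].isna() | numeric["rt_min"].isna()
    area_cols = [*sample_cols, "blank"]
    bad |= numeric[area_cols].isna().any(axis=1) | (numeric[area_cols] < 0).any(axis=1)

    table = pd.concat(
        [raw.loc[~bad, ["feature_id"]].reset_index(drop=True),
         numeric.loc[~bad].reset_index(drop=True)], axis=1)
    table["polarity"] = (raw.loc[~bad, "polarity"].reset_index(drop=True)
                         if has_polarity else polarity)
    table = table[["feature_id", "mz", "rt_min", "polarity", *sample_cols, "blank"]]
    return FeatureMatrix(table, sample_cols, n_rejected=int(bad.sum()))


def remove_blank_features(
    matrix: FeatureMatrix, ratio_threshold: float = DEFAULT_BLANK_RATIO
) -> tuple[FeatureMatrix, list[str]]:
    """Drop features attributable to the solvent/instrument background.

    A feature is removed iff mean(sample areas) / blank_area < ratio_threshold.
    Features with blank_area == 0 are retained unconditionally (no background
    evidence).  Input order is preserved; the removed ids are returned.
    """
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be positive")
    feats = matrix.features
    mean_area = feats[matrix.sample_ids].mean(axis=1)
    blank = feats["blank"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_area / blank
    remove = (blank > 0) & (ratio < ratio_threshold)
    removed_ids = feats.loc[remove, "feature_id"].tolist()
    kept = FeatureMatrix(feats.loc[~remove].reset_index(drop=True),
                         list(matrix.sample_ids))
    return kept, removed_ids
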
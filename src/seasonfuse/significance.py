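"""Univariate significance of discriminant variables and rank-based FDR.

After VIP selection the retained variables are tested one-way across the
season groups (ANOVA, optionally Kruskal-Wallis), pairwise contrasts come
from Tukey's HSD, and multiplicity over the selected set is controlled with
the rank-based false-discovery-rate estimate: p-values are ranked ascending,
each is multiplied by the number of tested variables N and divided by its
rank, and the resulting raw FDR values are made monotone by the step-up
adjustment (running minimum from the largest rank downward, capped at 1).
Variables with adjusted FDR <= alpha (default 0.05) are flagged significant.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError

DEFAULT_ALPHA = 0.05


def _groups(values: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    classes = sorted(set(labels.tolist()))
    out = [values[labels == cls] for cls in classes]
    if len(out) < 2:
        raise ValueError("need >= 2 groups")
    for cls, g in zip(classes, out):
        if len(g) < 2:
            raise DegenerateInputError(f"group {cls!r} has fewer than 2 samples")
    return out


def group_pvalues(m: pd.DataFrame, labels, variables: Sequence[str] | None = None,
                  method: str = "anova") -> dict[str, float]:
    """Per-variable one-way group-difference p-value.

    ``method`` is "anova" (F-test) or "kruskal".  A variable with zero
    variance everywhere has an undefined test statistic and raises.
    """
    labels = np.asarray(labels)
    cols = [str(v) for v in variables] if variables is not None else list(m.columns)
    out: dict[str, float] = {}
    for col in cols:
        values = m[col].to_numpy(dtype=float)
        groups = _groups(values, labels)
        if np.ptp(values) == 0:
            raise DegenerateInputError(
                f"variable {col!r} is constant; group test undefined")
        if method == "anova":
            stat = stats.f_oneway(*groups)
        elif method == "kruskal":
            stat = stats.kruskal(*groups)
        else:
            raise ValueError(f"unknown method {method!r}")
        out[col] = float(stat.pvalue)
    return out


def tukey_hsd(values, labels) -> pd.DataFrame:
    """Tukey's honestly-significant-difference pairwise contrasts.

    Returns one row per group pair with the mean difference and the
    studentized-range adjusted p-value.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    groups = _groups(values, labels)
    res = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            rows.append((classes[i], classes[j],
                         float(groups[i].mean() - groups[j].mean()),
                         float(res.pvalue[i, j])))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "difference", "p_adj"])


def fdr_estimate(pvalues: Mapping[str, float], alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Rank-based FDR over a tested variable set.

    For p-values sorted ascending with ranks 1..N, fdr_raw_i = p_(i) * N / i;
    fdr_adj is the step-up monotone adjustment (running minimum from the
    largest rank down), capped at 1.  N is the size of the tested set itself.
    Returns a table sorted by rank with a ``significant`` flag at
    fdr_adj <= alpha.
    """
    if not pvalues:
        raise ValueError("no p-values supplied")
    ids = list(pvalues.keys())
    p = np.array([pvalues[i] for i in ids], dtype=float)
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, n + 1)
    p_sorted = p[order]
    fdr_raw = p_sorted * n / ranks
    fdr_adj = np.minimum.accumulate(fdr_raw[::-1])[::-1]
    fdr_adj = np.minimum(fdr_adj, 1.0)
    return pd.DataFrame({
        "variable_id": [ids[k] for k in order],
        "p": p_sorted,
        "rank": ranks,
        "fdr_raw": fdr_raw,
        "fdr_adj": fdr_adj,
        "significant": fdr_adj <= alpha,
    })


def season_summaries(m: pd.DataFrame, labels,
                     variables: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-variable, per-season mean and SD for box-plot style reporting."""
    labels = np.asarray(labels)
    cols = [str(v) for v in variables] if variables is not None else list(m.columns)
    classes = sorted(set(labels.tolist()))
    rows = []
    for col in cols:
        values = m[col].to_numpy(dtype=float)
        for cls in classes:
            g = values[labels == cls]
            rows.append((col, cls, float(g.mean()),
                         float(g.std(ddof=1)) if len(g) > 1 else 0.0))
    return pd.DataFrame(rows, columns=["variable_id", "season", "mean", "sd"])
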
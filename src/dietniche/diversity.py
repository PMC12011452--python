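"""Alpha diversity, rarefaction, and the Kruskal-Wallis group comparison.

Indices are computed per sample at the OTU level (including unassigned
OTUs), the stage at which sequencing coverage and richness are assessed:

* Chao1 (bias-corrected): ``S_obs + F1(F1-1) / (2(F2+1))`` with F1 the
  singleton and F2 the doubleton count; defined even when F2 = 0.
* Shannon-Wiener ``H = -sum p ln p`` (natural log by default; the base is
  configurable).
* Gini-Simpson ``1 - sum p^2`` (the raw dominance ``sum p^2`` is exposed as
  ``simpson_dominance``).
* Pielou evenness ``H / ln S_obs`` (1 for a single-OTU sample).
* Good's coverage ``1 - F1/N``.

Rarefaction subsamples reads without replacement (multivariate
hypergeometric) and reports the median index over replicate draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import OtuTable, ValidationError

__all__ = [
    "AlphaDiversity",
    "RarefactionCurve",
    "chao1",
    "shannon",
    "simpson",
    "simpson_dominance",
    "pielou",
    "goods_coverage",
    "alpha_diversity",
    "alpha_diversity_table",
    "rarefaction_curve",
    "kruskal_wallis",
]


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if not np.issubdtype(c.dtype, np.integer):
        if not np.allclose(c, np.round(c)):
            raise ValueError("counts must be integers")
        c = np.round(c).astype(np.int64)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if c.sum() == 0:
        raise ValueError("sample has no reads")
    return c


def _as_proportions(proportions) -> np.ndarray:
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("proportions sum to zero")
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {total!r}, not 1")
    return p


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness estimate; always >= observed richness."""
    c = _as_counts(counts)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(proportions, base: float | None = None) -> float:
    """Shannon-Wiener diversity over p > 0; natural log unless ``base``."""
    p = _as_proportions(proportions)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def simpson_dominance(proportions) -> float:
    p = _as_proportions(proportions)
    return float((p**2).sum())


def simpson(proportions) -> float:
    """Gini-Simpson index ``1 - sum p^2``."""
    return 1.0 - simpson_dominance(proportions)


def pielou(proportions) -> float:
    """Evenness ``H / ln S``; defined as 1 for a single category."""
    p = _as_proportions(proportions)
    s = int((p > 0).sum())
    if s == 1:
        return 1.0
    return shannon(p) / float(np.log(s))


def goods_coverage(counts) -> float:
    """Good's coverage ``1 - F1/N`` (F1 singleton OTUs, N total reads)."""
    c = _as_counts(counts)
    f1 = int((c == 1).sum())
    return 1.0 - f1 / float(c.sum())


@dataclass
class AlphaDiversity:
    sample_id: str
    observed_otus: int
    chao1: float
    shannon: float
    simpson: float
    pielou: float
    goods_coverage: float


def alpha_diversity(sample_id: str, counts) -> AlphaDiversity:
    c = _as_counts(counts)
    p = c / c.sum()
    return AlphaDiversity(
        sample_id=sample_id,
        observed_otus=int((c > 0).sum()),
        chao1=chao1(c),
        shannon=shannon(p),
        simpson=simpson(p),
        pielou=pielou(p),
        goods_coverage=goods_coverage(c),
    )


def alpha_diversity_table(table: OtuTable) -> pd.DataFrame:
    """One row of alpha-diversity indices per sample."""
    rows = [alpha_diversity(sid, table.counts[i]) for i, sid in enumerate(table.sample_ids)]
    return pd.DataFrame([vars(r) for r in rows]).set_index("sample_id")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

_INDEX_FUNCS = {
    "shannon": lambda c: shannon(c / c.sum()),
    "simpson": lambda c: simpson(c / c.sum()),
    "observed_otus": lambda c: float((c > 0).sum()),
    "chao1": chao1,
}


@dataclass
class RarefactionCurve:
    sample_id: str
    depths: list[int]
    values: list[float]
    index: str
    n_replicates: int
    seed: int


def rarefaction_curve(
    sample_id: str,
    counts,
    depths: Sequence[int],
    n_replicates: int = 10,
    index: str = "shannon",
    seed: int = 0,
) -> RarefactionCurve:
    """Median index value over ``n_replicates`` subsamples at each depth.

    Subsampling is without replacement, so at full depth every replicate is
    the sample itself and the curve ends exactly at the unrarefied index.
    """
    c = _as_counts(counts)
    if index not in _INDEX_FUNCS:
        raise ValueError(f"unknown index {index!r}; choose from {sorted(_INDEX_FUNCS)}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    depths = [int(d) for d in depths]
    if sorted(depths) != depths or len(set(depths)) != len(depths):
        raise ValueError("depths must be strictly increasing")
    total = int(c.sum())
    if depths and depths[-1] > total:
        raise ValueError(f"depth {depths[-1]} exceeds sample total {total}")
    if depths and depths[0] < 1:
        raise ValueError("depths must be >= 1")
    rng = np.random.default_rng(seed)
    func = _INDEX_FUNCS[index]
    values = []
    for d in depths:
        if d == total:
            values.append(float(func(c)))
            continue
        reps = [
            float(func(rng.multivariate_hypergeometric(c, d)))
            for _ in range(n_replicates)
        ]
        values.append(float(np.median(reps)))
    return RarefactionCurve(sample_id, depths, values, index, n_replicates, seed)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: Iterable[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Mid-ranks for ties; k-1 degrees of freedom.  When every observation is
    identical the statistic is 0 and p is 1 (no evidence of any difference).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(gs)
    if pooled.size < 3:
        raise ValueError("need at least three observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*gs)
    return float(h), float(p)
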
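"""Trophic niche breadth and overlap.

These are the statistics the rest of the pipeline exists to feed.  All three
operate on diet proportion vectors P (RRA of one consumer group):

* Levins' niche breadth      ``B = 1 / sum_i P_i^2``; B = 1 for a pure
  specialist, B = S for a perfectly even generalist over S food categories.
* Hurlbert's standardization ``Ba = (B - 1) / (S - 1)``, rescaling breadth
  to [0, 1] so groups with different resource-category counts compare.
  S is the number of food categories with nonzero proportion in the group's
  pooled profile (a per-consumer count, not the global taxon universe).
* Pianka's overlap           ``Q_jk = sum_i P_ij P_ik /
  sqrt(sum_i P_ij^2 * sum_i P_ik^2)`` — the cosine similarity of two diet
  vectors aligned on the union of their taxa; 0 = no shared food item,
  1 = proportional resource use.  Q > 0.6 is conventionally read as a
  significant overlap (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Season, Species, ValidationError
from .profiles import DietProfile

__all__ = [
    "NicheResult",
    "OverlapMatrix",
    "levins",
    "levins_breadth",
    "standardized_breadth",
    "pianka",
    "pianka_overlap",
    "niche_result",
    "overlap_matrix",
]

OVERLAP_THRESHOLD = 0.6


def levins(proportions) -> tuple[float, int]:
    """Levins' breadth B and the nonzero-category count S for one vector.

    The vector is renormalised, so breadth is scale-free.
    """
    p = np.asarray(proportions, dtype=float)
    if p.size == 0 or (p < 0).any() or p.sum() == 0:
        raise ValidationError("need a non-empty, non-negative proportion vector")
    p = p / p.sum()
    b = 1.0 / float((p**2).sum())
    s = int((p > 0).sum())
    return b, s


def levins_breadth(profile: DietProfile) -> tuple[float, int]:
    """Levins' B and S for a pooled group profile."""
    return levins(profile.proportions)


def standardized_breadth(b: float, s: int) -> float:
    """Hurlbert's Ba = (B - 1) / (S - 1); 0 by convention when S = 1."""
    if s < 1:
        raise ValidationError("S must be >= 1")
    if b < 1 - 1e-9 or b > s + 1e-9:
        raise ValidationError(f"B = {b} outside [1, S = {s}]")
    if s == 1:
        return 0.0
    return (min(max(b, 1.0), float(s)) - 1.0) / (s - 1.0)


def pianka(p: Sequence[float], q: Sequence[float]) -> float:
    """Pianka's overlap for two aligned proportion vectors."""
    x = np.asarray(p, dtype=float)
    y = np.asarray(q, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must be aligned on the same categories")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("proportions must be non-negative")
    nx = float((x**2).sum())
    ny = float((y**2).sum())
    if nx == 0 or ny == 0:
        raise ValidationError("zero-vector profile has no defined overlap")
    val = float((x * y).sum()) / np.sqrt(nx * ny)
    return float(min(max(val, 0.0), 1.0))


def _align(profile_j: DietProfile, profile_k: DietProfile):
    union = sorted(set(profile_j.taxa) | set(profile_k.taxa))
    pj = profile_j.as_series().reindex(union, fill_value=0.0).to_numpy()
    pk = profile_k.as_series().reindex(union, fill_value=0.0).to_numpy()
    return union, pj, pk


def pianka_overlap(profile_j: DietProfile, profile_k: DietProfile) -> float:
    """Pianka's Q for two group profiles, aligned on the union of taxa."""
    if profile_j.rank != profile_k.rank:
        raise ValidationError(
            f"profiles at different ranks: {profile_j.rank} vs {profile_k.rank}"
        )
    _, pj, pk = _align(profile_j, profile_k)
    return pianka(pj, pk)


@dataclass
class NicheResult:
    """Levins breadth, category count, and Hurlbert standardization."""

    species: Species
    season: Season
    B: float
    S: int
    Ba: float

    @classmethod
    def from_profile(cls, profile: DietProfile) -> "NicheResult":
        b, s = levins_breadth(profile)
        return cls(profile.species, profile.season, b, s, standardized_breadth(b, s))


def niche_result(profile: DietProfile) -> NicheResult:
    return NicheResult.from_profile(profile)


@dataclass
class OverlapMatrix:
    """Pairwise Pianka overlaps for the consumers of one season."""

    season: Season
    species: list[Species]
    Q: np.ndarray
    threshold: float = OVERLAP_THRESHOLD

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        n = len(self.species)
        if self.Q.shape != (n, n):
            raise ValidationError("overlap matrix shape does not match species list")
        if not np.allclose(self.Q, self.Q.T):
            raise ValidationError("overlap matrix must be symmetric")
        if not np.allclose(np.diag(self.Q), 1.0):
            raise ValidationError("overlap matrix diagonal must be 1")
        if (self.Q < -1e-12).any() or (self.Q > 1 + 1e-12).any():
            raise ValidationError("overlap values must lie in [0, 1]")

    @property
    def significant(self) -> np.ndarray:
        """Strictly-greater-than-threshold flags (diagonal excluded)."""
        flags = self.Q > self.threshold
        np.fill_diagonal(flags, False)
        return flags

    def to_dataframe(self) -> pd.DataFrame:
        names = [s.value for s in self.species]
        return pd.DataFrame(self.Q, index=names, columns=names)


def overlap_matrix(
    profiles: Mapping[Species, DietProfile] | Sequence[DietProfile],
    threshold: float = OVERLAP_THRESHOLD,
) -> OverlapMatrix:
    """All pairwise Pianka overlaps among one season's group profiles."""
    if isinstance(profiles, Mapping):
        items = list(profiles.values())
    else:
        items = list(profiles)
    if len(items) < 2:
        raise ValidationError("need at least two profiles")
    ranks = {p.rank for p in items}
    if len(ranks) > 1:
        raise ValidationError(f"profiles at mismatched ranks: {sorted(ranks)}")
    seasons = {p.season for p in items}
    if len(seasons) > 1:
        raise ValidationError("overlap matrix mixes seasons")
    n = len(items)
    q = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            q[i, j] = q[j, i] = pianka_overlap(items[i], items[j])
    return OverlapMatrix(
        season=items[0].season,
        species=[p.species for p in items],
        Q=q,
        threshold=threshold,
    )
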
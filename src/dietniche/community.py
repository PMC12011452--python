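"""Community structure: Bray-Curtis, NMDS ordination, clustering, Venn.

Samples are compared by Bray-Curtis dissimilarity (on per-sample RRA at the
OTU level by default), ordinated with non-metric multidimensional scaling
(best-of-restarts SMACOF with isotonic regression on dissimilarity ranks,
reporting Kruskal stress-1), summarized by within/between-group distance
distributions, and clustered by UPGMA (average linkage, ultrametric) for a
Newick dendrogram.  Shared/specific OTU counts per season give the 7-region
Venn partition across the three consumers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import braycurtis, pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .diversity import kruskal_wallis
from .io import OtuTable, SampleRecord, Season, Species, ValidationError

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "SharedOtuSummary",
    "bray_curtis",
    "bray_curtis_matrix",
    "kruskal_stress",
    "pcoa_coordinates",
    "nmds",
    "intergroup_distances",
    "IntergroupDistances",
    "upgma",
    "TreeNode",
    "shared_otu_counts",
]


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity ``1 - 2 sum min(x, y) / (sum x + sum y)``."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("abundances must be non-negative")
    if a.sum() == 0 and b.sum() == 0:
        raise ValidationError("Bray-Curtis undefined for two empty samples")
    return float(braycurtis(a, b))


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with a zero diagonal."""

    ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.ids)
        if self.D.shape != (n, n):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if (self.D < -1e-12).any():
            raise ValidationError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.D, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.ids, columns=self.ids)


def bray_curtis_matrix(vectors: np.ndarray, ids: Sequence[str]) -> DistanceMatrix:
    """Pairwise Bray-Curtis over rows of ``vectors``."""
    arr = np.asarray(vectors, dtype=float)
    if (arr.sum(axis=1) == 0).any():
        raise ValidationError("every row needs a positive total")
    d = squareform(pdist(arr, metric="braycurtis"))
    return DistanceMatrix(list(ids), d)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    ids: list[str]
    coordinates: np.ndarray
    stress: float
    n_restarts: int
    seed: int
    converged: bool

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"axis{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(
            self.coordinates, index=pd.Index(self.ids, name="sample_id"), columns=cols
        )


def kruskal_stress(dm: DistanceMatrix, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix.

    Disparities come from isotonic regression of the embedded distances on
    the rank order of the input dissimilarities; stress-1 is
    ``sqrt(sum (d - dhat)^2 / sum d^2)`` over all pairs.
    """
    iu = np.triu_indices(dm.n, k=1)
    diss = dm.D[iu]
    d = squareform(
        np.sqrt(((coordinates[:, None, :] - coordinates[None, :, :]) ** 2).sum(-1)),
        checks=False,
    )
    order = np.argsort(diss, kind="stable")
    dhat = np.empty_like(d)
    dhat[order] = IsotonicRegression().fit_transform(np.arange(order.size), d[order])
    denom = float((d**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def pcoa_coordinates(dm: DistanceMatrix, dims: int = 2) -> np.ndarray:
    """Classical (metric) MDS coordinates used as the deterministic restart."""
    n = dm.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm.D**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:dims]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    return coords


def nmds(
    dm: DistanceMatrix,
    dims: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS: best (lowest stress-1) of one PCoA-initialized and
    ``n_restarts - 1`` random-start SMACOF runs; deterministic given seed."""
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if dm.n == 1:
        return OrdinationResult(list(dm.ids), np.zeros((1, dims)), 0.0, n_restarts, seed, True)
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(n_restarts)
    best_coords = None
    best_stress = np.inf
    for r in range(n_restarts):
        init = pcoa_coordinates(dm, dims) if r == 0 else None
        coords, stress = smacof(
            dm.D,
            metric=False,
            n_components=dims,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            random_state=int(states[r] % (2**31)),
            normalized_stress=True,
        )
        if stress < best_stress:
            best_stress = float(stress)
            best_coords = coords
    return OrdinationResult(
        ids=list(dm.ids),
        coordinates=best_coords,
        stress=best_stress,
        n_restarts=n_restarts,
        seed=seed,
        converged=bool(np.isfinite(best_stress)),
    )


# ---------------------------------------------------------------------------
# Within/between group distances
# ---------------------------------------------------------------------------


@dataclass
class IntergroupDistances:
    """Distance distributions within each group and between each pair."""

    within: dict[str, np.ndarray]
    between: dict[tuple[str, str], np.ndarray]
    kruskal: dict[tuple[str, str], tuple[float, float]]
    singleton_groups: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for g, d in sorted(self.within.items()):
            if d.size:
                rows.append(("within", g, g, d.size, float(np.median(d)), float(d.mean())))
        for (a, b), d in sorted(self.between.items()):
            h, p = self.kruskal.get((a, b), (np.nan, np.nan))
            rows.append(("between", a, b, d.size, float(np.median(d)), float(d.mean())))
        df = pd.DataFrame(
            rows, columns=["kind", "group_a", "group_b", "n_pairs", "median", "mean"]
        )
        pvals = []
        for _, row in df.iterrows():
            key = (row["group_a"], row["group_b"])
            pvals.append(self.kruskal[key][1] if key in self.kruskal else np.nan)
        df["kw_p"] = pvals
        return df


def intergroup_distances(
    dm: DistanceMatrix, labels: Mapping[str, str]
) -> IntergroupDistances:
    """Split pairwise distances into within-group and between-group multisets.

    For each pair of groups a Kruskal-Wallis test compares the two
    within-group distributions against the between-group one.  Groups with a
    single member have no within-distances and are flagged.
    """
    groups = sorted(set(labels[i] for i in dm.ids))
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    idx_by_group = {g: [i for i, s in enumerate(dm.ids) if labels[s] == g] for g in groups}
    within = {}
    singleton = []
    for g, idx in idx_by_group.items():
        if len(idx) < 2:
            within[g] = np.array([])
            singleton.append(g)
        else:
            sub = dm.D[np.ix_(idx, idx)]
            within[g] = sub[np.triu_indices(len(idx), k=1)]
    between = {}
    kw = {}
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            d = dm.D[np.ix_(idx_by_group[a], idx_by_group[b])].ravel()
            between[(a, b)] = d
            if within[a].size and within[b].size and d.size:
                pooled = np.concatenate([within[a], within[b], d])
                if np.all(pooled == pooled[0]):
                    kw[(a, b)] = (0.0, 1.0)
                else:
                    kw[(a, b)] = kruskal_wallis([within[a], within[b], d])
    return IntergroupDistances(within, between, kw, singleton)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Rooted ultrametric tree node; ``height`` is distance to the leaves."""

    name: str | None
    height: float
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [n for c in self.children for n in c.leaf_names()]

    def to_newick(self) -> str:
        return self._newick_rec(parent_height=self.height) + ";"

    def _newick_rec(self, parent_height: float) -> str:
        length = parent_height - self.height
        if self.is_leaf:
            return f"{self.name}:{length:.10g}"
        inner = ",".join(c._newick_rec(self.height) for c in self.children)
        return f"({inner}):{length:.10g}"


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomerative clustering; ultrametric rooted tree.

    Node heights are half the merge distance, so every root-to-leaf path has
    the same length (the cophenetic distance between two leaves is the merge
    distance of their join).
    """
    if dm.n < 2:
        raise ValidationError("need at least two leaves")
    link = hierarchy.linkage(dm.condensed(), method="average")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=dm.ids[i], height=0.0) for i in range(dm.n)
    }
    for k, (a, b, dist, _) in enumerate(link):
        nodes[dm.n + k] = TreeNode(
            name=None,
            height=float(dist) / 2.0,
            children=[nodes[int(a)], nodes[int(b)]],
        )
    return nodes[dm.n + len(link) - 1]


# ---------------------------------------------------------------------------
# Shared / specific OTUs (Venn)
# ---------------------------------------------------------------------------


@dataclass
class SharedOtuSummary:
    """7-region Venn partition of OTU presence across the three consumers."""

    season: Season
    species: list[Species]
    regions: dict[frozenset, int]

    @property
    def shared_all(self) -> int:
        return self.regions.get(frozenset(self.species), 0)

    @property
    def specific(self) -> dict[Species, int]:
        return {sp: self.regions.get(frozenset([sp]), 0) for sp in self.species}

    @property
    def total_present(self) -> int:
        return sum(self.regions.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for members, count in sorted(
            self.regions.items(), key=lambda kv: (len(kv[0]), sorted(s.value for s in kv[0]))
        ):
            rows.append(
                (self.season.value, "&".join(sorted(s.value for s in members)), count)
            )
        return pd.DataFrame(rows, columns=["season", "region", "n_otus"])


def shared_otu_counts(
    table: OtuTable,
    metadata: Iterable[SampleRecord],
    season: Season,
    presence_threshold: int = 1,
    otu_subset: set[str] | None = None,
) -> SharedOtuSummary:
    """Venn partition of OTU presence for one season.

    An OTU is present for a species when its summed reads across that
    species' seasonal samples reach ``presence_threshold``.  ``otu_subset``
    restricts the analysis (typically to taxonomically assigned OTUs).
    """
    meta = [r for r in metadata if r.season == season]
    species = sorted({r.species for r in meta}, key=lambda s: s.value)
    if len(species) < 2:
        raise ValidationError(f"need >= 2 species with samples in {season.value}")
    cols = list(range(table.n_otus))
    if otu_subset is not None:
        cols = [j for j, o in enumerate(table.otu_ids) if o in otu_subset]
    presence = {}
    sample_pos = {s: i for i, s in enumerate(table.sample_ids)}
    for sp in species:
        rows = [sample_pos[r.sample_id] for r in meta if r.species == sp and r.sample_id in sample_pos]
        if not rows:
            raise ValidationError(f"no samples for {sp.value} in {season.value}")
        totals = table.counts[np.ix_(rows, cols)].sum(axis=0)
        presence[sp] = totals >= presence_threshold
    stack = np.vstack([presence[sp] for sp in species])
    regions: dict[frozenset, int] = {}
    present_any = stack.any(axis=0)
    for j in np.flatnonzero(present_any):
        members = frozenset(sp for i, sp in enumerate(species) if stack[i, j])
        regions[members] = regions.get(members, 0) + 1
    return SharedOtuSummary(season=season, species=species, regions=regions)
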
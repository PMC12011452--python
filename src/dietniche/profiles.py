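"""Diet profiles: LCA collapsing, relative read abundance, group pooling.

Read counts are a semi-quantitative surrogate for diet proportions, so every
sample is converted to relative read abundance (RRA: counts divided by the
sample's retained total) before any comparison.  OTUs whose BLAST hits span
several taxa are collapsed to the lowest rank shared by all candidates, and
unassigned OTUs are excluded from diet composition by default (they still
count for OTU-level diversity statistics).

A "group" is one herbivore species in one season; its pooled profile is the
unweighted mean of the per-sample RRA vectors (``mean_rra``, the default, so
deeply sequenced samples do not dominate) or the RRA of the summed group
counts (``pooled_reads``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    RANKS,
    GrowthFormMap,
    Lineage,
    OtuTable,
    SampleRecord,
    Season,
    Species,
    TaxonAssignment,
    ValidationError,
)

__all__ = [
    "DietProfile",
    "SampleRra",
    "lca_collapse",
    "resolve_taxa",
    "to_rra",
    "pool_group_profile",
    "group_profiles",
    "top_n_taxa",
    "growth_form_percentages",
]

_SUM_TOL = 1e-9


@dataclass
class SampleRra:
    """Per-sample relative read abundances over taxa at one rank."""

    sample_id: str
    taxa: list[str]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        _check_simplex(self.proportions, f"sample {self.sample_id}")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError(f"sample {self.sample_id}: duplicate taxa")

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=self.taxa)


@dataclass
class DietProfile:
    """Pooled RRA vector for one (species, season) group at one rank."""

    species: Species
    season: Season
    rank: str
    taxa: list[str]
    proportions: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        _check_simplex(self.proportions, f"group {self.group_id}")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError(f"group {self.group_id}: duplicate taxa")

    @property
    def group_id(self) -> tuple[str, str]:
        return (self.species.value, self.season.value)

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=self.taxa)


def _check_simplex(p: np.ndarray, what: str) -> None:
    if (p < 0).any() or (p > 1 + _SUM_TOL).any():
        raise ValidationError(f"{what}: proportions outside [0, 1]")
    if p.size and abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValidationError(f"{what}: proportions sum to {p.sum()!r}, not 1")


# ---------------------------------------------------------------------------
# LCA collapsing
# ---------------------------------------------------------------------------


def lca_collapse(assignment: TaxonAssignment) -> Lineage | None:
    """Collapse an OTU's candidate lineages to their lowest common rank.

    Walks the ranks from kingdom down and keeps a rank when every candidate
    that names any rank agrees on it; ranks missing from *all* candidates are
    skipped (bare family-level exports carry nothing above family).  Returns
    ``None`` for an unassigned OTU or when the candidates share no rank.
    """
    if assignment.is_unassigned:
        return None
    agreed: list[tuple[str, str]] = []
    for rank in RANKS:
        values = [c.get(rank) for c in assignment.candidates]
        present = [v for v in values if v is not None]
        if not present:
            continue  # no candidate names this rank; keep walking
        if len(present) < len(values) or len(set(present)) > 1:
            break
        agreed.append((rank, present[0]))
    if not agreed:
        return None
    return Lineage(tuple(agreed))


def resolve_taxa(
    assignments: Iterable[TaxonAssignment], rank: str
) -> dict[str, str | None]:
    """Map each OTU id to its taxon label at ``rank`` (``None`` = unassigned).

    An OTU whose LCA sits above the requested rank keeps its coarser name
    (e.g. a family label in a genus-level table), mirroring the convention of
    reporting ambiguous OTUs at the higher level that includes all matches.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    resolved: dict[str, str | None] = {}
    for a in assignments:
        lineage = lca_collapse(a)
        resolved[a.otu_id] = None if lineage is None else lineage.label_at(rank)
    return resolved


# ---------------------------------------------------------------------------
# RRA conversion
# ---------------------------------------------------------------------------


def to_rra(
    table: OtuTable,
    resolved: Mapping[str, str | None],
    drop_unassigned: bool = True,
) -> list[SampleRra]:
    """Convert counts to per-sample RRA over resolved taxa.

    Counts of OTUs mapping to the same taxon are summed per sample, then
    divided by the sample's retained total.  With ``drop_unassigned`` the
    unassigned OTUs are removed before normalisation (proportions are over
    assigned reads only); otherwise their reads pool into an ``"unassigned"``
    category.
    """
    labels = []
    keep = []
    for j, otu in enumerate(table.otu_ids):
        label = resolved.get(otu)
        if label is None:
            if drop_unassigned:
                continue
            label = "unassigned"
        labels.append(label)
        keep.append(j)
    if not keep:
        raise ValidationError("no assigned OTUs left after filtering")
    sub = table.counts[:, keep]
    taxa = sorted(set(labels))
    taxon_idx = {t: i for i, t in enumerate(taxa)}
    agg = np.zeros((table.n_samples, len(taxa)), dtype=np.int64)
    for col, label in enumerate(labels):
        agg[:, taxon_idx[label]] += sub[:, col]
    totals = agg.sum(axis=1)
    empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if empty:
        raise ValidationError(
            f"samples with zero retained reads after filtering: {empty}"
        )
    out = []
    for i, sid in enumerate(table.sample_ids):
        out.append(SampleRra(sid, list(taxa), agg[i] / totals[i]))
    return out


# ---------------------------------------------------------------------------
# Group pooling
# ---------------------------------------------------------------------------


def pool_group_profile(
    samples: Sequence[SampleRra],
    metadata: Iterable[SampleRecord],
    species: Species,
    season: Season,
    rank: str,
    method: str = "mean_rra",
    table: OtuTable | None = None,
    resolved: Mapping[str, str | None] | None = None,
    drop_unassigned: bool = True,
) -> DietProfile:
    """Pool the samples of one (species, season) group into a DietProfile.

    ``mean_rra`` averages per-sample proportion vectors over the union of
    taxa (absent taxon = 0) and renormalises; ``pooled_reads`` recomputes RRA
    from the summed raw counts of the group (requires ``table`` and
    ``resolved``).
    """
    meta = {r.sample_id: r for r in metadata}
    group_ids = [
        s.sample_id
        for s in samples
        if s.sample_id in meta
        and meta[s.sample_id].species == species
        and meta[s.sample_id].season == season
    ]
    if not group_ids:
        raise ValidationError(f"no samples for group ({species.value}, {season.value})")
    group_samples = [s for s in samples if s.sample_id in set(group_ids)]
    if method == "mean_rra":
        frame = pd.DataFrame(
            {s.sample_id: s.as_series() for s in group_samples}
        ).fillna(0.0)
        mean = frame.mean(axis=1)
        mean = mean / mean.sum()
        mean = mean.sort_index()
        return DietProfile(
            species, season, rank, list(mean.index), mean.to_numpy(), len(group_samples)
        )
    if method == "pooled_reads":
        if table is None or resolved is None:
            raise ValueError("pooled_reads pooling needs the OTU table and taxon map")
        sub = table.subset_samples(group_ids)
        summed = OtuTable(
            ["pooled"], list(sub.otu_ids), sub.counts.sum(axis=0, keepdims=True)
        )
        pooled = to_rra(summed, resolved, drop_unassigned=drop_unassigned)[0]
        order = np.argsort(pooled.taxa)
        return DietProfile(
            species,
            season,
            rank,
            [pooled.taxa[i] for i in order],
            pooled.proportions[order],
            len(group_ids),
        )
    raise ValueError(f"unknown pooling method {method!r}")


def group_profiles(
    table: OtuTable,
    metadata: Iterable[SampleRecord],
    resolved: Mapping[str, str | None],
    rank: str,
    method: str = "mean_rra",
    drop_unassigned: bool = True,
) -> dict[tuple[Species, Season], DietProfile]:
    """All (species, season) profiles present in the metadata."""
    meta = list(metadata)
    rras = to_rra(table, resolved, drop_unassigned=drop_unassigned)
    groups = sorted(
        {(r.species, r.season) for r in meta if r.sample_id in set(table.sample_ids)},
        key=lambda g: (g[0].value, g[1].value),
    )
    return {
        (sp, se): pool_group_profile(
            rras, meta, sp, se, rank, method=method, table=table, resolved=resolved,
            drop_unassigned=drop_unassigned,
        )
        for sp, se in groups
    }


# ---------------------------------------------------------------------------
# Derived tables
# ---------------------------------------------------------------------------


def top_n_taxa(profile: DietProfile, n: int) -> pd.DataFrame:
    """Top-``n`` taxa by proportion plus an ``Others`` remainder row.

    Ties are broken alphabetically; the remainder preserves the unit sum.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    order = sorted(
        range(len(profile.taxa)),
        key=lambda i: (-profile.proportions[i], profile.taxa[i]),
    )
    head = order[:n]
    rows = [(profile.taxa[i], profile.proportions[i]) for i in head]
    rest = float(sum(profile.proportions[i] for i in order[n:]))
    if len(order) > n:
        rows.append(("Others", rest))
    return pd.DataFrame(rows, columns=["taxon", "proportion"])


def growth_form_percentages(
    profile: DietProfile,
    gmap: GrowthFormMap,
    lineages: Mapping[str, Lineage] | None = None,
) -> dict[str, float]:
    """Diet proportions summed by growth form (herb/shrub/arbor/unknown).

    Taxa are looked up by name; if ``lineages`` provides a lineage for a
    taxon, the lookup falls back species -> genus -> family.  Unmapped mass
    is reported under ``"unknown"``.  The output sums to 1.
    """
    out = {"herb": 0.0, "shrub": 0.0, "arbor": 0.0, "unknown": 0.0}
    for taxon, p in zip(profile.taxa, profile.proportions):
        form = gmap.lookup(taxon)
        if form is None and lineages is not None and taxon in lineages:
            form = gmap.lookup_lineage(lineages[taxon])
        out[form.value if form is not None else "unknown"] += float(p)
    return out
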
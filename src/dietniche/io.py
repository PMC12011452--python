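"""Tabular input/output and validated domain types.

The pipeline consumes four plain-text, tab-separated tables:

* an OTU count table (samples x OTUs, or the transpose),
* sample metadata mapping each sample to a herbivore species and a season,
* a taxonomy table mapping each OTU to zero or more candidate lineages,
* an optional growth-form map (taxon -> herb/shrub/arbor).

Lineage strings come in two dialects (see :func:`parse_lineage`): QIIME-style
rank-prefixed paths (``k__Plantae;...;g__Rubus;s__Rubus hirsutus``) which may
start at any rank from kingdom, and bare semicolon paths which are read as
``family;genus;species``.  Both are documented in the README; the bare form
matches common BLAST/LCA-annotation exports for plant trnL amplicons.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "FormatError",
    "ValidationError",
    "Species",
    "Season",
    "GrowthForm",
    "OtuTable",
    "SampleRecord",
    "Lineage",
    "TaxonAssignment",
    "GrowthFormMap",
    "parse_lineage",
    "format_lineage",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_growth_forms",
    "write_growth_forms",
]

#: Taxonomic ranks in order from most inclusive to most specific.
RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_RANK_PREFIX = {
    "k__": "kingdom",
    "p__": "phylum",
    "c__": "class",
    "o__": "order",
    "f__": "family",
    "g__": "genus",
    "s__": "species",
}
_PREFIX_FOR_RANK = {rank: pre for pre, rank in _RANK_PREFIX.items()}


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant."""


class Species(str, enum.Enum):
    """The three sympatric herbivores of the study system."""

    SIKA_DEER = "sika_deer"
    REEVES_MUNTJAC = "reeves_muntjac"
    CHINESE_HARE = "chinese_hare"

    @classmethod
    def parse(cls, label: str) -> "Species":
        key = _canon(label)
        try:
            return cls(key)
        except ValueError:
            raise ValidationError(
                f"unknown species label {label!r}; expected one of "
                f"{[s.value for s in cls]}"
            ) from None


class Season(str, enum.Enum):
    SPRING = "spring"
    SUMMER = "summer"
    FALL = "fall"
    WINTER = "winter"

    @classmethod
    def parse(cls, label: str) -> "Season":
        key = _canon(label)
        key = _SEASON_ALIASES.get(key, key)
        try:
            return cls(key)
        except ValueError:
            raise ValidationError(
                f"unknown season label {label!r}; expected one of "
                f"{[s.value for s in cls]} (alias: autumn)"
            ) from None


#: "autumn" and "fall" are used interchangeably for Sep-Nov.
_SEASON_ALIASES = {"autumn": "fall"}


class GrowthForm(str, enum.Enum):
    HERB = "herb"
    SHRUB = "shrub"
    ARBOR = "arbor"

    @classmethod
    def parse(cls, label: str) -> "GrowthForm":
        try:
            return cls(_canon(label))
        except ValueError:
            raise ValidationError(
                f"unknown growth form {label!r}; expected herb/shrub/arbor"
            ) from None


def _canon(label: str) -> str:
    return label.strip().lower().replace(" ", "_").replace("-", "_").replace("'", "")


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------


@dataclass
class OtuTable:
    """Non-negative integer read counts, samples x OTUs.

    Invariants (enforced by :meth:`validate`): no duplicate sample or OTU
    identifiers, all counts >= 0, and every sample has at least one read.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    def validate(self) -> None:
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate {name} identifier {i!r}")
                seen.add(i)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                bad = np.argwhere(~np.isclose(self.counts, np.round(self.counts)))[0]
                raise FormatError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"OTU {self.otu_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise ValidationError(f"samples with zero total reads: {empty}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.otu_ids,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(
            sample_ids=[str(i) for i in df.index],
            otu_ids=[str(c) for c in df.columns],
            counts=df.to_numpy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.otu_ids), self.counts[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


def _read_header_ids(path: Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    return header.split("\t")[1:]


def read_otu_table(path: str | Path, orientation: str = "samples_as_rows") -> OtuTable:
    """Read a TSV count table; ``orientation`` names what the rows are.

    The first column holds row identifiers; the header row holds column
    identifiers.  ``orientation='otus_as_rows'`` transposes on read, so both
    layouts yield the same samples x OTUs table.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    col_ids = _read_header_ids(path)
    if len(set(col_ids)) != len(col_ids):
        dup = next(i for i in col_ids if col_ids.count(i) > 1)
        raise FormatError(f"{path}: duplicate column identifier {dup!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate row identifier {dup!r}")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        try:
            numeric = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric cell in column {col!r}: {exc}")
        if (numeric < 0).any():
            row = df.index[int(np.argmax(numeric.to_numpy() < 0))]
            raise FormatError(
                f"{path}: negative count at row {row!r}, column {col!r}"
            )
        arr = numeric.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            row = df.index[int(np.argmax(~np.isclose(arr, np.round(arr))))]
            raise FormatError(
                f"{path}: non-integer count at row {row!r}, column {col!r}"
            )
        values[:, j] = np.round(arr).astype(np.int64)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if orientation == "otus_as_rows":
        return OtuTable(sample_ids=col_ids, otu_ids=row_ids, counts=values.T)
    return OtuTable(sample_ids=row_ids, otu_ids=col_ids, counts=values)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    species: Species
    season: Season


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read a TSV with columns ``sample_id``, ``species``, ``season``.

    Enum labels are matched case-insensitively; "autumn" is accepted as an
    alias for fall.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "species", "season"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: metadata must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    records = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in seen:
            raise ValidationError(f"{path}: duplicate metadata row for sample {sid!r}")
        seen.add(sid)
        records.append(
            SampleRecord(sid, Species.parse(row["species"]), Season.parse(row["season"]))
        )
    return records


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.species.value, r.season.value) for r in records],
        columns=["sample_id", "species", "season"],
    )
    df.to_csv(path, sep="\t", index=False)


def metadata_index(records: Iterable[SampleRecord]) -> dict[str, SampleRecord]:
    return {r.sample_id: r for r in records}


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lineage:
    """An ordered taxonomic path; filled ranks must be contiguous.

    ``names`` maps rank -> taxon name for the filled ranks only.  A filled
    rank below an unfilled one (e.g. genus without family) is rejected,
    except that a lineage may *start* below kingdom (bare ``family;genus``
    exports carry no ranks above family).
    """

    names: tuple[tuple[str, str], ...]  # ((rank, name), ...) in RANKS order

    def __post_init__(self) -> None:
        idx = [RANKS.index(r) for r, _ in self.names]
        if idx != sorted(idx):
            raise FormatError(f"lineage ranks out of order: {self.names}")
        if idx and idx != list(range(idx[0], idx[0] + len(idx))):
            raise FormatError(
                f"lineage has a gap (a filled rank below an empty one): {self.names}"
            )

    def get(self, rank: str) -> str | None:
        for r, n in self.names:
            if r == rank:
                return n
        return None

    @property
    def deepest_rank(self) -> str | None:
        return self.names[-1][0] if self.names else None

    def label_at(self, rank: str) -> str | None:
        """Deepest name at or above ``rank``; falls back to the shallowest
        filled name if the lineage starts below ``rank``."""
        cutoff = RANKS.index(rank)
        best = None
        for r, n in self.names:
            if RANKS.index(r) <= cutoff:
                best = n
        if best is None and self.names:
            best = self.names[0][1]
        return best

    def truncate(self, rank: str) -> "Lineage":
        cutoff = RANKS.index(rank)
        return Lineage(tuple((r, n) for r, n in self.names if RANKS.index(r) <= cutoff))


def parse_lineage(text: str) -> Lineage:
    """Parse a semicolon-delimited lineage string.

    Fields with QIIME-style prefixes (``f__Rosaceae``) are placed at their
    declared rank; bare fields are read positionally as family, genus,
    species (at most three).
    """
    text = text.strip()
    if not text:
        return Lineage(())
    fields = [f.strip() for f in text.split(";") if f.strip()]
    if not fields:
        return Lineage(())
    if any(f[:3] in _RANK_PREFIX for f in fields):
        names = []
        for f in fields:
            if f[:3] not in _RANK_PREFIX:
                raise FormatError(f"mixed prefixed and bare lineage fields: {text!r}")
            names.append((_RANK_PREFIX[f[:3]], f[3:].strip()))
        return Lineage(tuple(names))
    if len(fields) > 3:
        raise FormatError(
            f"bare lineage {text!r} has more than three fields; use k__/p__/... "
            "rank prefixes for lineages above family"
        )
    bare_ranks = ("family", "genus", "species")
    return Lineage(tuple(zip(bare_ranks[: len(fields)], fields)))


def format_lineage(lineage: Lineage) -> str:
    return ";".join(f"{_PREFIX_FOR_RANK[r]}{n}" for r, n in lineage.names)


@dataclass
class TaxonAssignment:
    """Candidate lineages for one OTU; zero candidates means unassigned."""

    otu_id: str
    candidates: list[Lineage] = field(default_factory=list)

    @property
    def is_unassigned(self) -> bool:
        return len(self.candidates) == 0


def read_taxonomy(path: str | Path) -> list[TaxonAssignment]:
    """Read ``otu_id<TAB>lineage`` rows; repeated OTU ids merge into one
    assignment with several candidate lineages.  An empty lineage field marks
    an unassigned OTU."""
    path = Path(path)
    order: list[str] = []
    by_otu: dict[str, TaxonAssignment] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.lower().startswith("otu_id"):
            raise FormatError(f"{path}: expected header starting with 'otu_id'")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            otu_id = parts[0].strip()
            lineage_text = parts[1] if len(parts) > 1 else ""
            if otu_id not in by_otu:
                by_otu[otu_id] = TaxonAssignment(otu_id)
                order.append(otu_id)
            try:
                lineage = parse_lineage(lineage_text)
            except FormatError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from None
            if lineage.names:
                by_otu[otu_id].candidates.append(lineage)
    return [by_otu[o] for o in order]


def write_taxonomy(assignments: Iterable[TaxonAssignment], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("otu_id\tlineage\n")
        for a in assignments:
            if not a.candidates:
                fh.write(f"{a.otu_id}\t\n")
            for c in a.candidates:
                fh.write(f"{a.otu_id}\t{format_lineage(c)}\n")


# ---------------------------------------------------------------------------
# Growth forms
# ---------------------------------------------------------------------------


@dataclass
class GrowthFormMap:
    """Taxon name -> growth form, with species -> genus -> family fallback."""

    forms: dict[str, GrowthForm]

    def lookup(self, taxon: str) -> GrowthForm | None:
        return self.forms.get(taxon)

    def lookup_lineage(self, lineage: Lineage) -> GrowthForm | None:
        for rank in ("species", "genus", "family"):
            name = lineage.get(rank)
            if name is not None and name in self.forms:
                return self.forms[name]
        return None


def read_growth_forms(path: str | Path) -> GrowthFormMap:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"taxon", "growth_form"}.issubset(df.columns):
        raise FormatError(
            f"{path}: growth-form map must have columns ['taxon', 'growth_form']"
        )
    forms: dict[str, GrowthForm] = {}
    for _, row in df.iterrows():
        taxon = str(row["taxon"]).strip()
        form = GrowthForm.parse(row["growth_form"])
        if taxon in forms and forms[taxon] != form:
            raise ValidationError(f"{path}: conflicting growth forms for {taxon!r}")
        forms[taxon] = form
    return GrowthFormMap(forms)


def write_growth_forms(gmap: GrowthFormMap, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted((t, f.value) for t, f in gmap.forms.items()),
        columns=["taxon", "growth_form"],
    )
    df.to_csv(path, sep="\t", index=False)
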
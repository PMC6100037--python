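"""Volatile-compound panels and the aromatic-series taxonomy.

A *compound library* is the panel of volatiles a study quantifies: each
compound carries a chemical class, an odor threshold (μg/kg, the lowest
concentration at which its smell is detectable) and a list of literature
odor descriptors ("green", "rose", "banana", ...).

An *aroma taxonomy* maps descriptors onto ten primary aromatic series
(herbaceous, floral, fruity, sweet, spicy, roasty, fatty, earthy, balsamic,
solvent); the broad fruity/floral/sweet series are subdivided into named
secondary series (apple, rose, honey, ...).  A compound belongs to every
series any of its descriptors maps to, so a compound with three fruity
descriptors simultaneously feeds the fruity primary series and three
secondary series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, TaxonomyError, ValidationError

CHEMICAL_CLASSES: frozenset[str] = frozenset(
    {
        "alcohol",
        "ester",
        "aldehyde",
        "ketone",
        "acid",
        "terpene",
        "C13_norisoprenoid",
        "C6",
        "other",
    }
)

#: The ten primary aromatic series.
PRIMARY_SERIES: tuple[str, ...] = (
    "herbaceous",
    "floral",
    "fruity",
    "sweet",
    "spicy",
    "roasty",
    "fatty",
    "earthy",
    "balsamic",
    "solvent",
)

#: Primary series that are subdivided into secondary series.
SECONDARY_PARENTS: tuple[str, ...] = ("fruity", "floral", "sweet")

_LIBRARY_COLUMNS = ["compound_id", "name", "class", "threshold_ug_per_kg", "descriptors"]
_TAXONOMY_COLUMNS = ["descriptor", "primary_series", "secondary_series"]


def normalize_descriptor(token: str) -> str:
    """Case-fold and whitespace-trim a descriptor token before lookup."""
    return str(token).strip().casefold()


@dataclass(frozen=True)
class Compound:
    """One volatile compound of the panel."""

    compound_id: str
    name: str
    chemical_class: str
    odor_threshold: float
    descriptors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.chemical_class not in CHEMICAL_CLASSES:
            raise ValidationError(
                f"compound {self.compound_id!r}: unknown chemical class "
                f"{self.chemical_class!r}; expected one of {sorted(CHEMICAL_CLASSES)}"
            )
        if not np.isfinite(self.odor_threshold) or self.odor_threshold <= 0:
            raise ValidationError(
                f"compound {self.compound_id!r}: odor threshold must be strictly "
                f"positive, got {self.odor_threshold!r}"
            )
        object.__setattr__(
            self, "descriptors", tuple(normalize_descriptor(d) for d in self.descriptors if str(d).strip())
        )


class CompoundLibrary:
    """An ordered, id-unique collection of :class:`Compound` records."""

    def __init__(self, compounds: Iterable[Compound]):
        self._compounds: dict[str, Compound] = {}
        for c in compounds:
            if c.compound_id in self._compounds:
                raise ValidationError(f"duplicate compound_id {c.compound_id!r}")
            self._compounds[c.compound_id] = c

    def __len__(self) -> int:
        return len(self._compounds)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._compounds.values())

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._compounds

    def __getitem__(self, compound_id: str) -> Compound:
        return self._compounds[compound_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompoundLibrary):
            return NotImplemented
        return list(self) == list(other)

    @property
    def ids(self) -> list[str]:
        return list(self._compounds)

    def thresholds(self) -> pd.Series:
        """Odor thresholds (μg/kg) aligned to :attr:`ids`."""
        return pd.Series({c.compound_id: c.odor_threshold for c in self}, name="threshold_ug_per_kg")

    def classes(self) -> pd.Series:
        return pd.Series({c.compound_id: c.chemical_class for c in self}, name="class")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound_id": c.compound_id,
                "name": c.name,
                "class": c.chemical_class,
                "threshold_ug_per_kg": c.odor_threshold,
                "descriptors": "|".join(c.descriptors),
            }
            for c in self
        ]
        return pd.DataFrame(rows, columns=_LIBRARY_COLUMNS)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CompoundLibrary":
        missing = [c for c in _LIBRARY_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"compound library missing columns: {missing}")
        compounds = []
        for _, row in frame.iterrows():
            raw = row["descriptors"]
            descriptors: tuple[str, ...]
            if pd.isna(raw) or str(raw).strip() == "":
                descriptors = ()
            else:
                descriptors = tuple(str(raw).split("|"))
            try:
                threshold = float(row["threshold_ug_per_kg"])
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"compound {row['compound_id']!r}: non-numeric threshold "
                    f"{row['threshold_ug_per_kg']!r}"
                ) from exc
            compounds.append(
                Compound(
                    compound_id=str(row["compound_id"]),
                    name=str(row["name"]),
                    chemical_class=str(row["class"]),
                    odor_threshold=threshold,
                    descriptors=descriptors,
                )
            )
        return cls(compounds)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, comment="#", dtype=str)


def load_compound_library(path: str | Path) -> CompoundLibrary:
    """Load and validate a compound panel from a CSV/TSV file.

    The table must have columns ``compound_id, name, class,
    threshold_ug_per_kg, descriptors`` (pipe-separated descriptor list).
    Duplicate ids and non-positive thresholds are rejected.
    """
    return CompoundLibrary.from_frame(_read_table(path))


def default_compound_library() -> CompoundLibrary:
    """The example table-grape panel shipped with the package."""
    with resources.as_file(resources.files("grapearoma.data") / "default_compounds.csv") as p:
        return load_compound_library(p)


@dataclass
class AromaTaxonomy:
    """Descriptor → aromatic-series mapping.

    ``primary_of`` assigns every descriptor exactly one primary series;
    ``secondary_of`` assigns descriptors whose primary series is fruity,
    floral or sweet a (possibly empty) set of secondary series;
    ``secondary_parent`` records which primary series each secondary series
    subdivides.
    """

    primary_of: dict[str, str]
    secondary_of: dict[str, frozenset[str]] = field(default_factory=dict)
    secondary_parent: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.primary_of:
            raise TaxonomyError("empty taxonomy: no descriptor rows")
        for desc, primary in self.primary_of.items():
            if primary not in PRIMARY_SERIES:
                raise TaxonomyError(f"descriptor {desc!r}: unknown primary series {primary!r}")
        for desc, secondaries in self.secondary_of.items():
            primary = self.primary_of.get(desc)
            if primary is None:
                raise TaxonomyError(f"secondary mapping for unknown descriptor {desc!r}")
            if secondaries and primary not in SECONDARY_PARENTS:
                raise TaxonomyError(
                    f"descriptor {desc!r}: secondary series under primary {primary!r}; "
                    f"only {SECONDARY_PARENTS} may carry secondary series"
                )
            for s in secondaries:
                parent = self.secondary_parent.get(s)
                if parent is None:
                    self.secondary_parent[s] = primary
                elif parent != primary:
                    raise TaxonomyError(
                        f"secondary series {s!r} claimed by two primaries: {parent!r} and {primary!r}"
                    )

    @property
    def primary_series(self) -> frozenset[str]:
        """Primary series actually used by at least one descriptor."""
        return frozenset(self.primary_of.values())

    def secondary_series(self, parent: str | None = None) -> frozenset[str]:
        if parent is None:
            return frozenset(self.secondary_parent)
        return frozenset(s for s, p in self.secondary_parent.items() if p == parent)

    def lookup(self, descriptor: str) -> tuple[str, frozenset[str]] | None:
        """Return (primary, secondaries) for a descriptor, or None if unmapped."""
        desc = normalize_descriptor(descriptor)
        primary = self.primary_of.get(desc)
        if primary is None:
            return None
        return primary, self.secondary_of.get(desc, frozenset())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "descriptor": d,
                "primary_series": p,
                "secondary_series": "|".join(sorted(self.secondary_of.get(d, frozenset()))),
            }
            for d, p in self.primary_of.items()
        ]
        return pd.DataFrame(rows, columns=_TAXONOMY_COLUMNS)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_taxonomy(path: str | Path) -> AromaTaxonomy:
    """Load a descriptor → series taxonomy from CSV/TSV.

    Columns: ``descriptor, primary_series, secondary_series`` (pipe-separated,
    optional).  A descriptor mapped to two different primaries is a conflict
    error; secondary series under a primary other than fruity/floral/sweet
    are rejected.
    """
    frame = _read_table(path)
    missing = [c for c in _TAXONOMY_COLUMNS[:2] if c not in frame.columns]
    if missing:
        raise FormatError(f"taxonomy missing columns: {missing}")
    if frame.empty:
        raise TaxonomyError(f"empty taxonomy file: {path}")
    primary_of: dict[str, str] = {}
    secondary_of: dict[str, frozenset[str]] = {}
    for _, row in frame.iterrows():
        desc = normalize_descriptor(row["descriptor"])
        primary = str(row["primary_series"]).strip()
        if desc in primary_of and primary_of[desc] != primary:
            raise TaxonomyError(
                f"descriptor {desc!r} mapped to two primaries: "
                f"{primary_of[desc]!r} and {primary!r}"
            )
        primary_of[desc] = primary
        raw = row.get("secondary_series", "")
        if pd.isna(raw) or str(raw).strip() == "":
            secondaries: frozenset[str] = frozenset()
        else:
            secondaries = frozenset(normalize_descriptor(s) for s in str(raw).split("|") if s.strip())
        if desc in secondary_of:
            secondaries = secondary_of[desc] | secondaries
        secondary_of[desc] = secondaries
    return AromaTaxonomy(primary_of=primary_of, secondary_of=secondary_of)


def default_taxonomy() -> AromaTaxonomy:
    """The shipped default taxonomy: 10 primary series, 14/13/5 secondary
    series under fruity/floral/sweet (named where the literature names them,
    labelled placeholders otherwise)."""
    with resources.as_file(resources.files("grapearoma.data") / "default_taxonomy.csv") as p:
        return load_taxonomy(p)


@dataclass(frozen=True)
class SeriesMembership:
    """The aromatic series a single compound contributes to."""

    compound_id: str
    primary_series: frozenset[str]
    secondary_series: frozenset[str]


@dataclass
class MembershipTable:
    """Resolved memberships for a whole library plus unmapped-descriptor warnings."""

    memberships: list[SeriesMembership]
    warnings: list[str]

    def __iter__(self) -> Iterator[SeriesMembership]:
        return iter(self.memberships)

    def __len__(self) -> int:
        return len(self.memberships)

    def by_compound(self) -> Mapping[str, SeriesMembership]:
        return {m.compound_id: m for m in self.memberships}

    def members_of(self, series: str, level: str) -> list[str]:
        attr = "primary_series" if level == "primary" else "secondary_series"
        return [m.compound_id for m in self.memberships if series in getattr(m, attr)]


def resolve_memberships(library: CompoundLibrary, taxonomy: AromaTaxonomy) -> MembershipTable:
    """Resolve each compound's series memberships from its odor descriptors.

    A compound with k descriptors contributes to the union of the series its
    descriptors map to; it simultaneously joins each matching primary series
    and all matching secondary series.  Descriptors absent from the taxonomy
    (and compounds without any descriptor) produce warnings, never errors.
    """
    memberships: list[SeriesMembership] = []
    warnings: list[str] = []
    for compound in library:
        primaries: set[str] = set()
        secondaries: set[str] = set()
        if not compound.descriptors:
            warnings.append(f"compound {compound.compound_id!r} has no descriptors")
        for desc in compound.descriptors:
            hit = taxonomy.lookup(desc)
            if hit is None:
                warnings.append(
                    f"compound {compound.compound_id!r}: descriptor {desc!r} not in taxonomy"
                )
                continue
            primary, secs = hit
            primaries.add(primary)
            secondaries |= secs
        memberships.append(
            SeriesMembership(
                compound_id=compound.compound_id,
                primary_series=frozenset(primaries),
                secondary_series=frozenset(secondaries),
            )
        )
    return MembershipTable(memberships=memberships, warnings=warnings)
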
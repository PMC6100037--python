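"""Odor activity values, aromatic-series aggregation and aroma fingerprints.

The odor activity value (OAV) of a compound in a sample is its
concentration divided by its odor threshold; compounds with OAV > 1 are
perceptible ("aroma-active").  An aromatic series' value in a sample is the
sum of the OAVs of its member compounds; a compound that belongs to several
series (through several descriptors) contributes its full OAV to each of
them.  Series values at or above 1 in at least one sample count as active
series.  A cultivar's aroma fingerprint collects its per-tissue primary-
and secondary-series values for radial ("aroma wheel") display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compound_library import AromaTaxonomy, MembershipTable, PRIMARY_SERIES
from .errors import ValidationError
from .profiles import SampleSet

#: Compounds strictly above this OAV are aroma-active.
ACTIVE_COMPOUND_CUTOFF: float = 1.0
#: Series at or above this value in at least one sample are active.
ACTIVE_SERIES_CUTOFF: float = 1.0


@dataclass
class OavTable:
    """Per-sample, per-compound odor activity values."""

    values: pd.DataFrame          # index (cultivar, tissue, replicate), columns compounds
    active_cutoff: float = ACTIVE_COMPOUND_CUTOFF

    def replicate_means(self) -> pd.DataFrame:
        """OAVs averaged over replicates, indexed by (cultivar, tissue)."""
        return self.values.groupby(level=["cultivar_id", "tissue"]).mean()


def compute_oav(sset: SampleSet, active_cutoff: float = ACTIVE_COMPOUND_CUTOFF) -> OavTable:
    """Element-wise concentration / odor-threshold table.

    An absent (not-detected) concentration yields OAV 0; thresholds are
    strictly positive by library invariant, so every OAV is finite.
    """
    thresholds = sset.library.thresholds().reindex(sset.data.columns)
    return OavTable(values=sset.data / thresholds, active_cutoff=active_cutoff)


@dataclass
class ActiveCompounds:
    """Aroma-active compounds (OAV strictly above the cutoff)."""

    per_sample: pd.DataFrame      # boolean mask, same shape as the OAV table
    pooled_by_tissue: dict[str, frozenset[str]]
    pooled: frozenset[str]


def active_compounds(table: OavTable) -> ActiveCompounds:
    """Per-sample and pooled sets of compounds with OAV > cutoff.

    The pooled set of a tissue is the union over that tissue's samples; the
    overall pooled set is the union over all samples.
    """
    mask = table.values > table.active_cutoff
    pooled_by_tissue: dict[str, frozenset[str]] = {}
    for tissue in sorted(set(mask.index.get_level_values("tissue"))):
        sub = mask.xs(tissue, level="tissue")
        pooled_by_tissue[tissue] = frozenset(sub.columns[sub.any(axis=0)])
    pooled = frozenset(mask.columns[mask.any(axis=0)])
    return ActiveCompounds(per_sample=mask, pooled_by_tissue=pooled_by_tissue, pooled=pooled)


@dataclass
class SeriesProfile:
    """Per-sample aromatic-series values (sums of member-compound OAVs)."""

    level: str                    # "primary" | "secondary"
    values: pd.DataFrame          # index (cultivar, tissue, replicate), columns series

    def replicate_stats(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(mean, SD) over replicates, indexed by (cultivar, tissue)."""
        grouped = self.values.groupby(level=["cultivar_id", "tissue"])
        return grouped.mean(), grouped.std(ddof=1)


def series_values(
    table: OavTable,
    memberships: MembershipTable,
    level: str = "primary",
    taxonomy: AromaTaxonomy | None = None,
) -> SeriesProfile:
    """Aggregate OAVs into aromatic-series values.

    The value of series S in sample k is the sum of OAV(k, c) over member
    compounds c; multi-membership compounds contribute their full OAV to
    every series they belong to.  If a taxonomy is supplied, series without
    any member compound are included as all-zero columns (useful for
    complete fingerprints).
    """
    if level not in ("primary", "secondary"):
        raise ValidationError(f"level must be 'primary' or 'secondary', got {level!r}")
    attr = "primary_series" if level == "primary" else "secondary_series"
    series_names: set[str] = set()
    for m in memberships:
        series_names |= getattr(m, attr)
    if taxonomy is not None:
        if level == "primary":
            series_names |= set(PRIMARY_SERIES)
        else:
            series_names |= set(taxonomy.secondary_series())
    columns = sorted(series_names)
    out = pd.DataFrame(0.0, index=table.values.index, columns=columns)
    by_compound = memberships.by_compound()
    for cid in table.values.columns:
        m = by_compound.get(cid)
        if m is None:
            continue
        for s in getattr(m, attr):
            out[s] += table.values[cid]
    return SeriesProfile(level=level, values=out)


def active_series(profile: SeriesProfile, cutoff: float = ACTIVE_SERIES_CUTOFF) -> frozenset[str]:
    """Series whose value reaches the cutoff (inclusive) in at least one
    sample; series below the cutoff everywhere carry no active aroma."""
    mask = (profile.values >= cutoff).any(axis=0)
    return frozenset(profile.values.columns[mask])


@dataclass
class Fingerprint:
    """A cultivar's per-tissue primary/secondary aromatic-series values.

    ``display_halved`` is export metadata only: renderers may halve the
    listed series for readability, the stored values are never transformed.
    """

    cultivar_id: str
    primary: dict[str, dict[str, float]]     # tissue -> series -> replicate-mean value
    secondary: dict[str, dict[str, float]]
    display_halved: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "cultivar_id": self.cultivar_id,
            "primary": self.primary,
            "secondary": self.secondary,
            "display_halved": list(self.display_halved),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def build_fingerprint(
    primary_profile: SeriesProfile,
    secondary_profile: SeriesProfile,
    cultivar_id: str,
    tissues: tuple[str, ...] = ("pulp", "skin"),
    display_halved: tuple[str, ...] = (),
) -> Fingerprint:
    """Assemble a cultivar's aroma fingerprint from series profiles.

    Requires both profiles to contain every requested tissue for the
    cultivar; values are replicate means.
    """
    prim_mean, _ = primary_profile.replicate_stats()
    sec_mean, _ = secondary_profile.replicate_stats()
    primary: dict[str, dict[str, float]] = {}
    secondary: dict[str, dict[str, float]] = {}
    for tissue in tissues:
        key = (cultivar_id, tissue)
        if key not in prim_mean.index or key not in sec_mean.index:
            raise ValidationError(f"missing tissue {tissue!r} for cultivar {cultivar_id!r}")
        primary[tissue] = {s: float(v) for s, v in prim_mean.loc[key].items()}
        secondary[tissue] = {s: float(v) for s, v in sec_mean.loc[key].items()}
    return Fingerprint(
        cultivar_id=cultivar_id,
        primary=primary,
        secondary=secondary,
        display_halved=tuple(display_halved),
    )
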
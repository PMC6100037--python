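"""Per-sample volatile concentration tables and maturity metadata.

Samples are indexed by (cultivar, tissue, replicate); tissues form the
closed vocabulary {pulp, skin, whole}.  Concentrations are μg/kg, stored in
a wide matrix whose columns are the compound panel; a compound that was not
detected is stored as 0.  Maturity records carry the standard ripeness
chemistry (TSS °Brix, titratable acidity g/L, pH, berry weight g); table
grapes count as ripe at TSS ≥ 16 °Brix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .compound_library import CompoundLibrary
from .errors import FormatError, ReferenceError_, ValidationError

TISSUES: tuple[str, ...] = ("pulp", "skin", "whole")

#: OIV ripeness rule for table grapes.
RIPENESS_TSS_BRIX: float = 16.0

_SAMPLE_COLUMNS = ["cultivar_id", "tissue", "replicate", "compound_id", "concentration_ug_per_kg"]
_MATURITY_COLUMNS = ["cultivar_id", "tss_brix", "ta_g_per_l", "ph", "berry_weight_g"]
_INDEX_NAMES = ["cultivar_id", "tissue", "replicate"]


@dataclass(frozen=True)
class SampleKey:
    """Identifies one biological sample."""

    cultivar_id: str
    tissue: str
    replicate: int

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if int(self.replicate) < 1:
            raise ValidationError(f"replicate must be a positive integer, got {self.replicate!r}")

    def as_tuple(self) -> tuple[str, str, int]:
        return (self.cultivar_id, self.tissue, int(self.replicate))


@dataclass(frozen=True)
class MaturityRecord:
    cultivar_id: str
    tss: float
    ta: float
    ph: float
    berry_weight: float

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"{self.cultivar_id}: TSS must be >= 0 °Brix")
        if self.ta <= 0:
            raise ValidationError(f"{self.cultivar_id}: TA must be > 0 g/L so TSS/TA is defined")


class SampleSet:
    """A validated cultivar × tissue × replicate concentration matrix.

    Parameters
    ----------
    data
        Wide matrix: rows indexed by (cultivar_id, tissue, replicate),
        columns = compound ids, values μg/kg (0 = not detected).
    library
        The compound panel the columns refer to.
    maturity
        Optional frame indexed by cultivar_id with columns tss_brix,
        ta_g_per_l, ph, berry_weight_g.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        library: CompoundLibrary,
        maturity: pd.DataFrame | None = None,
    ):
        unknown = [c for c in data.columns if c not in library]
        if unknown:
            raise ReferenceError_(f"columns not in compound library: {unknown}")
        if data.index.nlevels != 3:
            raise FormatError("sample index must be (cultivar_id, tissue, replicate)")
        data = data.copy()
        data.index = data.index.set_names(_INDEX_NAMES)
        bad_tissue = sorted(set(data.index.get_level_values("tissue")) - set(TISSUES))
        if bad_tissue:
            raise ValidationError(f"unknown tissue tokens: {bad_tissue}")
        if data.index.duplicated().any():
            dupes = data.index[data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample keys: {dupes}")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("non-finite concentration values")
        if (values < 0).any():
            rows = data.index[(values < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative concentrations in samples: {rows}")
        # Align columns to the library order, absent compounds -> 0.
        self.data = data.reindex(columns=library.ids, fill_value=0.0).astype(float)
        self.data = self.data.sort_index()
        self.library = library
        if maturity is not None:
            maturity = maturity.copy()
            maturity.index = maturity.index.astype(str)
        self.maturity = maturity

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleSet):
            return NotImplemented
        return self.data.equals(other.data) and self.library == other.library

    @property
    def cultivars(self) -> list[str]:
        return sorted(set(self.data.index.get_level_values("cultivar_id")))

    @property
    def tissues(self) -> list[str]:
        return sorted(set(self.data.index.get_level_values("tissue")))

    def vector(self, key: SampleKey) -> pd.Series:
        try:
            return self.data.loc[key.as_tuple()]
        except KeyError as exc:
            raise ReferenceError_(f"no such sample: {key}") from exc

    def tissue(self, tissue: str) -> pd.DataFrame:
        if tissue not in TISSUES:
            raise ValidationError(f"unknown tissue {tissue!r}")
        return self.data.xs(tissue, level="tissue")

    def cultivar_means(self, tissue: str) -> pd.DataFrame:
        """Replicate-mean concentrations, cultivars × compounds."""
        return self.tissue(tissue).groupby(level="cultivar_id").mean()

    # -- persistence -------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        long = self.data.stack().rename("concentration_ug_per_kg").reset_index()
        long = long.rename(columns={"level_3": "compound_id"})
        long.columns = _SAMPLE_COLUMNS
        return long[long["concentration_ug_per_kg"] > 0].reset_index(drop=True)

    def save(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)

    def save_maturity(self, path: str | Path) -> None:
        if self.maturity is None:
            raise ValidationError("no maturity records to save")
        out = self.maturity.reset_index()
        out.columns = _MATURITY_COLUMNS
        out.to_csv(path, index=False)

    # -- analysis ----------------------------------------------------------
    def screen_maturity(self) -> pd.DataFrame:
        """Per-cultivar ripeness report: tss, ta, tss/ta ratio and a ripe
        flag (TSS ≥ 16 °Brix).  Unripe cultivars are flagged, never removed;
        removal is a pipeline option.  Concentrations are not touched.
        """
        if self.maturity is None:
            raise ValidationError("sample set has no maturity records")
        missing = [c for c in self.cultivars if c not in self.maturity.index]
        if missing:
            raise ValidationError(f"missing maturity records for cultivars: {missing}")
        report = self.maturity.loc[self.cultivars, ["tss_brix", "ta_g_per_l"]].copy()
        report["tss_ta_ratio"] = report["tss_brix"] / report["ta_g_per_l"]
        report["ripe"] = report["tss_brix"] >= RIPENESS_TSS_BRIX
        return report

    def combine_tissues(self, skin_mass_fraction: float = 0.2) -> "SampleSet":
        """Blend pulp and skin into whole-berry samples.

        whole = f·skin + (1−f)·pulp per compound and replicate, with f the
        skin mass fraction.  Original pulp/skin samples are retained; any
        pre-existing whole samples are replaced.
        """
        if not 0.0 <= skin_mass_fraction <= 1.0:
            raise ValidationError("skin_mass_fraction must lie in [0, 1]")
        pulp = self.data.xs("pulp", level="tissue")
        skin = self.data.xs("skin", level="tissue")
        missing = sorted(set(pulp.index).symmetric_difference(set(skin.index)))
        if missing:
            raise ValidationError(
                f"pulp/skin replicate pairs unmatched for (cultivar, replicate): {missing}"
            )
        whole = skin_mass_fraction * skin + (1.0 - skin_mass_fraction) * pulp
        whole.index = pd.MultiIndex.from_tuples(
            [(c, "whole", r) for c, r in whole.index], names=_INDEX_NAMES
        )
        base = self.data[self.data.index.get_level_values("tissue") != "whole"]
        data = pd.concat([base, whole]).sort_index()
        return SampleSet(data, self.library, self.maturity)


def load_samples(
    path: str | Path,
    library: CompoundLibrary,
    maturity_path: str | Path | None = None,
) -> SampleSet:
    """Load a long-format concentration table into a :class:`SampleSet`.

    Rows: ``cultivar_id, tissue, replicate, compound_id,
    concentration_ug_per_kg``.  Unknown compound ids, negative
    concentrations and duplicate (sample, compound) rows are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    long = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in _SAMPLE_COLUMNS if c not in long.columns]
    if missing:
        raise FormatError(f"sample table missing columns: {missing}")
    long["cultivar_id"] = long["cultivar_id"].astype(str)
    long["compound_id"] = long["compound_id"].astype(str)
    unknown = sorted(set(long["compound_id"]) - set(library.ids))
    if unknown:
        raise ReferenceError_(f"unknown compound ids: {unknown}")
    dup_mask = long.duplicated(subset=["cultivar_id", "tissue", "replicate", "compound_id"], keep=False)
    if dup_mask.any():
        dupes = (
            long.loc[dup_mask, ["cultivar_id", "tissue", "replicate", "compound_id"]]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()
        )
        raise ValidationError(f"duplicate (sample, compound) rows: {dupes}")
    wide = long.pivot_table(
        index=["cultivar_id", "tissue", "replicate"],
        columns="compound_id",
        values="concentration_ug_per_kg",
        fill_value=0.0,
        aggfunc="sum",
    )
    wide.columns.name = None
    maturity = None
    if maturity_path is not None:
        maturity = load_maturity(maturity_path)
    return SampleSet(wide, library, maturity)


def load_maturity(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in _MATURITY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"maturity table missing columns: {missing}")
    for _, row in frame.iterrows():
        MaturityRecord(
            cultivar_id=str(row["cultivar_id"]),
            tss=float(row["tss_brix"]),
            ta=float(row["ta_g_per_l"]),
            ph=float(row["ph"]),
            berry_weight=float(row["berry_weight_g"]),
        )
    return frame.set_index(frame["cultivar_id"].astype(str))[_MATURITY_COLUMNS[1:]]
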
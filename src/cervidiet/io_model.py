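"""Typed tabular containers and TSV/CSV readers/writers.

Every pipeline stage consumes and produces the table types defined here.
Each type wraps a :class:`pandas.DataFrame` with a fixed set of key columns
(and, for the *wide* types, an open set of value columns: MOTU read counts
or taxon proportions) and validates its invariants on construction.

On-disk format is TSV (canonical) or CSV (accepted; delimiter sniffed from
the header line), decimal point only.  Proportions are stored on [0, 1];
the MOTU best-match similarity is kept in percent because that is how the
filtering threshold (95%) is universally quoted.  Taxonomy paths are
serialized as a single semicolon-delimited string ``family;genus;species``
with empty trailing ranks omitted.
"""

from __future__ import annotations

import math
from typing import Iterable, Type, TypeVar

import numpy as np
import pandas as pd

SPECIES = ("moose", "roe", "red", "fallow")
LANDSCAPES = ("coastal_boreal", "boreo_nemoral")
SEASONS = ("winter", "spring", "summer_autumn")
MARKERS = ("mammal", "plant")
CONTROL_KINDS = ("none", "extraction_blank", "pcr_negative", "pcr_positive",
                 "primer_blank")
#: Browsing-height range surveyed for each deer species (step-point method).
HEIGHT_RANGES = ("0-1.5m", "0-1.8m", "0-2.3m", "0-3m")
SPECIES_HEIGHT_RANGE = {
    "roe": "0-1.5m",
    "fallow": "0-1.8m",
    "red": "0-2.3m",
    "moose": "0-3m",
}

#: Month (1-12) -> season. Winter = Nov-Mar, spring = Apr-May, the growing
#: season Jun-Oct is pooled as summer_autumn.
MONTH_SEASON = {11: "winter", 12: "winter", 1: "winter", 2: "winter",
                3: "winter", 4: "spring", 5: "spring", 6: "summer_autumn",
                7: "summer_autumn", 8: "summer_autumn", 9: "summer_autumn",
                10: "summer_autumn"}


class SchemaError(ValueError):
    """A required column is missing or has the wrong kind of values."""


class ValidationError(ValueError):
    """A row violates a table invariant."""


T = TypeVar("T", bound="TypedTable")


class TypedTable:
    """Base class: a validated DataFrame with fixed key columns.

    Subclasses set ``FIXED`` (ordered key columns), ``WIDE`` (whether extra
    value columns are allowed/required), ``VALUE_DTYPE`` ("int" or "float"
    for wide value columns) and implement ``_validate``.
    """

    FIXED: tuple[str, ...] = ()
    WIDE: bool = False
    VALUE_DTYPE: str = "float"
    STRING_COLS: tuple[str, ...] = ()

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in self.FIXED if c not in frame.columns]
        if missing:
            raise SchemaError(
                f"{type(self).__name__}: missing required column(s) "
                + ", ".join(missing))
        value_cols = [c for c in frame.columns if c not in self.FIXED]
        if self.WIDE:
            if not value_cols:
                raise SchemaError(
                    f"{type(self).__name__}: needs at least one value column")
            value_cols = sorted(value_cols)
        elif value_cols:
            raise SchemaError(
                f"{type(self).__name__}: unexpected column(s) "
                + ", ".join(value_cols))
        frame = frame[list(self.FIXED) + value_cols]
        for c in self.STRING_COLS:
            frame[c] = frame[c].fillna("").astype(str)
        if self.WIDE and len(frame):
            dtype = np.int64 if self.VALUE_DTYPE == "int" else np.float64
            try:
                frame[value_cols] = frame[value_cols].astype(dtype)
            except (ValueError, TypeError) as exc:
                raise SchemaError(
                    f"{type(self).__name__}: value columns must be "
                    f"{self.VALUE_DTYPE}: {exc}") from None
        frame = frame.reset_index(drop=True)
        self._validate(frame, value_cols)
        self.frame = frame
        self.value_columns = value_cols

    def _validate(self, frame: pd.DataFrame, value_cols: list[str]) -> None:
        pass

    # -- convenience -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def equals(self, other: "TypedTable", tol: float = 1e-12) -> bool:
        """Round-trip equality: exact on keys/ints, ``tol`` on floats."""
        a, b = self.frame, other.frame
        if type(self) is not type(other) or list(a.columns) != list(b.columns):
            return False
        if len(a) != len(b):
            return False
        for c in a.columns:
            if pd.api.types.is_float_dtype(a[c]):
                if not np.allclose(a[c].to_numpy(), b[c].to_numpy(),
                                   atol=tol, rtol=0, equal_nan=True):
                    return False
            else:
                if not a[c].equals(b[c]):
                    return False
        return True

    @staticmethod
    def _require_enum(frame: pd.DataFrame, col: str,
                      allowed: Iterable[str]) -> None:
        bad = set(frame[col].astype(str)) - set(allowed)
        if bad:
            raise ValidationError(f"column {col!r}: invalid value(s) {bad}")


class ReadCountTable(TypedTable):
    """PCR-replicate x MOTU integer read counts, with control annotations."""

    FIXED = ("pcr_id", "sample_id", "marker", "replicate_index",
             "control_kind")
    WIDE = True
    VALUE_DTYPE = "int"
    STRING_COLS = ("pcr_id", "sample_id", "marker", "control_kind")

    def _validate(self, frame, value_cols):
        self._require_enum(frame, "marker", MARKERS)
        self._require_enum(frame, "control_kind", CONTROL_KINDS)
        counts = frame[value_cols].to_numpy()
        if len(frame) and (counts < 0).any():
            row = int(np.argwhere((counts < 0).any(axis=1))[0][0])
            raise ValidationError(f"negative read count in row {row}")
        rep = frame["replicate_index"].to_numpy()
        if len(frame) and (rep < 1).any():
            raise ValidationError("replicate_index must be >= 1")
        is_sample = (frame["control_kind"] == "none")
        if (is_sample & (frame["sample_id"] == "")).any():
            raise ValidationError(
                "non-control rows must carry a sample_id")
        keyed = frame.loc[frame["sample_id"] != "",
                          ["sample_id", "marker", "replicate_index"]]
        dup = keyed.duplicated()
        if dup.any():
            row = int(dup.idxmax())
            raise ValidationError(
                f"duplicate (sample_id, marker, replicate_index) at row {row}")

    @property
    def motus(self) -> list[str]:
        return self.value_columns

    def samples(self) -> "ReadCountTable":
        return ReadCountTable(self.frame[self.frame["control_kind"] == "none"])

    def controls(self) -> pd.DataFrame:
        return self.frame[self.frame["control_kind"] != "none"]


class MOTUCatalog(TypedTable):
    """Per-MOTU marker, amplicon length, best-match similarity, taxonomy."""

    FIXED = ("motu_id", "marker", "length_bp", "best_similarity",
             "taxonomy", "is_reference_exact")
    STRING_COLS = ("motu_id", "marker", "taxonomy")

    def _validate(self, frame, value_cols):
        self._require_enum(frame, "marker", MARKERS)
        if frame["motu_id"].duplicated().any():
            raise ValidationError("motu_id values must be unique")
        if len(frame) and (frame["length_bp"].to_numpy() <= 0).any():
            raise ValidationError("length_bp must be > 0")
        sim = frame["best_similarity"].to_numpy(dtype=float)
        if len(frame) and ((sim < 0) | (sim > 100)).any():
            raise ValidationError("best_similarity must be in [0, 100]")
        if (frame["taxonomy"] == "").any():
            raise ValidationError(
                "taxonomy path must be non-empty (use 'unassigned')")
        frame["is_reference_exact"] = _as_bool(frame["is_reference_exact"])

    def taxonomy_rank(self, rank: str) -> pd.Series:
        """Name at ``rank`` ('family'|'genus'|'species') per MOTU.

        Missing ranks fall back to the deepest available name.
        """
        idx = {"family": 0, "genus": 1, "species": 2}[rank]

        def pick(path: str) -> str:
            parts = path.split(";")
            return parts[idx] if idx < len(parts) else parts[-1]

        return pd.Series([pick(t) for t in self.frame["taxonomy"]],
                         index=self.frame["motu_id"].to_numpy())


class SampleMetadata(TypedTable):
    FIXED = ("sample_id", "transect_id", "landscape", "season",
             "collection_date", "putative_species")
    STRING_COLS = ("sample_id", "transect_id", "landscape", "season",
                   "collection_date", "putative_species")

    def _validate(self, frame, value_cols):
        self._require_enum(frame, "landscape", LANDSCAPES)
        self._require_enum(frame, "season", SEASONS)
        self._require_enum(frame, "putative_species", SPECIES + ("unknown",))
        if frame["sample_id"].duplicated().any():
            raise ValidationError("sample_id values must be unique")
        months = pd.to_datetime(frame["collection_date"]).dt.month
        expect = months.map(MONTH_SEASON)
        bad = expect.to_numpy() != frame["season"].to_numpy()
        if bad.any():
            row = int(np.argwhere(bad)[0][0])
            raise ValidationError(
                f"season inconsistent with collection_date in row {row}")


class DietProfile(TypedTable):
    """sample x taxon relative-read-abundance matrix; rows sum to 1."""

    FIXED = ("sample_id",)
    WIDE = True
    VALUE_DTYPE = "float"
    STRING_COLS = ("sample_id",)

    def _validate(self, frame, value_cols):
        if frame["sample_id"].duplicated().any():
            raise ValidationError("sample_id values must be unique")
        vals = frame[value_cols].to_numpy()
        if len(frame):
            if (vals < -1e-12).any():
                raise ValidationError("RRA values must be >= 0")
            sums = vals.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                row = int(np.argwhere(bad)[0][0])
                raise ValidationError(
                    f"row {row} ({frame['sample_id'][row]}): RRA sums to "
                    f"{sums[row]:.6g}, expected 1")

    @property
    def taxa(self) -> list[str]:
        return self.value_columns

    def matrix(self) -> np.ndarray:
        return self.frame[self.value_columns].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.frame["sample_id"].to_numpy()


class AvailabilityTable(TypedTable):
    """Step-point forage availability by transect, season, height range."""

    FIXED = ("transect_id", "season", "height_range", "category",
             "proportion")
    STRING_COLS = ("transect_id", "season", "height_range", "category")

    def _validate(self, frame, value_cols):
        self._require_enum(frame, "season", SEASONS)
        self._require_enum(frame, "height_range", HEIGHT_RANGES)
        p = frame["proportion"].to_numpy(dtype=float)
        if len(frame) and ((p < 0) | (p > 1)).any():
            raise ValidationError("proportion must be in [0, 1]")
        if len(frame):
            sums = frame.groupby(
                ["transect_id", "season", "height_range"])["proportion"].sum()
            bad = sums[np.abs(sums - 1.0) > 1e-9]
            if len(bad):
                raise ValidationError(
                    f"availability proportions do not sum to 1 for "
                    f"{bad.index[0]}")


class PelletCountTable(TypedTable):
    FIXED = ("transect_id", "year", "plot_id", "plot_area_m2",
             "species_class", "pellet_groups", "surveyed")
    STRING_COLS = ("transect_id", "species_class")

    def _validate(self, frame, value_cols):
        self._require_enum(frame, "species_class", ("large", "small"))
        if len(frame):
            areas = set(frame["plot_area_m2"].to_numpy(dtype=float))
            if not areas <= {10.0, 100.0}:
                raise ValidationError("plot_area_m2 must be 10 or 100")
            if (frame["pellet_groups"].to_numpy() < 0).any():
                raise ValidationError("pellet_groups must be >= 0")
            pid = frame["plot_id"].to_numpy()
            if ((pid < 1) | (pid > 16)).any():
                raise ValidationError("plot_id must be in 1..16")
        frame["surveyed"] = _as_bool(frame["surveyed"])


class CovariateTable(TypedTable):
    FIXED = ("transect_id", "cervid_index", "habitat_shannon", "arable_prop")
    STRING_COLS = ("transect_id",)

    def _validate(self, frame, value_cols):
        if frame["transect_id"].duplicated().any():
            raise ValidationError("transect_id values must be unique")
        if len(frame):
            if (frame["cervid_index"].to_numpy(dtype=float) < 0).any():
                raise ValidationError("cervid_index must be >= 0")
            if (frame["habitat_shannon"].to_numpy(dtype=float) < 0).any():
                raise ValidationError("habitat_shannon must be >= 0")
            a = frame["arable_prop"].to_numpy(dtype=float)
            if ((a < 0) | (a > 1)).any():
                raise ValidationError("arable_prop must be in [0, 1]")


class OverlapTable(TypedTable):
    """Per transect x season Pianka overlap, intra- or interspecific."""

    FIXED = ("transect_id", "season", "landscape", "kind", "species_a",
             "species_b", "pianka", "n_samples_a", "n_samples_b")
    STRING_COLS = ("transect_id", "season", "landscape", "kind",
                   "species_a", "species_b")

    def _validate(self, frame, value_cols):
        self._require_enum(frame, "season", SEASONS)
        self._require_enum(frame, "landscape", LANDSCAPES)
        self._require_enum(frame, "kind", ("intra", "inter"))
        self._require_enum(frame, "species_a", SPECIES)
        self._require_enum(frame, "species_b", SPECIES)
        o = frame["pianka"].to_numpy(dtype=float)
        if len(frame) and ((o < -1e-12) | (o > 1 + 1e-12)).any():
            raise ValidationError("pianka must be in [0, 1]")
        intra = frame["kind"] == "intra"
        if (intra & (frame["species_a"] != frame["species_b"])).any():
            raise ValidationError(
                "intra rows must have species_a == species_b")


class HostAssignmentTable(TypedTable):
    """Output of the host-species assignment stage."""

    FIXED = ("sample_id", "status", "assigned_species", "dominant_motu",
             "dominance_ratio")
    STRING_COLS = ("sample_id", "status", "assigned_species",
                   "dominant_motu")

    def _validate(self, frame, value_cols):
        self._require_enum(frame, "status",
                           ("assigned", "discarded_low_reads",
                            "discarded_ambiguous",
                            "discarded_no_reference_match"))


class ReplicateQCTable(TypedTable):
    """Per-replicate QC verdicts from the plant-marker consistency filter."""

    FIXED = ("sample_id", "replicate_index", "status",
             "distance_to_barycenter", "threshold_used")
    STRING_COLS = ("sample_id", "status")

    def _validate(self, frame, value_cols):
        self._require_enum(frame, "status",
                           ("kept", "discarded_distance",
                            "discarded_low_reads", "discarded_control_like"))


def _as_bool(s: pd.Series) -> pd.Series:
    if pd.api.types.is_bool_dtype(s):
        return s
    mapping = {"true": True, "false": False, "True": True, "False": False,
               True: True, False: False, 1: True, 0: False, "1": True,
               "0": False}
    try:
        return s.map(mapping).astype(bool)
    except Exception as exc:
        raise SchemaError(f"cannot parse boolean column: {exc}") from None


def taxonomy_path(family: str, genus: str = "", species: str = "") -> str:
    """Serialize a rank path, omitting empty trailing ranks."""
    parts = [family, genus, species]
    while parts and parts[-1] == "":
        parts.pop()
    return ";".join(parts)


# ---------------------------------------------------------------------------
# Readers / writers

def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_table(path, schema: Type[T]) -> T:
    """Read a TSV/CSV file into the given table type, validating invariants.

    Raises :class:`SchemaError` if a required column is absent and
    :class:`ValidationError` naming the offending row if an invariant fails.
    """
    sep = _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep)
    return schema(frame)


def write_table(table: TypedTable, path) -> None:
    """Write a typed table as TSV with a stable column order.

    ``read_table(path, type(table))`` recovers an equal table (exact for
    integer and string columns, <=1e-12 for proportions).
    """
    frame = table.frame.copy()
    for c in frame.columns:
        if pd.api.types.is_bool_dtype(frame[c]):
            frame[c] = frame[c].map({True: "true", False: "false"})
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g",
                 lineterminator="\n")


def dominance_sentinel(ratio: float) -> float:
    """Dominance ratio recorded when only a single MOTU remains."""
    return math.inf
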
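"""Data model and I/O for single-cell multiplex-immunofluorescence tables.

The unit of analysis is a *sample* (a patient; triplicate TMA cores are
pooled), carrying one row per segmented cell with its centroid position in
micrometres, its tissue compartment (``tumor`` — inside a tumor-cell nest —
or ``stroma``), and a binary positivity call for every marker in the panel.
Compartment areas (mm²) and clinical covariates are per-sample metadata read
from a separate clinical table, never computed from the cells.

Coordinates are continuous µm in the image frame (origin top-left, y down).
Intensity thresholding uses an inclusive ``>=`` comparison, matching common
gating software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPARTMENTS = ("tumor", "stroma")

#: normalization map for tissue-category strings found in exports
_COMPARTMENT_ALIASES = {
    "tumor": "tumor",
    "tumour": "tumor",
    "tumor nest": "tumor",
    "stroma": "stroma",
    "stromal": "stroma",
}


class CellTableError(ValueError):
    """Malformed cell table input."""


class CellTableFormatError(CellTableError):
    """A required column is missing or a row cannot be parsed."""


# ---------------------------------------------------------------------------
# marker panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker panel; CK defines the malignant lineage, CD68 the
    macrophage lineage."""

    markers: tuple[str, ...] = (
        "CK", "CD68", "CD163", "CD206", "ARG1", "MRP8_14", "CD86", "PDL1",
    )

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise CellTableError("marker names must be unique")
        for required in ("CK", "CD68"):
            if required not in self.markers:
                raise CellTableError(f"panel must contain {required}")

    def __iter__(self) -> Iterator[str]:
        return iter(self.markers)

    def __contains__(self, marker: str) -> bool:
        return marker in self.markers


DEFAULT_PANEL = MarkerPanel()

#: label spellings used in phenotype names and vendor exports
MARKER_ALIASES: dict[str, str] = {
    "CK": "CK",
    "CD68": "CD68",
    "CD163": "CD163",
    "CD206": "CD206",
    "ARG1": "ARG1",
    "ARG-1": "ARG1",
    "MRP8_14": "MRP8_14",
    "MRP8-14": "MRP8_14",
    "MRPP8-14": "MRP8_14",  # typo occurring in the wild
    "CD86": "CD86",
    "PDL1": "PDL1",
    "PD-L1": "PDL1",
}


def canonical_marker(name: str) -> str:
    """Map a marker spelling (``Arg-1``, ``PD-L1`` ...) to its panel name."""
    key = name.strip().upper()
    if key not in MARKER_ALIASES:
        raise CellTableError(f"unknown marker name: {name!r}")
    return MARKER_ALIASES[key]


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellRecord:
    """One segmented cell."""

    cell_id: str
    sample_id: str
    core_id: str
    x_um: float
    y_um: float
    compartment: str
    positivity: Mapping[str, bool]
    intensity: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_um) and np.isfinite(self.y_um)):
            raise CellTableError(
                f"cell {self.cell_id}: coordinates must be finite")
        if self.compartment not in COMPARTMENTS:
            raise CellTableError(
                f"cell {self.cell_id}: compartment {self.compartment!r} "
                f"not in {set(COMPARTMENTS)}")


@dataclass
class SampleTable:
    """All cells of one sample plus its per-sample metadata.

    ``cells`` is a DataFrame with columns ``cell_id, core_id, x_um, y_um,
    compartment`` plus one boolean ``<marker>_pos`` column per panel marker
    and optionally one ``<marker>_int`` intensity column.
    """

    sample_id: str
    cells: pd.DataFrame
    panel: MarkerPanel = DEFAULT_PANEL
    tumor_area_mm2: Optional[float] = None
    stroma_area_mm2: Optional[float] = None
    clinical: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for area in (self.tumor_area_mm2, self.stroma_area_mm2):
            if area is not None and not area > 0:
                raise CellTableError(
                    f"sample {self.sample_id}: areas must be positive")
        missing = [m for m in self.panel
                   if f"{m}_pos" not in self.cells.columns]
        if missing:
            raise CellTableFormatError(
                f"sample {self.sample_id}: missing positivity columns for "
                f"{missing}")
        bad = set(self.cells["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise CellTableError(
                f"sample {self.sample_id}: unknown compartments {bad}; "
                f"allowed: {set(COMPARTMENTS)}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def total_area_mm2(self) -> Optional[float]:
        if self.tumor_area_mm2 is None or self.stroma_area_mm2 is None:
            return None
        return self.tumor_area_mm2 + self.stroma_area_mm2

    def area_mm2(self, compartment: str) -> float:
        """Area of ``tumor``/``stroma``/``total``; error if metadata absent."""
        lookup = {"tumor": self.tumor_area_mm2,
                  "stroma": self.stroma_area_mm2,
                  "total": self.total_area_mm2}
        if compartment not in lookup:
            raise CellTableError(f"unknown compartment {compartment!r}")
        area = lookup[compartment]
        if area is None:
            raise CellTableError(
                f"sample {self.sample_id}: compartment areas not attached "
                "(provide a clinical table with tumor_area_mm2 / "
                "stroma_area_mm2)")
        return area

    def records(self) -> Iterator[CellRecord]:
        """Iterate cells as :class:`CellRecord` (row-level convenience)."""
        for _, row in self.cells.iterrows():
            yield CellRecord(
                cell_id=str(row["cell_id"]),
                sample_id=self.sample_id,
                core_id=str(row.get("core_id", "")),
                x_um=float(row["x_um"]),
                y_um=float(row["y_um"]),
                compartment=str(row["compartment"]),
                positivity={m: bool(row[f"{m}_pos"]) for m in self.panel},
                intensity=(
                    {m: float(row[f"{m}_int"]) for m in self.panel
                     if f"{m}_int" in self.cells.columns} or None),
            )


@dataclass
class Cohort:
    """Collection of samples with unique ids."""

    samples: dict[str, SampleTable]

    def __post_init__(self) -> None:
        for sid, sample in self.samples.items():
            if sid != sample.sample_id:
                raise CellTableError(
                    f"sample keyed {sid!r} carries sample_id "
                    f"{sample.sample_id!r}")

    @classmethod
    def from_samples(cls, samples: Iterable[SampleTable]) -> "Cohort":
        out: dict[str, SampleTable] = {}
        for s in samples:
            if s.sample_id in out:
                raise CellTableError(f"duplicate sample_id {s.sample_id!r}")
            out[s.sample_id] = s
        return cls(out)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SampleTable]:
        return iter(self.samples.values())

    def __getitem__(self, sample_id: str) -> SampleTable:
        return self.samples[sample_id]

    @property
    def panel(self) -> MarkerPanel:
        return next(iter(self.samples.values())).panel


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

#: canonical column names of the cell-table dialect this package writes
CANONICAL_DIALECT: dict[str, str] = {
    "sample_id": "sample_id",
    "core_id": "core_id",
    "cell_id": "cell_id",
    "x_um": "x_um",
    "y_um": "y_um",
    "compartment": "compartment",
}

#: mapping for inForm-style "cell seg data" exports
INFORM_DIALECT: dict[str, str] = {
    "sample_id": "Sample Name",
    "core_id": "Annotation ID",
    "cell_id": "Cell ID",
    "x_um": "Cell X Position",
    "y_um": "Cell Y Position",
    "compartment": "Tissue Category",
}

_REQUIRED_FIELDS = ("sample_id", "cell_id", "x_um", "y_um", "compartment")


def _normalize_compartment(value: str, row_index: int) -> str:
    key = str(value).strip().lower()
    if key not in _COMPARTMENT_ALIASES:
        raise CellTableFormatError(
            f"row {row_index}: unknown tissue category {value!r}; "
            f"allowed values: {set(COMPARTMENTS)}")
    return _COMPARTMENT_ALIASES[key]


def read_cell_table(
    path: str | Path,
    dialect: Optional[Mapping[str, str]] = None,
    panel: MarkerPanel = DEFAULT_PANEL,
    marker_columns: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = None,
) -> Cohort:
    """Read a TSV/CSV cell table into a :class:`Cohort`.

    Parameters
    ----------
    dialect
        Maps canonical fields (``sample_id, core_id, cell_id, x_um, y_um,
        compartment``) to the file's column names. Defaults to the canonical
        dialect; :data:`INFORM_DIALECT` covers inForm-style exports.
    marker_columns
        Maps each panel marker to its positivity column. Defaults to
        ``<marker>_pos``.
    sep
        Field separator; inferred from the extension when omitted
        (``.csv`` → comma, otherwise tab).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    dialect = dict(CANONICAL_DIALECT, **(dialect or {}))
    marker_columns = dict(
        {m: f"{m}_pos" for m in panel}, **(marker_columns or {}))

    raw = pd.read_csv(path, sep=sep, dtype=str)

    for fld in _REQUIRED_FIELDS:
        if dialect[fld] not in raw.columns:
            raise CellTableFormatError(
                f"missing required column {dialect[fld]!r} (field {fld})")
    for m, col in marker_columns.items():
        if col not in raw.columns:
            raise CellTableFormatError(
                f"missing positivity column {col!r} for marker {m}")

    df = pd.DataFrame({
        "sample_id": raw[dialect["sample_id"]].astype(str),
        "core_id": (raw[dialect["core_id"]].astype(str)
                    if dialect["core_id"] in raw.columns else ""),
        "cell_id": raw[dialect["cell_id"]].astype(str),
    })
    for axis in ("x_um", "y_um"):
        vals = pd.to_numeric(raw[dialect[axis]], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise CellTableFormatError(
                f"row {int(bad[0])}: non-numeric coordinate in column "
                f"{dialect[axis]!r}")
        df[axis] = vals.astype(float)
    df["compartment"] = [
        _normalize_compartment(v, i)
        for i, v in enumerate(raw[dialect["compartment"]])]

    truthy = {"1", "1.0", "true", "yes", "pos", "positive"}
    falsy = {"0", "0.0", "false", "no", "neg", "negative", ""}
    for m, col in marker_columns.items():
        vals = raw[col].astype(str).str.strip().str.lower()
        unknown = set(vals) - truthy - falsy
        if unknown:
            raise CellTableFormatError(
                f"column {col!r}: unparseable positivity values {unknown}")
        df[f"{m}_pos"] = vals.isin(truthy).to_numpy()
    for m in panel:
        col = f"{m}_int"
        if col in raw.columns:
            df[col] = pd.to_numeric(raw[col], errors="coerce").astype(float)

    # unknown columns kept verbatim as opaque metadata
    consumed = (set(dialect.values()) | set(marker_columns.values())
                | {f"{m}_int" for m in panel})
    for col in raw.columns:
        if col not in consumed and col not in df.columns:
            df[col] = raw[col]

    samples = []
    for sid, grp in df.groupby("sample_id", sort=False):
        samples.append(SampleTable(
            sample_id=str(sid),
            cells=grp.drop(columns=["sample_id"]).reset_index(drop=True),
            panel=panel,
        ))
    return Cohort.from_samples(samples)


def write_cell_table(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort's cells as a canonical-dialect TSV (lossless)."""
    if len(cohort) == 0:
        raise CellTableError("cannot write an empty cohort")
    path = Path(path)
    panel = cohort.panel
    frames = []
    for sample in cohort:
        block = sample.cells.copy()
        block.insert(0, "sample_id", sample.sample_id)
        frames.append(block)
    df = pd.concat(frames, ignore_index=True)
    lead = ["sample_id", "core_id", "cell_id", "x_um", "y_um", "compartment"]
    pos = [f"{m}_pos" for m in panel]
    ints = [f"{m}_int" for m in panel if f"{m}_int" in df.columns]
    other = [c for c in df.columns if c not in lead + pos + ints]
    df = df[lead + pos + ints + other]
    for c in pos:
        df[c] = df[c].astype(int)
    df.to_csv(path, sep="\t", index=False)
    return path


_CLINICAL_COLUMNS = ("sample_id", "histology", "asbestos", "stage",
                     "os_months", "event", "tumor_area_mm2",
                     "stroma_area_mm2")


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical/area CSV (one row per sample)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise CellTableFormatError(f"clinical table missing columns {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise CellTableError("duplicate sample_id in clinical table")
    return df


def write_clinical_table(cohort: Cohort, path: str | Path) -> Path:
    rows = []
    for s in cohort:
        rows.append({
            "sample_id": s.sample_id,
            "histology": s.clinical.get("histology"),
            "asbestos": s.clinical.get("asbestos"),
            "stage": s.clinical.get("stage"),
            "os_months": s.clinical.get("os_months"),
            "event": s.clinical.get("event"),
            "tumor_area_mm2": s.tumor_area_mm2,
            "stroma_area_mm2": s.stroma_area_mm2,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def attach_clinical(cohort: Cohort, clinical: pd.DataFrame) -> Cohort:
    """Return a cohort with areas and clinical covariates merged in."""
    table = clinical.set_index("sample_id")
    samples = {}
    for sid, sample in cohort.samples.items():
        if sid not in table.index:
            raise CellTableError(f"sample {sid!r} absent from clinical table")
        row = table.loc[sid]
        samples[sid] = replace(
            sample,
            tumor_area_mm2=float(row["tumor_area_mm2"]),
            stroma_area_mm2=float(row["stroma_area_mm2"]),
            clinical={
                "histology": row["histology"],
                "asbestos": row["asbestos"],
                "stage": row["stage"],
                "os_months": float(row["os_months"]),
                "event": bool(row["event"]),
            },
        )
    return Cohort(samples)


def apply_intensity_threshold(
    cohort: Cohort, cutoffs: Mapping[str, float]
) -> Cohort:
    """Re-derive positivity from intensities: positive iff intensity >= cutoff.

    Only markers named in ``cutoffs`` are overwritten. Raises if a listed
    marker has no intensity column.
    """
    if not cutoffs:
        return cohort
    samples = {}
    for sid, sample in cohort.samples.items():
        cells = sample.cells.copy()
        for marker, cut in cutoffs.items():
            m = canonical_marker(marker)
            col = f"{m}_int"
            if col not in cells.columns:
                raise CellTableError(
                    f"sample {sid}: no intensity data for marker {m}")
            cells[f"{m}_pos"] = (cells[col].to_numpy() >= cut)
        samples[sid] = replace(sample, cells=cells)
    return Cohort(samples)
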
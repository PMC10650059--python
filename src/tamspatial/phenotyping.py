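"""Marker co-expression phenotype catalogue and per-cell gating.

A phenotype is a boolean query over the marker panel: a set of markers that
must be positive, a set that must be negative, everything else don't-care.
Labels are therefore *non-exclusive* — one cell may carry several labels
(e.g. a CD68+CD163+ cell with all other markers negative is both an M2 and
an M2c of the CD163 base).

Lineage exclusivity: CK+ cells are malignant; they are excluded from every
macrophage-lineage definition regardless of their CD68 state (double-lineage
cells are treated as segmentation artifacts).

Catalogue entries are parsed from the field's label grammar
(``CD68+CD163+Arg-1negMRP8-14negCD86neg``), so a catalogue is data: it can
be loaded from YAML/JSON and extended without touching code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .cell_table import (
    MARKER_ALIASES,
    CellRecord,
    DEFAULT_PANEL,
    MarkerPanel,
    SampleTable,
    canonical_marker,
)

LINEAGE_CLASSES = (
    "malignant", "macrophage_total", "M1", "M2", "M2a", "M2b", "M2c",
    "checkpoint",
)

#: lineage classes counted as "macrophage phenotypes"
_M_CLASSES = frozenset({"M1", "M2", "M2a", "M2b", "M2c"})


class CatalogueError(ValueError):
    """Invalid phenotype definition or catalogue."""


# ---------------------------------------------------------------------------
# label grammar
# ---------------------------------------------------------------------------

def parse_marker_pattern(pattern: str) -> tuple[frozenset[str], frozenset[str]]:
    """Parse ``MARKER+ / MARKERneg`` sequences into (positive, negative) sets.

    >>> parse_marker_pattern("CD68+CD86+MRP8-14neg")
    (frozenset({'CD68', 'CD86'}), frozenset({'MRP8_14'}))
    """
    # longest alias first so CD163 is not read as CD16 + "3..."
    aliases = sorted(MARKER_ALIASES, key=len, reverse=True)
    pos, neg = set(), set()
    s = pattern.strip()
    i = 0
    while i < len(s):
        for alias in aliases:
            if s.upper().startswith(alias, i):
                i += len(alias)
                marker = MARKER_ALIASES[alias]
                if s.startswith("+", i):
                    pos.add(marker)
                    i += 1
                elif s[i:i + 3].lower() == "neg":
                    neg.add(marker)
                    i += 3
                else:
                    raise CatalogueError(
                        f"marker {alias} in {pattern!r} lacks +/neg suffix")
                break
        else:
            raise CatalogueError(
                f"cannot parse marker pattern at ...{s[i:]!r}")
    return frozenset(pos), frozenset(neg)


# ---------------------------------------------------------------------------
# definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeDefinition:
    """Required-positive / required-negative marker query with a lineage class."""

    name: str
    lineage_class: str
    required_positive: frozenset[str]
    required_negative: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.lineage_class not in LINEAGE_CLASSES:
            raise CatalogueError(
                f"{self.name}: unknown lineage class {self.lineage_class!r}")
        if self.required_positive & self.required_negative:
            raise CatalogueError(
                f"{self.name}: a marker cannot be required both "
                "positive and negative")
        if self.is_macrophage_lineage and "CD68" not in self.required_positive:
            raise CatalogueError(
                f"{self.name}: macrophage definitions must require CD68+")
        if self.lineage_class == "malignant" and \
                "CK" not in self.required_positive:
            raise CatalogueError(
                f"{self.name}: malignant definitions must require CK+")

    @property
    def is_macrophage_lineage(self) -> bool:
        """True for every CD68-based (non-CK) definition, including
        macrophage_total and the CD68+PD-L1+ checkpoint row."""
        return self.lineage_class in _M_CLASSES or (
            self.lineage_class in ("macrophage_total", "checkpoint")
            and "CD68" in self.required_positive
            and "CK" not in self.required_positive)

    @property
    def is_macrophage_phenotype(self) -> bool:
        """Macrophage *phenotypes*: the M-labelled rows plus CD68+PD-L1+
        (total CD68+ is the lineage denominator, not a phenotype)."""
        return self.is_macrophage_lineage and \
            self.lineage_class != "macrophage_total"

    def markers_used(self) -> frozenset[str]:
        return self.required_positive | self.required_negative

    @classmethod
    def from_label(cls, name: str, lineage_class: str,
                   pattern: Optional[str] = None) -> "PhenotypeDefinition":
        """Build from a label such as ``(M2b) CD68+CD86+MRP8-14neg``; the
        pattern defaults to the part of the name after any ``(class)``
        prefix."""
        if pattern is None:
            pattern = name.split(")", 1)[-1].strip() if ")" in name else name
            pattern = pattern.removeprefix("Total").strip()
        pos, neg = parse_marker_pattern(pattern)
        return cls(name=name, lineage_class=lineage_class,
                   required_positive=pos, required_negative=neg)


@dataclass(frozen=True)
class PhenotypeCatalogue:
    """Ordered, uniquely-named collection of phenotype definitions."""

    definitions: tuple[PhenotypeDefinition, ...]

    def __post_init__(self) -> None:
        names = [d.name for d in self.definitions]
        if len(set(names)) != len(names):
            raise CatalogueError("phenotype names must be unique")

    def __iter__(self) -> Iterator[PhenotypeDefinition]:
        return iter(self.definitions)

    def __len__(self) -> int:
        return len(self.definitions)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.definitions)

    def __getitem__(self, name: str) -> PhenotypeDefinition:
        for d in self.definitions:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def macrophage_phenotypes(self) -> tuple[PhenotypeDefinition, ...]:
        return tuple(d for d in self.definitions if d.is_macrophage_phenotype)

    def validate_against(self, panel: MarkerPanel) -> None:
        for d in self.definitions:
            outside = d.markers_used() - set(panel.markers)
            if outside:
                raise CatalogueError(
                    f"{d.name}: references markers outside the panel: "
                    f"{sorted(outside)}")


# ---------------------------------------------------------------------------
# the default catalogue (the validation cohort's published rows)
# ---------------------------------------------------------------------------

_DEFAULT_ROWS: tuple[tuple[str, str], ...] = (
    ("Total CK+", "malignant"),
    ("Total CD68+", "macrophage_total"),
    ("(M1) CD68+MRP8-14+CD163negCD206negArg-1neg", "M1"),
    ("(M1) CD68+CD86+CD163negCD206negArg-1neg", "M1"),
    ("(M1) CD68+CD86+MRP8-14+CD163negCD206negArg-1neg", "M1"),
    ("(M2) CD68+CD163+MRP8-14negCD86neg", "M2"),
    ("(M2) CD68+CD206+MRP8-14negCD86neg", "M2"),
    ("(M2) CD68+CD163+CD206+MRP8-14negCD86neg", "M2"),
    ("(M2a) CD68+CD163+Arg-1+MRP8-14negCD86neg", "M2a"),
    ("(M2a) CD68+CD206+Arg-1+MRP8-14negCD86neg", "M2a"),
    ("(M2a) CD68+CD163+CD206+Arg-1+MRP8-14negCD86neg", "M2a"),
    ("(M2b) CD68+CD86+MRP8-14neg", "M2b"),
    ("(M2c) CD68+CD163+Arg-1negMRP8-14negCD86neg", "M2c"),
    ("(M2c) CD68+CD206+Arg-1negMRP8-14negCD86neg", "M2c"),
    ("(M2c) CD68+CD163+CD206+Arg-1negMRP8-14negCD86neg", "M2c"),
    ("CK+PD-L1+", "checkpoint"),
    ("CD68+PD-L1+", "checkpoint"),
)


def default_catalogue() -> PhenotypeCatalogue:
    """The published macrophage/malignant catalogue: total CK+, total CD68+,
    3 M1, 3 M2, 3 M2a, 1 M2b, 3 M2c, CK+PD-L1+ and CD68+PD-L1+ — 14 of which
    are macrophage phenotypes."""
    defs = []
    for name, cls in _DEFAULT_ROWS:
        # CK+PD-L1+ is malignant-lineage; modeled as checkpoint class with CK+
        if name == "CK+PD-L1+":
            defs.append(PhenotypeDefinition(
                name=name, lineage_class="checkpoint",
                required_positive=frozenset({"CK", "PDL1"})))
        else:
            defs.append(PhenotypeDefinition.from_label(name, cls))
    cat = PhenotypeCatalogue(tuple(defs))
    cat.validate_against(DEFAULT_PANEL)
    return cat


def load_catalogue(path: str | Path) -> PhenotypeCatalogue:
    """Load a catalogue from a YAML/JSON list of
    ``{name, class, positive: [...], negative: [...]}`` entries."""
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text))
    defs = []
    for entry in data:
        defs.append(PhenotypeDefinition(
            name=entry["name"],
            lineage_class=entry["class"],
            required_positive=frozenset(
                canonical_marker(m) for m in entry.get("positive", ())),
            required_negative=frozenset(
                canonical_marker(m) for m in entry.get("negative", ())),
        ))
    return PhenotypeCatalogue(tuple(defs))


def save_catalogue(catalogue: PhenotypeCatalogue, path: str | Path) -> Path:
    path = Path(path)
    data = [
        {"name": d.name, "class": d.lineage_class,
         "positive": sorted(d.required_positive),
         "negative": sorted(d.required_negative)}
        for d in catalogue
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

def matches(cell: CellRecord, definition: PhenotypeDefinition) -> bool:
    """Does one cell satisfy a phenotype query (including lineage
    exclusivity)?"""
    for m in definition.markers_used():
        if m not in cell.positivity:
            raise CatalogueError(
                f"{definition.name}: cell lacks positivity for marker {m}")
    if definition.is_macrophage_lineage and cell.positivity.get("CK", False):
        return False
    return (all(cell.positivity[m] for m in definition.required_positive)
            and not any(cell.positivity[m]
                        for m in definition.required_negative))


def match_mask(cells: pd.DataFrame,
               definition: PhenotypeDefinition) -> np.ndarray:
    """Vectorized :func:`matches` over a sample's cells DataFrame."""
    for m in definition.markers_used() | {"CK"}:
        if f"{m}_pos" not in cells.columns:
            raise CatalogueError(
                f"{definition.name}: cells table lacks column {m}_pos")
    mask = np.ones(len(cells), dtype=bool)
    for m in definition.required_positive:
        mask &= cells[f"{m}_pos"].to_numpy(dtype=bool)
    for m in definition.required_negative:
        mask &= ~cells[f"{m}_pos"].to_numpy(dtype=bool)
    if definition.is_macrophage_lineage:
        mask &= ~cells["CK_pos"].to_numpy(dtype=bool)
    return mask


def classify_cells(
    sample: SampleTable, catalogue: PhenotypeCatalogue
) -> dict[str, frozenset[str]]:
    """Map each phenotype name to the exact set of matching cell ids.

    Sets may overlap (labels are queries, not a partition); the result is a
    pure function of each cell's positivity vector and is invariant to cell
    order.
    """
    catalogue.validate_against(sample.panel)
    ids = sample.cells["cell_id"].astype(str).to_numpy()
    return {
        d.name: frozenset(ids[match_mask(sample.cells, d)])
        for d in catalogue
    }
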
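"""Marker panel model.

A :class:`MarkerPanel` is the ordered list of antibody/DNA channels acquired
for every region of interest (ROI).  The default panel bundled with the
package covers 32 protein markers plus 2 iridium DNA intercalator channels,
grouped into tumor, stromal, immune, endothelial, functional, and DNA
categories.  Functional markers (e.g. Ki67) and DNA channels are excluded
from phenotype-driven analyses such as embeddings, which is what the
``phenotypic`` flag encodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import yaml

from .errors import ConfigurationError

CATEGORIES = ("tumor", "stromal", "immune", "endothelial", "functional", "DNA")


@dataclass(frozen=True)
class MarkerEntry:
    name: str
    metal: str
    category: str
    phenotypic: bool


@dataclass
class MarkerPanel:
    """Ordered, validated collection of markers."""

    entries: list[MarkerEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate marker names in panel: {dupes}")
        for e in self.entries:
            if e.category not in CATEGORIES:
                raise ConfigurationError(
                    f"marker {e.name!r}: unknown category {e.category!r}"
                )
            if e.category in ("functional", "DNA") and e.phenotypic:
                raise ConfigurationError(
                    f"marker {e.name!r}: {e.category} markers cannot be phenotypic"
                )

    # -- lookups ---------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def phenotypic_markers(self) -> list[str]:
        return [e.name for e in self.entries if e.phenotypic]

    @property
    def dna_markers(self) -> list[str]:
        return [e.name for e in self.entries if e.category == "DNA"]

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.entries)

    def category_of(self, name: str) -> str:
        for e in self.entries:
            if e.name == name:
                return e.category
        raise KeyError(name)

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "markers": [
                {
                    "name": e.name,
                    "metal": e.metal,
                    "category": e.category,
                    "phenotypic": e.phenotypic,
                }
                for e in self.entries
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "MarkerPanel":
        try:
            raw: Iterable[dict] = payload["markers"]
        except (KeyError, TypeError):
            raise ConfigurationError("panel YAML must contain a 'markers' list")
        entries = []
        for m in raw:
            try:
                entries.append(
                    MarkerEntry(
                        name=str(m["name"]),
                        metal=str(m.get("metal", "")),
                        category=str(m["category"]),
                        phenotypic=bool(m["phenotypic"]),
                    )
                )
            except KeyError as exc:
                raise ConfigurationError(f"panel entry missing field {exc}")
        return cls(entries)


def _entry(name: str, metal: str, category: str, phenotypic: bool = True) -> MarkerEntry:
    return MarkerEntry(name, metal, category, phenotypic)


#: Default 34-channel panel (32 protein + 2 DNA).  Metal tags are the
#: lanthanide labels conventionally used on this instrument class.
DEFAULT_PANEL_ENTRIES: Sequence[MarkerEntry] = (
    # tumor / granulosa lineage
    _entry("FOXL2", "Eu153", "tumor"),
    _entry("SF1", "Nd143", "tumor"),
    _entry("Calretinin", "Nd145", "tumor"),
    _entry("InhibinA", "Nd146", "tumor"),
    _entry("ERa", "Gd158", "tumor"),
    _entry("PR", "Gd160", "tumor"),
    # stromal
    _entry("COL1A1", "Tm169", "stromal"),
    _entry("aSMA", "Pr141", "stromal"),
    _entry("Vimentin", "Nd144", "stromal"),
    _entry("S100A4", "Sm147", "stromal"),
    _entry("PDGFRa", "Sm149", "stromal"),
    _entry("PDGFRb", "Nd150", "stromal"),
    _entry("FAP", "Eu151", "stromal"),
    # immune
    _entry("CD45", "Sm152", "immune"),
    _entry("CD45RO", "Nd148", "immune"),
    _entry("CD20", "Dy161", "immune"),
    _entry("CD8a", "Dy162", "immune"),
    _entry("CD4", "Gd156", "immune"),
    _entry("FOXP3", "Dy163", "immune"),
    _entry("CD25", "Dy164", "immune"),
    _entry("CD56", "Ho165", "immune"),
    _entry("CD33", "Er166", "immune"),
    _entry("CD11b", "Er167", "immune"),
    _entry("CD68", "Er168", "immune"),
    _entry("CD163", "Yb171", "immune"),
    _entry("CD66b", "Yb172", "immune"),
    _entry("CD123", "Yb173", "immune"),
    _entry("GranzymeB", "Yb174", "immune"),
    # endothelial
    _entry("CD31", "Sm154", "endothelial"),
    # functional (never phenotypic)
    _entry("Ki67", "Lu175", "functional", phenotypic=False),
    _entry("ADAMTS1", "Yb176", "functional", phenotypic=False),
    _entry("ADAMTS5", "Gd155", "functional", phenotypic=False),
    # DNA intercalators (never phenotypic)
    _entry("DNA1", "Ir191", "DNA", phenotypic=False),
    _entry("DNA2", "Ir193", "DNA", phenotypic=False),
)


def default_panel() -> MarkerPanel:
    """The bundled 34-marker panel (32 protein markers + 2 DNA markers)."""
    return MarkerPanel(list(DEFAULT_PANEL_ENTRIES))


def load_packaged_panel() -> MarkerPanel:
    """Load the panel shipped as package data (identical to default_panel)."""
    ref = resources.files("imctme") / "data" / "panel.yaml"
    with resources.as_file(ref) as path:
        return MarkerPanel.from_yaml(path)
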
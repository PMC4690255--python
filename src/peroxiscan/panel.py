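"""Marker panels: which families are screened and how they are classed.

The default panel holds the 14 peroxins conserved in metazoans (the core
eukaryotic set Pex1, 2, 3, 5, 6, 7, 10, 11, 12, 13, 14, 16 and 19 plus the
Pex1/Pex6-recruiting membrane anchor Pex26) and 33 families of putative
peroxisomal matrix enzymes spanning beta-oxidation, ether-lipid
(plasmalogen) synthesis, amino-acid metabolism, oxygen detoxification and
purine catabolism.  Pex3 and Pex19 are flagged essential: both are required
for de-novo peroxisome biogenesis, so their joint absence is read as loss
of the organelle itself rather than loss of individual pathways.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ConfigError

PEROXIN_FAMILIES = (
    "Pex1", "Pex2", "Pex3", "Pex5", "Pex6", "Pex7", "Pex10",
    "Pex11", "Pex12", "Pex13", "Pex14", "Pex16", "Pex19", "Pex26",
)

ESSENTIAL_PEROXINS = ("Pex3", "Pex19")

#: 33 enzyme families: peroxisomal/mitochondrial beta-oxidation, plasmalogen
#: synthesis (Gnpat, Agps, Far1/Far2), amino-acid and oxygen metabolism,
#: purine catabolism (Xdh, Uox, Allc).
ENZYME_FAMILIES = (
    "Acox1", "Acox3", "Lbp", "Dbp", "Acaa1", "Scp2", "Amacr", "Crat",
    "Crot", "Ech1", "Decr", "Pec1", "Vlcs", "Pte1", "Pte2", "Phyh",
    "Hpcl2", "Gnpat", "Agps", "Far1", "Far2", "Agxt", "Pipox", "Cat",
    "Prdx5", "Dao", "Hao1", "Ephx2", "Gstk1", "Paox", "Xdh", "Uox",
    "Allc",
)

MARKER_CLASSES = ("peroxin", "enzyme", "background_og")


@dataclass(frozen=True)
class PanelEntry:
    family_id: str
    marker_class: str  # peroxin | enzyme | background_og
    essential: bool = False


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered collection of marker families with class and essentiality."""

    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.family_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ConfigError("panel family_ids must be unique")
        for e in self.entries:
            if e.marker_class not in MARKER_CLASSES:
                raise ConfigError(f"unknown marker_class {e.marker_class!r}")
            if e.essential and e.marker_class != "peroxin":
                raise ConfigError("only peroxins may be flagged essential")

    def __iter__(self) -> Iterator[PanelEntry]:
        return iter(self.entries)

    def __contains__(self, family_id: str) -> bool:
        return any(e.family_id == family_id for e in self.entries)

    @property
    def family_ids(self) -> tuple[str, ...]:
        return tuple(e.family_id for e in self.entries)

    @property
    def peroxins(self) -> tuple[str, ...]:
        return tuple(e.family_id for e in self.entries if e.marker_class == "peroxin")

    @property
    def enzymes(self) -> tuple[str, ...]:
        return tuple(e.family_id for e in self.entries if e.marker_class == "enzyme")

    @property
    def background_groups(self) -> tuple[str, ...]:
        return tuple(
            e.family_id for e in self.entries if e.marker_class == "background_og"
        )

    @property
    def essential_peroxins(self) -> tuple[str, ...]:
        return tuple(e.family_id for e in self.entries if e.essential)

    def marker_class_of(self, family_id: str) -> str:
        for e in self.entries:
            if e.family_id == family_id:
                return e.marker_class
        raise KeyError(family_id)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "family_id": e.family_id,
                "marker_class": e.marker_class,
                "essential": e.essential,
            }
            for e in self.entries
        ]
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkerPanel":
        try:
            payload = json.loads(Path(path).read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ConfigError(f"panel file {path}: invalid JSON ({exc})") from exc
        entries = tuple(
            PanelEntry(
                family_id=item["family_id"],
                marker_class=item["marker_class"],
                essential=bool(item.get("essential", False)),
            )
            for item in payload
        )
        return cls(entries)

    @classmethod
    def from_entries(
        cls, items: Iterable[tuple[str, str, bool]]
    ) -> "MarkerPanel":
        return cls(tuple(PanelEntry(f, c, e) for f, c, e in items))


def default_panel(n_background: int = 0) -> MarkerPanel:
    """The 14-peroxin + 33-enzyme metazoan screening panel.

    ``n_background`` appends that many neutral background orthologous
    groups (``BG001`` ...), which take part in genome-complexity counting
    but never in organelle-loss calling.
    """
    entries = [
        PanelEntry(f, "peroxin", f in ESSENTIAL_PEROXINS) for f in PEROXIN_FAMILIES
    ]
    entries += [PanelEntry(f, "enzyme", False) for f in ENZYME_FAMILIES]
    entries += [
        PanelEntry(f"BG{i + 1:03d}", "background_og", False)
        for i in range(n_background)
    ]
    return MarkerPanel(tuple(entries))
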
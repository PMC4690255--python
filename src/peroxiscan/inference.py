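"""Presence matrices, peroxisome-loss calls and genome-complexity counts.

From the per-protein marker assignments this module builds the species x
family presence matrix (cells: present_high / present_low / absent, with
per-cell provenance), ingests external vetting verdicts for flagged
low-confidence cells, calls per-species peroxisome loss using the
essentiality of Pex3 and Pex19, attaches localization categories to
enzyme families, and counts unique orthologous groups per species as a
proxy for gene-content complexity.

Loss-calling logic: peroxisomes are called lost only when *every* panel
peroxin is absent; they are called retained when at least one peroxin is
present with high confidence AND both essential peroxins (Pex3, Pex19)
are present at any confidence.  Everything else — including species whose
only peroxin evidence is low-confidence, or species with no protein data
at all — is reported indeterminate with an explanatory evidence block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, InputError
from .io import read_tsv, write_tsv
from .panel import MarkerPanel
from .profiles import MarkerAssignment
from .signals import TargetingCall, combine_localization

PRESENCE_STATES = ("present_high", "present_low", "absent")
VERDICTS = ("peroxisomes_retained", "peroxisomes_lost", "indeterminate")


@dataclass(frozen=True)
class CellEvidence:
    """Provenance for one non-absent matrix cell."""

    protein_ids: tuple[str, ...]
    best_score: float
    note: str = ""


@dataclass
class PresenceMatrix:
    """Species x family grid of presence states with per-cell provenance."""

    species_ids: list[str]
    family_ids: list[str]
    cells: dict[tuple[str, str], str] = field(default_factory=dict)
    evidence: dict[tuple[str, str], CellEvidence] = field(default_factory=dict)

    def state(self, species_id: str, family_id: str) -> str:
        return self.cells.get((species_id, family_id), "absent")

    def set_state(
        self,
        species_id: str,
        family_id: str,
        state: str,
        evidence: CellEvidence | None = None,
    ) -> None:
        if state not in PRESENCE_STATES:
            raise ConfigError(f"unknown presence state {state!r}")
        self.cells[(species_id, family_id)] = state
        if evidence is not None:
            self.evidence[(species_id, family_id)] = evidence

    def low_confidence_cells(self) -> list[tuple[str, str]]:
        """Cells flagged for external vetting (the asterisk scenario)."""
        return sorted(k for k, v in self.cells.items() if v == "present_low")

    def to_tsv(self, path: str | Path) -> None:
        rows = (
            [sp] + [self.state(sp, fam) for fam in self.family_ids]
            for sp in self.species_ids
        )
        write_tsv(path, ["species_id"] + list(self.family_ids), rows)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        header, rows = read_tsv(path)
        if not header or header[0] != "species_id":
            raise InputError(f"{path}: not a presence-matrix TSV")
        family_ids = header[1:]
        matrix = cls(species_ids=[r[0] for r in rows], family_ids=family_ids)
        for r in rows:
            for fam, state in zip(family_ids, r[1:]):
                if state != "absent":
                    matrix.cells[(r[0], fam)] = state
        return matrix


def build_presence_matrix(
    assignments: Iterable[MarkerAssignment],
    panel: MarkerPanel,
    species_ids: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Collapse assignments into the species x family presence grid.

    A cell is present_high if any assignment to that family in that
    species has high confidence, present_low if only low-confidence
    assignments exist, absent otherwise.  ``species_ids`` fixes the row
    set (species without a single assignment still need an all-absent
    row); it defaults to the species seen in the assignments.
    """
    assignments = list(assignments)
    known = set(panel.family_ids)
    for a in assignments:
        if a.family_id not in known:
            raise ConfigError(
                f"assignment to family {a.family_id!r} outside the panel "
                f"and background set"
            )
    if species_ids is None:
        species_ids = sorted({a.species_id for a in assignments})
    matrix = PresenceMatrix(
        species_ids=list(species_ids), family_ids=list(panel.family_ids)
    )
    grouped: dict[tuple[str, str], list[MarkerAssignment]] = {}
    for a in assignments:
        grouped.setdefault((a.species_id, a.family_id), []).append(a)
    for key, cell_assignments in grouped.items():
        high = [a for a in cell_assignments if a.confidence == "high"]
        state = "present_high" if high else "present_low"
        best = max(cell_assignments, key=lambda a: a.score)
        matrix.set_state(
            *key,
            state,
            CellEvidence(
                protein_ids=tuple(sorted(a.protein_id for a in cell_assignments)),
                best_score=best.score,
            ),
        )
    return matrix


def apply_vetting_overrides(
    matrix: PresenceMatrix, verdicts: Mapping[tuple[str, str], str]
) -> PresenceMatrix:
    """Apply external (e.g. phylogenetic) vetting verdicts to cells.

    'reject' forces a cell to absent; 'confirm' promotes a present_low
    cell to present_high.  Unknown (species, family) keys are an input
    error.  The input matrix is not modified.
    """
    out = PresenceMatrix(
        species_ids=list(matrix.species_ids),
        family_ids=list(matrix.family_ids),
        cells=dict(matrix.cells),
        evidence=dict(matrix.evidence),
    )
    for key, verdict in sorted(verdicts.items()):
        species_id, family_id = key
        if species_id not in matrix.species_ids or family_id not in matrix.family_ids:
            raise InputError(f"vetting verdict for unknown cell {key!r}")
        if verdict == "reject":
            out.cells[key] = "absent"
            prev = out.evidence.pop(key, None)
            out.evidence[key] = CellEvidence(
                protein_ids=prev.protein_ids if prev else (),
                best_score=prev.best_score if prev else 0.0,
                note="rejected by external vetting",
            )
        elif verdict == "confirm":
            if out.cells.get(key) == "present_low":
                out.cells[key] = "present_high"
                prev = out.evidence.get(key)
                if prev is not None:
                    out.evidence[key] = replace(
                        prev, note="confirmed by external vetting"
                    )
        else:
            raise InputError(
                f"vetting verdict for {key!r} must be confirm/reject, "
                f"got {verdict!r}"
            )
    return out


def read_vetting_tsv(path: str | Path) -> dict[tuple[str, str], str]:
    header, rows = read_tsv(path)
    if header != ["species_id", "family_id", "verdict"]:
        raise InputError(f"{path}: unexpected vetting header {header}")
    return {(sp, fam): verdict for sp, fam, verdict in rows}


@dataclass(frozen=True)
class LossCall:
    """Per-species peroxisome verdict with supporting evidence."""

    species_id: str
    verdict: str
    n_present: int
    n_absent: int
    n_peroxins: int
    absent_peroxins: tuple[str, ...]
    essential_states: Mapping[str, str]
    low_confidence_cells: tuple[str, ...]
    note: str = ""


def call_peroxisome_loss(
    matrix: PresenceMatrix,
    panel: MarkerPanel,
    n_proteins: Mapping[str, int] | None = None,
) -> list[LossCall]:
    """Call peroxisome loss per species from the peroxin presence states.

    ``n_proteins`` (species -> proteome size) lets species with no protein
    data at all be reported indeterminate instead of lost: absence of
    data is not absence of genes.
    """
    peroxins = panel.peroxins
    if not peroxins:
        raise ConfigError("panel contains no peroxin families")
    missing = [f for f in peroxins if f not in matrix.family_ids]
    if missing:
        raise ConfigError(f"matrix does not cover panel peroxins: {missing}")
    essential = panel.essential_peroxins
    calls: list[LossCall] = []
    for sp in matrix.species_ids:
        states = {f: matrix.state(sp, f) for f in peroxins}
        absent = tuple(f for f, s in states.items() if s == "absent")
        present = [f for f, s in states.items() if s != "absent"]
        high = [f for f, s in states.items() if s == "present_high"]
        essential_states = {f: states[f] for f in essential}
        low_cells = tuple(
            f"{sp}:{fam}" for (s, fam) in matrix.low_confidence_cells() if s == sp
        )
        note = ""
        if n_proteins is not None and n_proteins.get(sp, 0) == 0:
            verdict = "indeterminate"
            note = "no protein data for this species"
        elif not present:
            verdict = "peroxisomes_lost"
        elif high and all(s != "absent" for s in essential_states.values()):
            verdict = "peroxisomes_retained"
        else:
            verdict = "indeterminate"
            if not high:
                note = "only low-confidence peroxin evidence"
            else:
                lost_ess = [f for f, s in essential_states.items() if s == "absent"]
                note = f"essential peroxins absent: {','.join(lost_ess)}"
        calls.append(
            LossCall(
                species_id=sp,
                verdict=verdict,
                n_present=len(present),
                n_absent=len(absent),
                n_peroxins=len(peroxins),
                absent_peroxins=absent,
                essential_states=essential_states,
                low_confidence_cells=low_cells,
                note=note,
            )
        )
    return calls


def write_loss_calls_tsv(path: str | Path, calls: Sequence[LossCall]) -> None:
    write_tsv(
        path,
        [
            "species_id", "verdict", "n_present", "n_absent", "n_peroxins",
            "absent_peroxins", "essential_states", "low_confidence_cells",
            "note",
        ],
        (
            (
                c.species_id,
                c.verdict,
                c.n_present,
                c.n_absent,
                c.n_peroxins,
                ",".join(c.absent_peroxins) or "-",
                ";".join(f"{k}={v}" for k, v in sorted(c.essential_states.items())),
                ",".join(c.low_confidence_cells) or "-",
                c.note or "-",
            )
            for c in calls
        ),
    )


@dataclass(frozen=True)
class EnzymeCell:
    presence: str  # present_high | present_low | absent
    category: str  # one of the eight localization categories


def build_enzyme_matrix(
    assignments: Iterable[MarkerAssignment],
    targeting_calls: Mapping[str, TargetingCall],
    panel: MarkerPanel,
    species_ids: Sequence[str] | None = None,
) -> dict[tuple[str, str], EnzymeCell]:
    """Per (species, enzyme family): presence plus a localization category.

    The category is the union of signal flags over *all* proteins assigned
    to the family in that species (paralogs pool their signals), collapsed
    through the eight-way table; dual targeting such as a PTS1 paralog
    plus a mitochondrially targeted paralog therefore reads pts_mito.
    """
    assignments = [
        a for a in assignments if panel.marker_class_of(a.family_id) == "enzyme"
    ]
    if species_ids is None:
        species_ids = sorted({a.species_id for a in assignments})
    grouped: dict[tuple[str, str], list[MarkerAssignment]] = {}
    for a in assignments:
        grouped.setdefault((a.species_id, a.family_id), []).append(a)

    out: dict[tuple[str, str], EnzymeCell] = {}
    for sp in species_ids:
        for fam in panel.enzymes:
            cell_assignments = grouped.get((sp, fam), [])
            if not cell_assignments:
                out[(sp, fam)] = EnzymeCell("absent", "none")
                continue
            pts = False
            nterm_tokens: set[str] = set()
            for a in cell_assignments:
                call = targeting_calls.get(a.protein_id)
                if call is None:
                    raise InputError(
                        f"no targeting call for assigned protein {a.protein_id!r}"
                    )
                pts |= call.pts1 is not None or call.pts2 is not None
                nterm_tokens.add(call.nterm)
            category = combine_localization(
                "pooled" if pts else None, None, nterm_tokens or {"none"}
            )
            presence = (
                "present_high"
                if any(a.confidence == "high" for a in cell_assignments)
                else "present_low"
            )
            out[(sp, fam)] = EnzymeCell(presence, category)
    return out


def write_enzyme_matrix_tsv(
    path: str | Path,
    matrix: Mapping[tuple[str, str], EnzymeCell],
    panel: MarkerPanel,
    species_ids: Sequence[str],
) -> None:
    rows = []
    for sp in species_ids:
        for fam in panel.enzymes:
            cell = matrix.get((sp, fam), EnzymeCell("absent", "none"))
            rows.append((sp, fam, cell.presence, cell.category))
    write_tsv(path, ["species_id", "family_id", "presence", "category"], rows)


@dataclass(frozen=True)
class ComplexityCount:
    """Distinct orthologous groups detected in one species' proteome."""

    species_id: str
    n_unique_orthogroups: int


def count_orthogroups(
    assignments: Iterable[MarkerAssignment], species_id: str
) -> ComplexityCount:
    """Count distinct assigned families (score > 0) for one species.

    Set semantics: paralogs and duplicated proteins do not inflate the
    count.  Background orthologous groups participate here even though
    they never enter loss calling.
    """
    families = {
        a.family_id for a in assignments if a.species_id == species_id
    }
    return ComplexityCount(species_id, len(families))


def write_complexity_tsv(
    path: str | Path, counts: Sequence[ComplexityCount]
) -> None:
    write_tsv(
        path,
        ["species_id", "n_unique_orthogroups"],
        ((c.species_id, c.n_unique_orthogroups) for c in counts),
    )
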
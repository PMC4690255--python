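"""Synthetic species cohorts with planted marker families and signals.

The generator emulates the statistical structure a presence/absence
screen assumes: each marker family is a random consensus sequence from
which both the family alignment (the profile's training data) and the
planted proteome members are sampled by independent per-site substitution
at a controlled divergence.  Designated loss species carry zero peroxin
homologs and a reduced enzyme repertoire; every planted protein may carry
peroxisomal (PTS1/PTS2), mitochondrial-like or secretory-like targeting
signals, written so the corresponding scanner is guaranteed to find them.

By default, chance occurrences of any planted-class signal in decoys and
in unplanned regions of marker proteins are scrubbed away (resampled), so
the emitted ground truth is exact.  Scrubbing can be disabled to study
chance-match rates (about 0.5% of random C-terminal tripeptides are valid
PTS1s).

Everything is driven by a single integer seed through named substreams,
so identical configuration + seed yields byte-identical fixtures.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import CANONICAL, encode
from .errors import ConfigError, InputError, PlantingError, ScreenError
from .io import Proteome, write_fasta, write_tsv, read_tsv
from .panel import (
    ENZYME_FAMILIES,
    ESSENTIAL_PEROXINS,
    MARKER_CLASSES,
    MarkerPanel,
    PanelEntry,
    PEROXIN_FAMILIES,
)
from . import signals as sigmod

SIGNAL_KINDS = ("pts1", "pts2", "mito", "sec")

#: 25-residue N-termini that the rule-based classifier deterministically
#: calls sec / mito; their tails are non-hydrophobic so chance residues
#: just downstream cannot extend them into a spurious signal.
SEC_NTERM = "MLLLALLVVAGQTNPQSTNQGQNPG"
MITO_NTERM = "MRSLRTKSNRALSQTRNPQGRSTNQ"

#: default 1-based start for planted PTS2 motifs: outside the N-terminal
#: classifier windows, well inside the 100-residue PTS2 window.
DEFAULT_PTS2_START = 35
_PTS2_MAX_START = sigmod.PTS2_WINDOW - sigmod.PTS2_LENGTH + 1  # 91

_PTS2_POSITION_SETS = ("RK", "LVIQ", CANONICAL, CANONICAL, "LVIHQ",
                       "LSGAK", CANONICAL, CANONICAL, "HQ", "LAF")


def substream(seed: int, *labels) -> np.random.Generator:
    """A named, order-independent child RNG of the master seed."""
    keys = [zlib.crc32(str(label).encode("utf-8")) for label in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))


def _decode(idx: np.ndarray) -> str:
    return "".join(CANONICAL[i] for i in idx)


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class MarkerFamilySpec:
    """How one marker family is simulated."""

    family_id: str
    marker_class: str  # peroxin | enzyme | background_og
    essential: bool = False
    n_seed_seqs: int = 8
    seq_length: int = 200
    divergence: float = 0.1

    def __post_init__(self) -> None:
        if self.marker_class not in MARKER_CLASSES:
            raise ConfigError(f"unknown marker_class {self.marker_class!r}")
        if not 0.0 <= self.divergence <= 0.5:
            raise ConfigError(
                f"{self.family_id}: divergence must be in [0, 0.5], "
                f"got {self.divergence}"
            )
        if self.n_seed_seqs < 2:
            raise ConfigError(
                f"{self.family_id}: n_seed_seqs must be >= 2, got {self.n_seed_seqs}"
            )
        if self.seq_length < 10:
            raise ConfigError(f"{self.family_id}: seq_length too short")


@dataclass(frozen=True)
class SpeciesSpec:
    """Presence plan, signal plan and decoy settings for one species."""

    species_id: str
    presence_plan: Mapping[str, str]  # family_id -> present | absent
    signal_plan: Mapping[str, frozenset[str]] = field(default_factory=dict)
    n_decoys: int = 20
    decoy_length_range: tuple[int, int] = (80, 400)

    def __post_init__(self) -> None:
        for fam, state in self.presence_plan.items():
            if state not in ("present", "absent"):
                raise ConfigError(
                    f"{self.species_id}: presence state for {fam} must be "
                    f"present/absent, got {state!r}"
                )
        planted = {
            planted_protein_id(self.species_id, fam)
            for fam, state in self.presence_plan.items()
            if state == "present"
        }
        for pid, sigs in self.signal_plan.items():
            if pid not in planted:
                raise ConfigError(
                    f"{self.species_id}: signal_plan key {pid!r} does not "
                    f"refer to a planted protein"
                )
            for s in sigs:
                if s not in SIGNAL_KINDS:
                    raise ConfigError(f"unknown signal kind {s!r}")
        lo, hi = self.decoy_length_range
        if lo < 10 or hi < lo:
            raise ConfigError(f"{self.species_id}: bad decoy_length_range")

    def present_families(self) -> list[str]:
        return [f for f, s in self.presence_plan.items() if s == "present"]

    def is_full_loss(self, peroxins: Sequence[str] = PEROXIN_FAMILIES) -> bool:
        return all(self.presence_plan.get(f, "absent") == "absent" for f in peroxins)


def planted_protein_id(species_id: str, family_id: str) -> str:
    """Deterministic id of the protein planted for a family in a species."""
    return f"{species_id}_{family_id}"


# ---------------------------------------------------------------------------
# family generation


@dataclass(frozen=True)
class MarkerFamily:
    """A generated family: ungapped consensus plus aligned seed members."""

    spec: MarkerFamilySpec
    consensus: str
    members: tuple[tuple[str, str], ...]  # (member_id, aligned residues)

    @property
    def family_id(self) -> str:
        return self.spec.family_id


def _mutate(consensus_idx: np.ndarray, divergence: float,
            rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution to a *different* residue with prob. divergence."""
    mask = rng.random(consensus_idx.size) < divergence
    offsets = rng.integers(1, len(CANONICAL), size=consensus_idx.size)
    out = consensus_idx.copy()
    out[mask] = (consensus_idx[mask] + offsets[mask]) % len(CANONICAL)
    return out


def generate_marker_family(spec: MarkerFamilySpec, rng_seed: int) -> MarkerFamily:
    """Sample a family consensus and its aligned seed members."""
    rng = substream(rng_seed, "family", spec.family_id)
    consensus_idx = rng.integers(0, len(CANONICAL), size=spec.seq_length)
    members = tuple(
        (
            f"{spec.family_id}_seed{i + 1}",
            _decode(_mutate(consensus_idx, spec.divergence, rng)),
        )
        for i in range(spec.n_seed_seqs)
    )
    return MarkerFamily(spec=spec, consensus=_decode(consensus_idx), members=members)


# ---------------------------------------------------------------------------
# signal planting


def sample_pts1(rng: np.random.Generator | None = None) -> str:
    """A PTS1 tripeptide; the canonical SKL unless an RNG is supplied."""
    if rng is None:
        return "SKL"
    choices = sorted(sigmod.pts1_accepted_tripeptides())
    return choices[int(rng.integers(0, len(choices)))]


def sample_pts2(rng: np.random.Generator | None = None) -> str:
    """A 10-mer matching the PTS2 pattern (position-wise draw)."""
    if rng is None:
        return "RLAALSAAHL"
    return "".join(
        s[int(rng.integers(0, len(s)))] for s in _PTS2_POSITION_SETS
    )


def plant_targeting_signal(
    sequence: str,
    signal: str,
    rng: np.random.Generator | None = None,
    pts2_start: int = DEFAULT_PTS2_START,
) -> str:
    """Overwrite part of a sequence so the named signal is present.

    pts1 replaces the final three residues; pts2 writes a pattern-matching
    10-mer at a 1-based start whose match lies entirely within residues
    1-100 (so start <= 91); mito/sec replace the first 25 residues with
    fixed N-termini the built-in classifier recognises.
    """
    if signal not in SIGNAL_KINDS:
        raise ConfigError(f"unknown signal kind {signal!r}")
    if signal == "pts1":
        if len(sequence) < 3:
            raise PlantingError("sequence too short to plant a PTS1 tripeptide")
        return sequence[:-3] + sample_pts1(rng)
    if signal == "pts2":
        if len(sequence) < 120:
            raise PlantingError(
                f"sequence of {len(sequence)} residues too short for PTS2 "
                f"planting (need >= 120)"
            )
        if not 1 <= pts2_start <= _PTS2_MAX_START:
            raise PlantingError(
                f"PTS2 start {pts2_start} places the match outside the first "
                f"{sigmod.PTS2_WINDOW} residues (start must be in "
                f"1..{_PTS2_MAX_START})"
            )
        motif = sample_pts2(rng)
        i = pts2_start - 1
        return sequence[:i] + motif + sequence[i + sigmod.PTS2_LENGTH:]
    nterm = MITO_NTERM if signal == "mito" else SEC_NTERM
    if len(sequence) < len(nterm):
        raise PlantingError(
            f"sequence too short to plant a {signal} N-terminus"
        )
    return nterm + sequence[len(nterm):]


def _plant_all(
    sequence: str,
    planned: frozenset[str],
    rng: np.random.Generator,
    pts2_start: int = DEFAULT_PTS2_START,
) -> tuple[str, np.ndarray]:
    """Plant every planned signal; return the sequence and a protected mask."""
    if "mito" in planned and "sec" in planned:
        raise ConfigError("cannot plant both mito and sec N-termini")
    protected = np.zeros(len(sequence), dtype=bool)
    for signal in ("mito", "sec"):
        if signal in planned:
            sequence = plant_targeting_signal(sequence, signal, rng)
            protected[: len(MITO_NTERM)] = True
    if "pts2" in planned:
        sequence = plant_targeting_signal(sequence, "pts2", rng, pts2_start)
        protected[pts2_start - 1: pts2_start - 1 + sigmod.PTS2_LENGTH] = True
    if "pts1" in planned:
        sequence = plant_targeting_signal(sequence, "pts1", rng)
        protected[-3:] = True
    return sequence, protected


# ---------------------------------------------------------------------------
# scrubbing of chance signals


def _find_sec_run(seq: str) -> tuple[int, int] | None:
    run = 0
    for i, ch in enumerate(seq[: sigmod.SEC_SCAN_WINDOW]):
        run = run + 1 if ch in sigmod.HYDROPHOBIC else 0
        if run >= sigmod.SEC_RUN_LENGTH:
            return i - run + 1, i + 1
    return None


def scrub_chance_signals(
    sequence: str,
    planned: frozenset[str],
    rng: np.random.Generator,
    protected: np.ndarray | None = None,
    max_rounds: int = 100,
) -> str:
    """Resample residues until no *unplanned* signal class is detectable.

    Planted regions (``protected``) are never touched; chance matches that
    overlap them are broken by resampling their unprotected residues only.
    """
    seq = list(sequence)
    if protected is None:
        protected = np.zeros(len(seq), dtype=bool)

    def resample(lo: int, hi: int) -> bool:
        changed = False
        for i in range(max(lo, 0), min(hi, len(seq))):
            if not protected[i]:
                seq[i] = CANONICAL[int(rng.integers(0, len(CANONICAL)))]
                changed = True
        return changed

    for _ in range(max_rounds):
        s = "".join(seq)
        dirty = False
        if "pts1" not in planned and sigmod.scan_pts1(s) is not None:
            dirty |= resample(len(seq) - 3, len(seq))
        if "pts2" not in planned:
            hit = sigmod.scan_pts2(s)
            if hit is not None:
                start = hit[1] - 1
                dirty |= resample(start, start + sigmod.PTS2_LENGTH)
        nterm = sigmod.naive_nterm_classifier(s)
        if nterm == "sec" and "sec" not in planned:
            span = _find_sec_run(s)
            if span is not None:
                dirty |= resample(*span)
        elif nterm == "mito" and "mito" not in planned:
            dirty |= resample(0, sigmod.MITO_SCAN_WINDOW)
        if not dirty:
            return s
    raise ScreenError("signal scrubbing did not converge")  # pragma: no cover


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class TruthRow:
    species_id: str
    protein_id: str
    family_id: str  # family id or "decoy"
    signals: frozenset[str]
    loss_species: bool


@dataclass
class GroundTruth:
    """Planted facts: which proteins trace to which families and signals."""

    rows: list[TruthRow] = field(default_factory=list)

    def species_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.species_id, None)
        return list(seen)

    def loss_species(self) -> set[str]:
        return {r.species_id for r in self.rows if r.loss_species}

    def proteins_of(self, species_id: str, family_id: str) -> list[str]:
        return [
            r.protein_id
            for r in self.rows
            if r.species_id == species_id and r.family_id == family_id
        ]

    def signals_of(self, protein_id: str) -> frozenset[str]:
        for r in self.rows:
            if r.protein_id == protein_id:
                return r.signals
        raise KeyError(protein_id)

    def planted_orthogroup_count(self, species_id: str) -> int:
        return len(
            {
                r.family_id
                for r in self.rows
                if r.species_id == species_id and r.family_id != "decoy"
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        write_tsv(
            path,
            ["species_id", "protein_id", "family_id", "signals", "loss_species"],
            (
                (
                    r.species_id,
                    r.protein_id,
                    r.family_id,
                    ",".join(sorted(r.signals)) or "-",
                    int(r.loss_species),
                )
                for r in self.rows
            ),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        header, rows = read_tsv(path)
        expected = ["species_id", "protein_id", "family_id", "signals", "loss_species"]
        if header != expected:
            raise InputError(f"{path}: unexpected ground-truth header {header}")
        out = cls()
        for sp, pid, fam, sigs, loss in rows:
            out.rows.append(
                TruthRow(
                    species_id=sp,
                    protein_id=pid,
                    family_id=fam,
                    signals=frozenset() if sigs == "-" else frozenset(sigs.split(",")),
                    loss_species=loss == "1",
                )
            )
        return out


# ---------------------------------------------------------------------------
# proteome and cohort generation


def generate_proteome(
    species: SpeciesSpec,
    families: Mapping[str, MarkerFamily],
    rng_seed: int,
    scrub_chance_motifs: bool = True,
) -> tuple[Proteome, list[TruthRow]]:
    """Emit one species proteome (planted members + decoys) and truth rows."""
    for fam in species.present_families():
        if fam not in families:
            raise ConfigError(
                f"{species.species_id}: family {fam} marked present but not generated"
            )
    rng = substream(rng_seed, "proteome", species.species_id)
    loss = species.is_full_loss()
    records: dict[str, str] = {}
    truth: list[TruthRow] = []

    for fam in species.present_families():
        family = families[fam]
        pid = planted_protein_id(species.species_id, fam)
        planned = frozenset(species.signal_plan.get(pid, frozenset()))
        seq = _decode(
            _mutate(encode(family.consensus), family.spec.divergence, rng)
        )
        seq, protected = _plant_all(seq, planned, rng)
        if scrub_chance_motifs:
            seq = scrub_chance_signals(seq, planned, rng, protected)
        records[pid] = seq
        truth.append(
            TruthRow(species.species_id, pid, fam, planned, loss)
        )

    lo, hi = species.decoy_length_range
    for i in range(species.n_decoys):
        pid = f"{species.species_id}_decoy{i + 1:03d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _decode(rng.integers(0, len(CANONICAL), size=length))
        if scrub_chance_motifs:
            seq = scrub_chance_signals(seq, frozenset(), rng)
        records[pid] = seq
        truth.append(
            TruthRow(species.species_id, pid, "decoy", frozenset(), loss)
        )

    return Proteome(species.species_id, records), truth


@dataclass(frozen=True)
class CohortPaths:
    """Locations of the on-disk fixture set written by generate_cohort."""

    root: Path
    proteome_dir: Path
    family_dir: Path
    truth_path: Path
    panel_path: Path
    config_path: Path


def generate_cohort(
    species_specs: Sequence[SpeciesSpec],
    family_specs: Sequence[MarkerFamilySpec],
    rng_seed: int,
    out_dir: str | Path,
    scrub_chance_motifs: bool = True,
) -> CohortPaths:
    """Write a full cohort fixture set: FASTAs, alignments, truth, panel."""
    root = Path(out_dir)
    if not root.parent.exists():
        raise InputError(f"parent of output directory does not exist: {root.parent}")
    proteome_dir = root / "proteomes"
    family_dir = root / "families"
    for d in (root, proteome_dir, family_dir):
        d.mkdir(exist_ok=True)

    families: dict[str, MarkerFamily] = {}
    for fspec in family_specs:
        fam = generate_marker_family(fspec, rng_seed)
        families[fspec.family_id] = fam
        write_fasta(family_dir / f"{fspec.family_id}.aln.fasta", fam.members)

    truth = GroundTruth()
    for sspec in species_specs:
        proteome, rows = generate_proteome(
            sspec, families, rng_seed, scrub_chance_motifs
        )
        proteome.to_fasta(proteome_dir / f"{sspec.species_id}.fasta")
        truth.rows.extend(rows)

    truth_path = root / "ground_truth.tsv"
    truth.to_tsv(truth_path)

    panel = MarkerPanel(
        tuple(
            PanelEntry(f.family_id, f.marker_class, f.essential)
            for f in family_specs
        )
    )
    panel_path = root / "panel.json"
    panel.to_json(panel_path)

    config_path = root / "cohort_config.json"
    config_path.write_text(
        json.dumps(
            {
                "rng_seed": int(rng_seed),
                "scrub_chance_motifs": scrub_chance_motifs,
                "families": [
                    {
                        "family_id": f.family_id,
                        "marker_class": f.marker_class,
                        "essential": f.essential,
                        "n_seed_seqs": f.n_seed_seqs,
                        "seq_length": f.seq_length,
                        "divergence": f.divergence,
                    }
                    for f in family_specs
                ],
                "species": [
                    {
                        "species_id": s.species_id,
                        "presence_plan": dict(s.presence_plan),
                        "signal_plan": {
                            k: sorted(v) for k, v in s.signal_plan.items()
                        },
                        "n_decoys": s.n_decoys,
                        "decoy_length_range": list(s.decoy_length_range),
                    }
                    for s in species_specs
                ],
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    return CohortPaths(
        root=root,
        proteome_dir=proteome_dir,
        family_dir=family_dir,
        truth_path=truth_path,
        panel_path=panel_path,
        config_path=config_path,
    )


# ---------------------------------------------------------------------------
# the default study cohort


#: enzyme families a full-loss species still retains (with non-peroxisomal
#: or no targeting signals), mirroring the reduced enzyme sets of
#: peroxisome-free genomes — including a catalase that carries a secretory
#: signal peptide instead of a PTS.
LOSS_RETAINED_ENZYMES = ("Cat", "Prdx5", "Gstk1", "Ech1", "Scp2", "Xdh")

#: enzyme signal plans for peroxisome-bearing species: most matrix enzymes
#: get a PTS1; the classical PTS2 cargo thiolase (Acaa1) and phytanoyl-CoA
#: hydroxylase (Phyh) get a PTS2; carnitine acetyltransferase (Crat) is
#: dually targeted (PTS1 + mitochondrial presequence).
_COMPLETE_ENZYME_SIGNALS: dict[str, frozenset[str]] = {
    **{f: frozenset({"pts1"}) for f in ENZYME_FAMILIES},
    "Acaa1": frozenset({"pts2"}),
    "Phyh": frozenset({"pts2"}),
    "Crat": frozenset({"pts1", "mito"}),
}

_LOSS_ENZYME_SIGNALS: dict[str, frozenset[str]] = {
    "Cat": frozenset({"sec"}),
    "Ech1": frozenset({"mito"}),
}


def default_family_specs(
    divergence: float = 0.1, n_seed_seqs: int = 8
) -> list[MarkerFamilySpec]:
    """The 47-family default panel (14 peroxins + 33 enzymes)."""
    specs = []
    all_families = list(PEROXIN_FAMILIES) + list(ENZYME_FAMILIES)
    for i, fam in enumerate(all_families):
        cls = "peroxin" if fam in PEROXIN_FAMILIES else "enzyme"
        specs.append(
            MarkerFamilySpec(
                family_id=fam,
                marker_class=cls,
                essential=fam in ESSENTIAL_PEROXINS,
                n_seed_seqs=n_seed_seqs,
                seq_length=140 + (i * 13) % 140,  # 140..273 residues
                divergence=divergence,
            )
        )
    return specs


def _species(
    species_id: str,
    present: Iterable[str],
    signal_map: Mapping[str, frozenset[str]],
    all_families: Sequence[str],
    n_decoys: int,
) -> SpeciesSpec:
    present = set(present)
    plan = {f: ("present" if f in present else "absent") for f in all_families}
    signal_plan = {
        planted_protein_id(species_id, fam): sigs
        for fam, sigs in signal_map.items()
        if fam in present
    }
    return SpeciesSpec(
        species_id=species_id,
        presence_plan=plan,
        signal_plan=signal_plan,
        n_decoys=n_decoys,
    )


def default_cohort_specs(
    n_complete: int = 16,
    n_loss: int = 6,
    n_decoys: int = 20,
) -> list[SpeciesSpec]:
    """The default 24-species cohort.

    16 complete species carry all 47 families; 6 full-loss species carry no
    peroxins and only a reduced enzyme set without peroxisomal signals; one
    species lacks only Pex7 (the PTS2 receptor, lost in nematodes) and one
    lacks only Pex26 (repeatedly lost among invertebrates).
    """
    fams = list(PEROXIN_FAMILIES) + list(ENZYME_FAMILIES)
    specs: list[SpeciesSpec] = []
    for i in range(n_complete):
        specs.append(
            _species(
                f"complete{i + 1:02d}", fams, _COMPLETE_ENZYME_SIGNALS, fams, n_decoys
            )
        )
    for i in range(n_loss):
        specs.append(
            _species(
                f"loss{i + 1:02d}",
                LOSS_RETAINED_ENZYMES,
                _LOSS_ENZYME_SIGNALS,
                fams,
                n_decoys,
            )
        )
    specs.append(
        _species(
            "pex7less",
            [f for f in fams if f != "Pex7"],
            _COMPLETE_ENZYME_SIGNALS,
            fams,
            n_decoys,
        )
    )
    specs.append(
        _species(
            "pex26less",
            [f for f in fams if f != "Pex26"],
            _COMPLETE_ENZYME_SIGNALS,
            fams,
            n_decoys,
        )
    )
    return specs
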
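"""End-to-end screen: profiles -> assignments -> signals -> verdicts.

Orchestrates the full presence/absence screen over a directory of
proteomes, using either the built-in profile scorer (family alignments)
or pre-computed HMMER3 domain tables, and writes every result table as a
deterministic TSV plus a JSON run manifest.  All randomness (calibration
nulls) derives from the single config seed through named substreams, so
a config + seed fixes every output byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .config import RunConfig
from .errors import ConfigError, InputError
from .inference import (
    ComplexityCount,
    LossCall,
    PresenceMatrix,
    apply_vetting_overrides,
    build_enzyme_matrix,
    build_presence_matrix,
    call_peroxisome_loss,
    count_orthogroups,
    read_vetting_tsv,
    write_complexity_tsv,
    write_enzyme_matrix_tsv,
    write_loss_calls_tsv,
)
from .io import Proteome, load_proteome_dir, read_alignment, write_tsv
from .panel import MarkerPanel, default_panel
from .profiles import (
    MarkerAssignment,
    SearchHit,
    assign_orthogroups,
    build_profile,
    calibrate_evalue,
    parse_domtbl,
    search_proteome,
)
from .signals import TargetingCall, call_targeting, parse_nterm_predictions
from .synthetic import substream

logger = logging.getLogger("peroxiscan")


@dataclass
class ScreenResult:
    """In-memory results plus the paths of the written tables."""

    output_dir: Path
    panel: MarkerPanel
    assignments: list[MarkerAssignment]
    targeting_calls: dict[str, TargetingCall]
    presence: PresenceMatrix
    loss_calls: list[LossCall]
    enzyme_matrix: dict
    complexity: list[ComplexityCount]
    backends: dict[str, str]

    @property
    def tsv_paths(self) -> list[Path]:
        return sorted(self.output_dir.glob("*.tsv"))


def _load_panel(config: RunConfig) -> MarkerPanel:
    if config.panel_file:
        return MarkerPanel.from_json(config.panel_file)
    return default_panel()


def _build_calibrated_profiles(config: RunConfig, panel: MarkerPanel):
    family_dir = Path(config.family_dir)
    if not family_dir.is_dir():
        raise InputError(f"family alignment directory not found: {family_dir}")
    profiles = []
    for family_id in panel.family_ids:
        candidates = [
            family_dir / f"{family_id}.aln.fasta",
            family_dir / f"{family_id}.fasta",
        ]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise InputError(
                f"no alignment for panel family {family_id} in {family_dir}"
            )
        profile = build_profile(
            read_alignment(path), family_id, pseudocount=config.pseudocount
        )
        profile = calibrate_evalue(
            profile,
            n_null=config.n_null,
            null_length=config.null_length_multiplier * profile.kept_column_count,
            rng_seed=substream(config.rng_seed, "calibration", family_id),
        )
        profiles.append(profile)
    return profiles


def _hits_for_species(
    config: RunConfig, proteome: Proteome, profiles
) -> tuple[list[SearchHit], str]:
    """Hits for one species via domtbl ingestion or the built-in scorer."""
    if config.domtbl_dir:
        domtbl = Path(config.domtbl_dir) / f"{proteome.species_id}.domtbl"
        if domtbl.exists():
            with open(domtbl, encoding="utf-8") as fh:
                return parse_domtbl(fh, species_id=proteome.species_id), "domtbl"
    if profiles is None:
        raise InputError(
            f"no domtbl file for {proteome.species_id} and no family "
            f"alignments configured"
        )
    return search_proteome(profiles, proteome), "builtin"


def run_screen(config: RunConfig) -> ScreenResult:
    """Run the full screen and write all output tables.

    Stages: profile build + calibration (or domtbl ingestion), acceptance
    filter and best-vs-next assignment, targeting-signal scan, presence
    matrix (+ optional vetting overrides), loss calls, enzyme
    localization matrix and unique-orthogroup counts.
    """
    if not config.output_dir:
        raise ConfigError("output_dir is required")
    out = Path(config.output_dir)
    if not out.parent.exists():
        raise InputError(f"parent of output directory does not exist: {out.parent}")
    out.mkdir(exist_ok=True)

    panel = _load_panel(config)
    proteomes = load_proteome_dir(config.proteome_dir)
    logger.info("[load] %d species, %d panel families", len(proteomes), len(panel.family_ids))

    profiles = None
    if config.family_dir:
        profiles = _build_calibrated_profiles(config, panel)
        logger.info("[profiles] built and calibrated %d profiles", len(profiles))

    nterm_maps: dict[str, dict[str, str]] = {}
    if config.nterm_dir:
        for proteome in proteomes:
            path = Path(config.nterm_dir) / f"{proteome.species_id}.tsv"
            if path.exists():
                with open(path, encoding="utf-8") as fh:
                    nterm_maps[proteome.species_id] = parse_nterm_predictions(fh)

    assignments: list[MarkerAssignment] = []
    targeting_calls: dict[str, TargetingCall] = {}
    backends: dict[str, str] = {}
    n_proteins: dict[str, int] = {}
    for proteome in proteomes:
        n_proteins[proteome.species_id] = len(proteome)
        hits, backend = _hits_for_species(config, proteome, profiles)
        backends[proteome.species_id] = backend
        species_assignments = assign_orthogroups(
            hits,
            evalue_max=config.evalue_max,
            enext_default=config.enext_default,
            score_high=config.score_high,
            log_base=config.log_base,
        )
        assignments.extend(species_assignments)
        nterm = nterm_maps.get(proteome.species_id)
        for pid, seq in proteome:
            targeting_calls[pid] = call_targeting(
                pid, seq, nterm, window_rule=config.pts2_window_rule
            )
        logger.info(
            "[search] %s: %d hits, %d assignments (%s backend)",
            proteome.species_id, len(hits), len(species_assignments), backend,
        )

    presence = build_presence_matrix(
        assignments, panel, species_ids=[p.species_id for p in proteomes]
    )
    if config.vetting_file:
        verdicts = read_vetting_tsv(config.vetting_file)
        presence = apply_vetting_overrides(presence, verdicts)
        logger.info("[vetting] applied %d verdicts", len(verdicts))

    loss_calls = call_peroxisome_loss(presence, panel, n_proteins=n_proteins)
    enzyme_matrix = build_enzyme_matrix(
        assignments, targeting_calls, panel,
        species_ids=[p.species_id for p in proteomes],
    )
    complexity = [
        count_orthogroups(assignments, p.species_id) for p in proteomes
    ]
    logger.info(
        "[infer] %d loss calls (%d lost)",
        len(loss_calls),
        sum(c.verdict == "peroxisomes_lost" for c in loss_calls),
    )

    # --- write tables -----------------------------------------------------
    write_tsv(
        out / "assignments.tsv",
        [
            "species_id", "protein_id", "family_id", "ehit", "enext",
            "score", "confidence", "backend",
        ],
        (
            (
                a.species_id, a.protein_id, a.family_id,
                f"{a.ehit:.6g}", f"{a.enext:.6g}", f"{a.score:.6g}",
                a.confidence, a.backend,
            )
            for a in assignments
        ),
    )
    write_tsv(
        out / "targeting_calls.tsv",
        ["protein_id", "pts1", "pts2_start", "nterm", "nterm_source", "category"],
        (
            (
                c.protein_id,
                c.pts1 or "-",
                c.pts2[1] if c.pts2 else "-",
                c.nterm,
                c.nterm_source,
                c.category,
            )
            for c in sorted(targeting_calls.values(), key=lambda c: c.protein_id)
        ),
    )
    presence.to_tsv(out / "presence_matrix.tsv")
    write_loss_calls_tsv(out / "loss_calls.tsv", loss_calls)
    write_enzyme_matrix_tsv(
        out / "enzyme_matrix.tsv", enzyme_matrix, panel,
        [p.species_id for p in proteomes],
    )
    write_complexity_tsv(out / "complexity.tsv", complexity)

    manifest = {
        "package_version": __version__,
        "config": {
            k: v for k, v in vars(config).items()
        },
        "config_sha256": config.sha256(),
        "rng_seed": config.rng_seed,
        "backends": backends,
        "stage_counts": {
            "species": len(proteomes),
            "panel_families": len(panel.family_ids),
            "assignments": len(assignments),
            "targeting_calls": len(targeting_calls),
            "lost_species": sum(
                c.verdict == "peroxisomes_lost" for c in loss_calls
            ),
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    return ScreenResult(
        output_dir=out,
        panel=panel,
        assignments=assignments,
        targeting_calls=targeting_calls,
        presence=presence,
        loss_calls=loss_calls,
        enzyme_matrix=enzyme_matrix,
        complexity=complexity,
        backends=backends,
    )
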
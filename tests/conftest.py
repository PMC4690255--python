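"""Shared fixtures: generated cohorts, screen runs, domtbl formatting."""

from __future__ import annotations

import dataclasses

import pytest

from peroxiscan import RunConfig, default_cohort_specs, default_family_specs
from peroxiscan.pipeline import run_screen
from peroxiscan.synthetic import GroundTruth, SpeciesSpec, generate_cohort


def screen_cohort(paths, out_dir, seed, **overrides):
    """Run the screen over a generated cohort with default parameters."""
    cfg = RunConfig(
        proteome_dir=str(paths.proteome_dir),
        family_dir=str(paths.family_dir),
        panel_file=str(paths.panel_path),
        output_dir=str(out_dir),
        rng_seed=seed,
        **overrides,
    )
    return run_screen(cfg)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Lazily cached (paths, screen result, truth) per seed, default cohort."""
    cache: dict[int, tuple] = {}

    def _run(seed: int):
        if seed not in cache:
            root = tmp_path_factory.mktemp(f"default-cohort-seed{seed}")
            paths = generate_cohort(
                default_cohort_specs(),
                default_family_specs(),
                rng_seed=seed,
                out_dir=root / "cohort",
            )
            result = screen_cohort(paths, root / "screen", seed)
            cache[seed] = (paths, result, GroundTruth.from_tsv(paths.truth_path))
        return cache[seed]

    return _run


def small_cohort_specs(n_decoys: int = 8):
    """A fast 4-species cohort over the full 47-family panel at length 80.

    Signal plans are stripped (80-residue proteins are too short for PTS2
    planting); presence/loss structure matches the default cohort shape.
    """
    families = [
        dataclasses.replace(f, seq_length=80, n_seed_seqs=4)
        for f in default_family_specs()
    ]
    species = []
    for spec in default_cohort_specs(n_decoys=n_decoys):
        if spec.species_id in ("complete01", "complete02", "loss01", "pex7less"):
            species.append(
                SpeciesSpec(
                    species_id=spec.species_id,
                    presence_plan=dict(spec.presence_plan),
                    signal_plan={},
                    n_decoys=n_decoys,
                    decoy_length_range=(40, 160),
                )
            )
    return species, families


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Generated small cohort fixture (paths only, seed 7)."""
    root = tmp_path_factory.mktemp("small-cohort")
    species, families = small_cohort_specs()
    return generate_cohort(species, families, rng_seed=7, out_dir=root / "cohort")


def format_domtbl(hits) -> str:
    """Render SearchHits in the HMMER3 per-domain table layout.

    Columns follow the documented order (target, accession, tlen, query,
    accession, qlen, full-seq E-value/score/bias, domain number/total,
    c-Evalue, i-Evalue, domain score/bias, hmm/ali/env coordinates, acc,
    description); E-values and scores are written at full precision so a
    parse round-trip preserves them exactly.
    """
    lines = [
        "#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target",
        "#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------",
    ]
    for h in hits:
        lines.append(
            f"{h.protein_id} - 100 {h.family_id} - 100 "
            f"{h.evalue!r} {h.raw_score!r} 0.0 1 1 "
            f"{h.evalue!r} {h.evalue!r} {h.raw_score!r} 0.0 "
            f"1 100 1 100 1 100 0.99 -"
        )
    return "\n".join(lines) + "\n"
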
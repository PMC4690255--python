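# Methods

## The screen

The pipeline decides, per species, whether a genome still encodes
peroxisomes.  It rests on two biological facts: (i) the peroxin import
machinery is the organelle's most reliable genomic marker, because matrix
enzyme content varies widely between species; and (ii) Pex3 and Pex19 are
individually essential for biogenesis, so their joint absence — and a
fortiori the absence of every peroxin — is read as loss of the organelle
itself rather than loss of a pathway.  The default marker panel is the
core metazoan set: 14 peroxins (Pex1, 2, 3, 5, 6, 7, 10, 11, 12, 13, 14,
16, 19 and the Pex1/Pex6 membrane anchor Pex26) and 33 families of
candidate matrix enzymes covering beta-oxidation, plasmalogen synthesis
(including both fatty acyl-CoA reductases Far1 and Far2), amino-acid and
oxygen metabolism, and purine catabolism.

## Marker detection and E-values

Each family is defined by a multiple protein alignment.  Columns with a
gap fraction above 0.5 are dropped; each kept column scores residue *a*
as

    log2( (count_a + c·bg_a) / (n + c) / bg_a )      (bits)

with pseudocount weight `c = 1` and background `bg` uniform over the 20
canonical residues.  The ambiguity residue X scores 0 in every column;
all other ambiguity codes are normalised to X on input.

A query is scored by the best ungapped placement of the profile along the
sequence (maximum over complete placements of the summed column
log-odds).  When the sequence is *shorter* than the profile, the best
partial-overlap placement covering at least half of the columns is used,
with every uncovered column contributing its expected background score.
This neutral completion keeps partial scores on the same full-profile
scale the E-value calibration is fitted on; summing only the covered
columns would put short sequences hundreds of bits above the full-length
null mean and make every short decoy look significant.

E-values come from an empirical Gumbel (type-I extreme-value) fit: the
profile is scored against `n_null` i.i.d. uniform-background sequences
and the method-of-moments estimates

    beta = sd · sqrt(6) / pi,    mu = mean − gamma · beta

(γ the Euler–Mascheroni constant) define
`E(s) = N · (1 − exp(−exp(−(s − mu)/beta)))`, with `N` the number of
proteins in the searched proteome, so an E-value reads as expected chance
hits per per-species search.  Null sequences default to **8× the profile
length**: adjacent placements share almost all their columns, so a null
sequence of length L contributes only about L/k effectively independent
placement maxima, and several are needed before the per-sequence maximum
approaches extreme-value behaviour.  (At 1× the fit is visibly wrong;
fit quality, measured as Kolmogorov–Smirnov distance of fresh-null
p-values from uniformity, improves steadily through 2×–8×.)  The
screening pipeline itself uses a 2× multiplier (`null_length_multiplier`)
for speed: the screen only needs to separate planted-family scores
(hundreds of bits above the null) from decoys, and the Gumbel right tail
is heavier than the sub-Gaussian truth, i.e. conservative.

Externally computed HMMER3 searches can replace the built-in scorer: the
per-domain tabular format (`--domtblout`) is ingested with target name →
protein, query name → family, independent E-value → E-value, domain bit
score → raw score.  Both backends feed identical downstream stages.

## Best-vs-next assignment

Hits with E-value above `evalue_max = 1e-3` are discarded as false
positives.  Surviving hits of one protein are collapsed to one per family
(minimum E-value; E-value then family id breaks ties deterministically)
and ranked; the best family is assigned iff

    Score = log10(Enext) − log10(Ehit) > 0,

i.e. only strict winners are assignments — a tie scores 0 and is not
reported.  `Enext` is the next-best *distinct family* for the *same
protein*; when no second family survives, it defaults to `evalue_max`
itself, the least favourable accepted value, so a lone strong hit still
scores positive (`enext_default_rule` makes this configurable).  Base-10
logs make the score read as orders of magnitude of E-value separation;
any base preserves the sign law.  Non-positive E-values are floored at
1e-300 before logs, with a logged warning, never an exception.  A score
margin ≥ 2 (`score_high`, a hundred-fold separation) marks a cell
high-confidence; weaker cells are flagged for external vetting, and a
verdict table (`confirm`/`reject`) can promote or erase them — the
package deliberately ingests such verdicts (e.g. from a phylogenetic
analysis) rather than producing them.

## Targeting signals and localization categories

PTS1: the extreme C-terminal tripeptide must match `[SAC][KRHN][LIM]` or
be one of the seven accepted deviations ASL, THL, LKL, SKV, KKL, SQL,
PRL — 43 accepted tripeptides in all (36 class members + 7 non-overlapping
exceptions).  PTS2: the 10-position pattern
`[RK][LVIQ]..[LVIHQ][LSGAK]..[HQ][LAF]`, with the whole match contained
in residues 1–100 (1-based).  The containment reading was chosen because
the signal is described as residing near the N-terminus; a `start_only`
switch relaxes it to "start ≤ 100".  The pattern is implemented verbatim
with its 10 positions even though PTS2 is often called a nonapeptide;
no 9-position variant is guessed.  Matching is case-insensitive; X never
satisfies a character class but does match wildcard positions.
Coordinates are 1-based inclusive everywhere.

N-terminal mitochondrial/secretory classes are normally ingested from an
external predictor's two-column table (`M`/`S`/`O` or
`mito`/`sec`/`other`).  For self-contained synthetic cohorts a
deterministic rule-based classifier stands in: *sec* iff the first 30
residues contain ≥ 8 consecutive hydrophobic residues (AILMFVWC, an
h-region caricature); else *mito* iff the first 20 contain ≥ 3 of {R, K},
≥ 2 of {S, T} and no acidic residue (a presequence caricature); checked
in that order.  It is not a real predictor and real analyses should
ingest one; its only purpose is an exact generator/scanner round trip.

Per protein, the flags (pts = PTS1 or PTS2, mito, sec) collapse to eight
categories.  Per enzyme family and species, flags are pooled across all
assigned paralogs before collapsing — the only reading that yields mixed
categories such as pts_mito (e.g. carnitine acetyltransferase with a
PTS1 paralog and a mitochondrially targeted paralog) without
isoform-level data.

## Loss calls and complexity

Per species: `peroxisomes_lost` iff every panel peroxin cell is absent
after vetting; `peroxisomes_retained` iff at least one peroxin is present
with high confidence **and** both essential peroxins are present at any
confidence; everything else `indeterminate` with an explanatory note
(only-low-confidence evidence, missing essentials, or no protein data at
all — an empty proteome is never called lost, since absence of data is
not absence of genes).  Low-confidence evidence alone can never support
`retained`; this mirrors the practice of rejecting a lone weak hit after
phylogenetic scrutiny.  Genome complexity is the count of distinct
families (panel plus any background orthologous groups) with at least one
positive-score assignment; background groups never enter loss calling.

## The synthetic cohort generator

The generator emulates exactly the statistical structure the screen
assumes.  Each family has a uniform-random consensus; alignment members
and planted proteome members are drawn by independent per-site
substitution to a *different* residue with probability `divergence`
(expected member-consensus identity is exactly 1 − divergence).  The
default study cohort has 24 species over the 47-family panel at
divergence 0.1 (family lengths 140–273 residues, 8 alignment rows, 20
decoys per species of 80–400 residues): 16 complete species, 6 full-loss
species retaining only 6 enzymes (catalase with a secretory peptide,
enoyl-CoA hydratase with a mitochondrial presequence, the rest
signal-free — no peroxisomal signals anywhere), one species lacking only
Pex7 and one lacking only Pex26.  Complete species carry PTS1 on matrix
enzymes, PTS2 on the classical PTS2 cargoes (thiolase Acaa1,
phytanoyl-CoA hydroxylase Phyh), and dual targeting on Crat.

Planted signals are written so the corresponding scanner finds them by
construction; by default, chance occurrences of any signal class in
decoys or in unplanned regions of marker proteins are scrubbed (offending
windows resampled, planted regions untouched), so the emitted ground
truth is exact.  Scrubbing can be disabled (`--keep-chance-motifs`) to
measure chance-match rates (~0.5% of random C-terminal tripeptides are
valid PTS1s).  Decoy and null backgrounds are uniform over the 20
canonical residues; the generator never emits ambiguity codes, though all
parsers accept X.

What the generator does *not* emulate: phylogenetic covariance among
species, indels and gapped homology, compositional bias, paralog
expansions (one planted copy per present family by default), or
codon-level evolution.  Passing tests therefore demonstrate the
correctness of the screen's logic and calibration under its own model
assumptions, not detection power on real, indel-rich, biased proteomes —
for real data the HMMER backend is the intended path.

## Determinism and problem sizes

Every stage draws from named substreams of a single integer seed
(master seed + CRC-keyed labels per family/species/stage), so identical
config + seed reproduces every output byte; TSVs use UNIX newlines,
UTF-8 and fixed column orders to make that checkable with byte
comparison.  The shipped checks run the full 24-species screen over five
seeds, 10,000 random sequences per motif-scanner oracle comparison, and
1,000-sequence calibration nulls — a few minutes on one CPU.

## Known limitations

- The built-in scorer is ungapped (no forward/Viterbi, no domain
  architecture); it is a deliberate simplification, with real HMMER
  ingestion as the production path.
- The Gumbel law is an approximation to the null score distribution;
  with method-of-moments fitting the KS distance of fresh-null p-values
  from uniformity sits near the α = 0.01 critical line for some profiles
  even at the 8× null-length default, so individual calibration checks
  can fail for unlucky profile/seed pairs while E-value ordering remains
  sound.
- Calibration uses one null length per profile; query-length dependence
  of the ungapped maximum is not modelled (short queries are handled by
  the neutral-completion rule instead).
- No phylogenetic inference: lineage-independence of losses is not
  assessed, and ambiguous hits are only flagged for external vetting.
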
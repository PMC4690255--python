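"""Targeting-signal detection and localization-category assignment.

Two peroxisomal targeting signals are scanned with fixed amino-acid
patterns:

* PTS1 — a C-terminal tripeptide, canonically Ser-Lys-Leu.  Accepted
  tripeptides are the character-class pattern ``[SAC][KRHN][LIM]`` plus
  seven enumerated mammalian deviations (ASL, THL, LKL, SKV, KKL, SQL,
  PRL), 43 tripeptides in total.  Only the extreme C-terminus counts.
* PTS2 — the pattern ``[RK][LVIQ]..[LVIHQ][LSGAK]..[HQ][LAF]`` whose match
  must lie entirely within the first 100 residues (an optional relaxed
  rule requires only the start position to be <= 100).

N-terminal mitochondrial presequences and secretory signal peptides are
normally ingested from an external predictor's tabular output; a small
deterministic rule-based classifier is included so fully synthetic cohorts
need no external tool.  The three flags (pts = pts1 or pts2, mito, sec)
collapse into eight localization categories.

Matching is case-insensitive.  The ambiguity residue X never satisfies a
character class but does match wildcard ('.') positions; other
non-canonical letters are normalised to X first.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import IO, Iterable

from .alphabet import CANONICAL, normalize
from .errors import FormatError

PTS1_CLASS = ("SAC", "KRHN", "LIM")
PTS1_EXCEPTIONS = ("ASL", "THL", "LKL", "SKV", "KKL", "SQL", "PRL")

# wildcard positions accept any canonical residue or X
_DOT = f"[{CANONICAL}X]"
PTS2_REGEX = re.compile(
    f"[RK][LVIQ]{_DOT}{_DOT}[LVIHQ][LSGAK]{_DOT}{_DOT}[HQ][LAF]"
)
PTS2_LENGTH = 10
PTS2_WINDOW = 100  # the match must sit inside residues 1..100 (1-based)

# rule-based N-terminus classifier (mirrored exactly by the cohort generator)
HYDROPHOBIC = frozenset("AILMFVWC")
SEC_RUN_LENGTH = 8
SEC_SCAN_WINDOW = 30
MITO_SCAN_WINDOW = 20

CATEGORIES = (
    "none", "pts", "mito", "sec", "pts_mito", "pts_sec", "sec_mito",
    "pts_mito_sec",
)


def pts1_accepted_tripeptides() -> frozenset[str]:
    """All tripeptides accepted as PTS1 (36 class members + 7 exceptions)."""
    class_members = {
        "".join(t) for t in itertools.product(*PTS1_CLASS)
    }
    return frozenset(class_members | set(PTS1_EXCEPTIONS))


_PTS1_SET = pts1_accepted_tripeptides()


def scan_pts1(sequence: str) -> str | None:
    """Return the C-terminal tripeptide if it is an accepted PTS1, else None."""
    if len(sequence) < 3:
        return None
    tail = normalize(sequence[-3:])
    return tail if tail in _PTS1_SET else None


def scan_pts2(
    sequence: str, window_rule: str = "containment"
) -> tuple[str, int] | None:
    """Leftmost PTS2 match near the N-terminus, as (10-mer, 1-based start).

    ``window_rule='containment'`` (default) requires the whole 10-residue
    match inside residues 1-100; ``'start_only'`` requires only the start
    position to be <= 100.
    """
    if window_rule not in ("containment", "start_only"):
        raise ValueError(f"unknown window_rule {window_rule!r}")
    if window_rule == "containment":
        region = normalize(sequence[:PTS2_WINDOW])
    else:
        region = normalize(sequence[: PTS2_WINDOW + PTS2_LENGTH - 1])
    m = PTS2_REGEX.search(region)
    if m is None:
        return None
    return m.group(0), m.start() + 1


def naive_nterm_classifier(sequence: str) -> str:
    """Deterministic stand-in for an N-terminal targeting-sequence predictor.

    sec: >= 8 consecutive hydrophobic residues (AILMFVWC) within the first
    30 positions (a signal-peptide-like h-region).  Otherwise mito: within
    the first 20 positions, >= 3 of {R, K}, >= 2 of {S, T} and no acidic
    residue (a presequence-like arginine-rich amphipathic stretch).
    Checked in that order; anything else is 'none'.
    """
    s = normalize(sequence)
    run = 0
    for ch in s[:SEC_SCAN_WINDOW]:
        run = run + 1 if ch in HYDROPHOBIC else 0
        if run >= SEC_RUN_LENGTH:
            return "sec"
    head = s[:MITO_SCAN_WINDOW]
    basic = sum(ch in "RK" for ch in head)
    hydroxyl = sum(ch in "ST" for ch in head)
    acidic = any(ch in "DE" for ch in head)
    if basic >= 3 and hydroxyl >= 2 and not acidic:
        return "mito"
    return "none"


_NTERM_TOKENS = {
    "M": "mito", "mito": "mito",
    "S": "sec", "sec": "sec",
    "O": "none", "other": "none",
}


def parse_nterm_predictions(stream: IO[str] | Iterable[str]) -> dict[str, str]:
    """Parse a two-column (protein_id, class) table of N-terminal predictions.

    Accepted class tokens are {M, S, O} or {mito, sec, other}.  Proteins
    absent from the table default to 'none' downstream.
    """
    result: dict[str, str] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise FormatError(
                f"N-terminal prediction line {lineno}: expected 2 columns, "
                f"got {len(fields)}"
            )
        protein_id, token = fields[0], fields[1]
        if token not in _NTERM_TOKENS:
            raise FormatError(
                f"N-terminal prediction line {lineno}: unknown class "
                f"{token!r} (expected M/S/O or mito/sec/other)"
            )
        result[protein_id] = _NTERM_TOKENS[token]
    return result


def combine_localization(
    pts1: str | None,
    pts2: tuple[str, int] | None,
    nterm: str | Iterable[str],
) -> str:
    """Collapse the signal flags into one of eight categories.

    ``nterm`` is a single token (mito/sec/none) for one protein, or an
    iterable of tokens when flags are pooled across the paralogs of a
    family — only pooling can produce the sec_mito and pts_mito_sec
    combinations.
    """
    pts = pts1 is not None or pts2 is not None
    tokens = {nterm} if isinstance(nterm, str) else set(nterm)
    unknown = tokens - {"mito", "sec", "none"}
    if unknown:
        raise ValueError(f"unknown nterm tokens {sorted(unknown)}")
    mito = "mito" in tokens
    sec = "sec" in tokens
    if pts and mito and sec:
        return "pts_mito_sec"
    if pts and mito:
        return "pts_mito"
    if pts and sec:
        return "pts_sec"
    if mito and sec:
        return "sec_mito"
    if pts:
        return "pts"
    if mito:
        return "mito"
    if sec:
        return "sec"
    return "none"


@dataclass(frozen=True)
class TargetingCall:
    """Per-protein signal flags collapsed to a localization category."""

    protein_id: str
    pts1: str | None
    pts2: tuple[str, int] | None
    nterm: str  # mito | sec | none
    nterm_source: str  # ingested | builtin
    category: str

    def __post_init__(self) -> None:
        # start <= 100 covers both window rules (containment and start_only)
        if self.pts2 is not None and self.pts2[1] > PTS2_WINDOW:
            raise ValueError("pts2 start outside the N-terminal window")

    @property
    def flags(self) -> frozenset[str]:
        out = set()
        if self.pts1 is not None or self.pts2 is not None:
            out.add("pts")
        if self.nterm in ("mito", "sec"):
            out.add(self.nterm)
        return frozenset(out)


def call_targeting(
    protein_id: str,
    sequence: str,
    nterm_predictions: dict[str, str] | None = None,
    window_rule: str = "containment",
) -> TargetingCall:
    """Scan one protein and emit its TargetingCall.

    When ``nterm_predictions`` is given, the N-terminal class is looked up
    there (missing proteins -> none, source 'ingested'); otherwise the
    built-in rule-based classifier runs.
    """
    pts1 = scan_pts1(sequence)
    pts2 = scan_pts2(sequence, window_rule=window_rule)
    if nterm_predictions is not None:
        nterm = nterm_predictions.get(protein_id, "none")
        source = "ingested"
    else:
        nterm = naive_nterm_classifier(sequence)
        source = "builtin"
    return TargetingCall(
        protein_id=protein_id,
        pts1=pts1,
        pts2=pts2,
        nterm=nterm,
        nterm_source=source,
        category=combine_localization(pts1, pts2, nterm),
    )
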
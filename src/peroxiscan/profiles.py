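"""Profile construction, scoring, E-value calibration and marker assignment.

A marker family is defined by a multiple protein alignment.  From it we
build an ungapped position-specific scoring matrix (log-odds in bits per
column), calibrate an empirical E-value by fitting a Gumbel (type-I
extreme-value) law to scores of random background sequences, and scan
query proteomes with it.  Externally computed HMMER3 searches can be
ingested from per-domain tabular (``--domtblout``) files instead; both
backends feed the same assignment step.

Assignment follows a best-versus-next-hit rule: hits with E-value above
``evalue_max`` (default 1e-3) are discarded as false positives, the
surviving hits of one protein are ranked by E-value, and the best family
is accepted only when

    score = log10(Enext) - log10(Ehit) > 0,

i.e. only strict winners are assigned.  ``Enext`` is the E-value of the
next-best *distinct family* for the same protein, defaulting to
``evalue_max`` when no second family survives.  Assignments with a score
margin >= 2 (a hundred-fold E-value separation) are classed high
confidence, the rest low.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import IO, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .alphabet import CANONICAL, X_INDEX, encode, uniform_background
from .errors import CalibrationError, ConfigError, FormatError, InputError
from .io import Proteome

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")
EULER_GAMMA = float(np.euler_gamma)

#: hits with E-value above this are not even reported
REPORT_CEILING = 10.0

#: floor applied before taking logs so degenerate E-values stay finite
EVALUE_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# profile construction


@dataclass(frozen=True)
class ScoringProfile:
    """Per-column log-odds matrix for one marker family.

    ``matrix`` has shape (kept_column_count, 21): one bits entry per
    canonical residue plus a zero-scoring X column.  ``mu``/``beta`` are
    the Gumbel location/scale fitted on null scores; they are None until
    :func:`calibrate_evalue` has run.
    """

    family_id: str
    matrix: np.ndarray
    kept_column_count: int
    null_col_mean: np.ndarray | None = None
    mu: float | None = None
    beta: float | None = None
    null_sample_size: int = 0

    @property
    def calibrated(self) -> bool:
        return self.mu is not None and self.beta is not None

    def survival(self, score: float | np.ndarray) -> float | np.ndarray:
        """Per-sequence p-value: P(null score >= score) under the fitted Gumbel."""
        if not self.calibrated:
            raise ConfigError(f"profile {self.family_id} is not calibrated")
        with np.errstate(over="ignore"):
            z = np.exp(-(np.asarray(score, dtype=float) - self.mu) / self.beta)
            p = -np.expm1(-z)
        return float(p) if np.isscalar(score) else p

    def evalue(self, score: float, database_size: int) -> float:
        """Expected chance hits at this score in a database of the given size."""
        return database_size * float(self.survival(score))


def build_profile(
    alignment: Sequence[tuple[str, str]] | Sequence[str],
    family_id: str = "",
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> ScoringProfile:
    """Build an uncalibrated log-odds profile from an aligned family.

    Columns with a gap fraction above ``max_gap_fraction`` are dropped.
    Each kept column scores residue ``a`` as

        log2( (count_a + pseudocount * bg_a) / (n + pseudocount) / bg_a )

    where ``n`` is the number of counted (canonical) residues in the
    column.  The ambiguity residue X scores 0 everywhere.
    """
    rows = [seq if isinstance(seq, str) else seq[1] for seq in alignment]
    if len(rows) < 2:
        raise ConfigError("profile construction needs at least 2 aligned sequences")
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be positive")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"ragged alignment (row lengths {sorted(lengths)})")
    if background is None:
        background = uniform_background()
    background = np.asarray(background, dtype=float)

    n_rows = len(rows)
    columns: list[np.ndarray] = []
    for j in range(lengths.pop()):
        col = [r[j].upper() for r in rows]
        gap_fraction = sum(c in GAP_CHARS for c in col) / n_rows
        if gap_fraction > max_gap_fraction:
            continue
        counts = np.zeros(len(CANONICAL))
        for c in col:
            if c in GAP_CHARS:
                continue
            idx = encode(c)[0]
            if idx != X_INDEX:  # X and other ambiguity codes are not counted
                counts[idx] += 1
        total = counts.sum()
        freq = (counts + pseudocount * background) / (total + pseudocount)
        columns.append(np.log2(freq / background))

    matrix = np.zeros((len(columns), len(CANONICAL) + 1))
    if columns:
        matrix[:, : len(CANONICAL)] = np.vstack(columns)
    return ScoringProfile(
        family_id=family_id,
        matrix=matrix,
        kept_column_count=len(columns),
        null_col_mean=matrix[:, : len(CANONICAL)] @ background,
    )


# ---------------------------------------------------------------------------
# scoring


def _full_placement_scores(matrix: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Scores of every complete placement of the profile along one sequence."""
    k = matrix.shape[0]
    windows = sliding_window_view(idx, k)  # (n - k + 1, k)
    return matrix[np.arange(k), windows].sum(axis=1)


def _best_partial_score(
    matrix: np.ndarray, null_col_mean: np.ndarray, idx: np.ndarray
) -> float:
    """Best partial-overlap placement covering >= 50% of profile columns.

    Used only when the sequence is shorter than the profile.  Columns the
    sequence does not cover contribute their expected background score,
    which keeps partial scores on the same full-profile scale that the
    E-value calibration was fitted on (a random fragment then scores near
    the null mean instead of far above it).  Returns -inf when even the
    50%-coverage requirement cannot be met.
    """
    k = matrix.shape[0]
    n = idx.size
    min_cols = -(-k // 2)  # ceil(k / 2)
    if n < min_cols:
        return -math.inf
    # Work in column-centered space (each column minus its background
    # expectation): uncovered columns then contribute exactly 0, so padding
    # the sequence with a neutral extra symbol turns every partial overlap
    # into a complete placement of the centered profile.  The X column of
    # the centered matrix becomes -null_col_mean, preserving "X scores 0"
    # on the original scale.
    centered = matrix - null_col_mean[:, None]
    cmat = np.hstack([centered, np.zeros((k, 1))])
    pad = np.full(k - min_cols, cmat.shape[1] - 1, dtype=idx.dtype)
    ext = np.concatenate([pad, idx, pad])
    windows = sliding_window_view(ext, k)
    scores = cmat[np.arange(k), windows].sum(axis=1)
    return float(scores.max() + null_col_mean.sum())


def score_sequence(profile: ScoringProfile, sequence: str | np.ndarray) -> float:
    """Best ungapped placement score (bits) of the profile on a sequence.

    The maximum over all complete placements of the sum of column
    log-odds; when the sequence is shorter than the profile, the best
    partial-overlap placement covering at least half of the columns,
    with uncovered columns contributing their expected background score.
    """
    idx = encode(sequence) if isinstance(sequence, str) else sequence
    if idx.size == 0:
        raise InputError("cannot score an empty sequence")
    k = profile.matrix.shape[0]
    if k == 0:
        raise ConfigError(f"profile {profile.family_id} has no kept columns")
    if idx.size >= k:
        return float(_full_placement_scores(profile.matrix, idx).max())
    null_col_mean = (
        profile.null_col_mean
        if profile.null_col_mean is not None
        else profile.matrix[:, : len(CANONICAL)].mean(axis=1)
    )
    return _best_partial_score(profile.matrix, null_col_mean, idx)


# ---------------------------------------------------------------------------
# E-value calibration


def sample_null_scores(
    profile: ScoringProfile,
    n_null: int,
    null_length: int,
    rng: np.random.Generator,
    null_background: np.ndarray | None = None,
) -> np.ndarray:
    """Score ``n_null`` i.i.d. random background sequences against the profile."""
    if null_background is None:
        probs = uniform_background()
    else:
        probs = np.asarray(null_background, dtype=float)
        probs = probs / probs.sum()
    k = profile.matrix.shape[0]
    if null_length < k:
        raise ConfigError(
            f"null_length {null_length} shorter than profile length {k}"
        )
    draws = rng.choice(len(CANONICAL), size=(n_null, null_length), p=probs)
    # gather in chunks: the fancy-indexed (chunk, m, k) block is materialized
    m = null_length - k + 1
    chunk = max(1, int(2e7 // (m * k)))
    scores = np.empty(n_null)
    cols = np.arange(k)
    for lo in range(0, n_null, chunk):
        windows = sliding_window_view(draws[lo: lo + chunk], k, axis=1)
        scores[lo: lo + chunk] = (
            profile.matrix[cols, windows].sum(axis=2).max(axis=1)
        )
    return scores


def calibrate_evalue(
    profile: ScoringProfile,
    null_background: np.ndarray | None = None,
    n_null: int = 1000,
    null_length: int | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> ScoringProfile:
    """Fit Gumbel E-value parameters from scores of random sequences.

    Method-of-moments fit: ``beta = sd * sqrt(6) / pi`` and
    ``mu = mean - euler_gamma * beta``.  Thereafter the E-value of a raw
    score ``s`` against a database of ``N`` sequences is
    ``N * (1 - exp(-exp(-(s - mu) / beta)))``.

    ``null_length`` defaults to eight times the profile length.  Adjacent
    placements share almost all their columns, so a null sequence of
    length L contributes only about L/k effectively independent placement
    maxima; several of them are needed before the per-sequence maximum is
    well described by an extreme-value law.
    """
    if n_null < 200:
        raise ConfigError(f"n_null must be >= 200, got {n_null}")
    k = profile.matrix.shape[0]
    if null_length is None:
        null_length = 8 * k
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    scores = sample_null_scores(profile, n_null, null_length, rng, null_background)
    sd = float(scores.std(ddof=1))
    if not np.isfinite(sd) or sd <= 1e-12:
        raise CalibrationError(
            f"profile {profile.family_id}: degenerate null-score variance"
        )
    beta = sd * math.sqrt(6.0) / math.pi
    mu = float(scores.mean()) - EULER_GAMMA * beta
    return replace(profile, mu=mu, beta=beta, null_sample_size=n_null)


# ---------------------------------------------------------------------------
# searching and ingestion


@dataclass(frozen=True)
class SearchHit:
    """One (protein, family) hit with raw score and E-value."""

    species_id: str
    protein_id: str
    family_id: str
    raw_score: float
    evalue: float
    backend: str  # builtin | domtbl


def search_proteome(
    profiles: Sequence[ScoringProfile],
    proteome: Proteome,
    report_ceiling: float = REPORT_CEILING,
) -> list[SearchHit]:
    """Scan every protein against every calibrated profile.

    The E-value database size is the number of proteins in the searched
    proteome, so E-values read as expected chance hits per per-species
    search.  Hits above ``report_ceiling`` are dropped.
    """
    for p in profiles:
        if not p.calibrated:
            raise ConfigError(f"profile {p.family_id} is not calibrated")
    database_size = len(proteome)
    hits: list[SearchHit] = []
    encoded = [(pid, encode(seq)) for pid, seq in proteome]
    for profile in profiles:
        for pid, idx in encoded:
            if idx.size == 0:
                continue
            raw = score_sequence(profile, idx)
            ev = profile.evalue(raw, database_size)
            if ev <= report_ceiling:
                hits.append(
                    SearchHit(
                        species_id=proteome.species_id,
                        protein_id=pid,
                        family_id=profile.family_id,
                        raw_score=raw,
                        evalue=ev,
                        backend="builtin",
                    )
                )
    return hits


#: column layout of HMMER3 ``--domtblout`` (22 fixed columns + description)
_DOMTBL_MIN_COLUMNS = 22
_DOMTBL_TARGET, _DOMTBL_QUERY = 0, 3
_DOMTBL_I_EVALUE, _DOMTBL_DOM_SCORE = 12, 13


def parse_domtbl(
    stream: IO[str] | Iterable[str], species_id: str = ""
) -> list[SearchHit]:
    """Ingest HMMER3 per-domain tabular output as SearchHits.

    Target name -> protein_id, query name -> family_id, the independent
    E-value column -> evalue and the domain bit score -> raw_score.
    Multiple lines for one (protein, family) pair are all retained;
    assignment later uses the minimum E-value.
    """
    hits: list[SearchHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) < _DOMTBL_MIN_COLUMNS:
            raise FormatError(
                f"domtbl line {lineno}: expected >= {_DOMTBL_MIN_COLUMNS} "
                f"columns, got {len(fields)}"
            )
        try:
            evalue = float(fields[_DOMTBL_I_EVALUE])
            score = float(fields[_DOMTBL_DOM_SCORE])
        except ValueError as exc:
            raise FormatError(f"domtbl line {lineno}: non-numeric field ({exc})")
        hits.append(
            SearchHit(
                species_id=species_id,
                protein_id=fields[_DOMTBL_TARGET],
                family_id=fields[_DOMTBL_QUERY],
                raw_score=score,
                evalue=evalue,
                backend="domtbl",
            )
        )
    return hits


# ---------------------------------------------------------------------------
# assignment


@dataclass(frozen=True)
class MarkerAssignment:
    """A protein's accepted best-family hit and its best-vs-next score."""

    species_id: str
    protein_id: str
    family_id: str
    ehit: float
    enext: float
    score: float
    confidence: str  # high | low
    backend: str


def assign_orthogroups(
    hits: Iterable[SearchHit],
    evalue_max: float = 1e-3,
    enext_default: float | None = None,
    score_high: float = 2.0,
    log_base: float = 10.0,
) -> list[MarkerAssignment]:
    """Apply the acceptance filter and best-vs-next-hit scoring per protein.

    Hits with E-value above ``evalue_max`` are discarded.  Per protein the
    surviving hits are collapsed to one per family (minimum E-value) and
    ranked; the best family is assigned iff
    ``score = log(Enext) - log(Ehit) > 0`` (strict winner).  When only one
    family survives, ``Enext`` falls back to ``enext_default`` (the
    acceptance threshold itself unless overridden).  Logs are base 10 by
    default; any base preserves the sign law.  Non-positive E-values are
    floored at 1e-300 with a logged warning.
    """
    if evalue_max <= 0:
        raise ConfigError("evalue_max must be positive")
    if enext_default is None:
        enext_default = evalue_max

    by_protein: dict[tuple[str, str], list[SearchHit]] = {}
    for hit in hits:
        if hit.evalue > evalue_max:
            continue
        by_protein.setdefault((hit.species_id, hit.protein_id), []).append(hit)

    def _log(x: float) -> float:
        if x <= 0:
            logger.warning("E-value %g floored at %g before log", x, EVALUE_FLOOR)
            x = EVALUE_FLOOR
        # math.log10 is correctly rounded, so scores on round E-values are exact
        return math.log10(x) if log_base == 10.0 else math.log(x, log_base)

    assignments: list[MarkerAssignment] = []
    for (species_id, protein_id), protein_hits in sorted(by_protein.items()):
        best_per_family: dict[str, SearchHit] = {}
        for hit in protein_hits:
            prev = best_per_family.get(hit.family_id)
            if prev is None or hit.evalue < prev.evalue:
                best_per_family[hit.family_id] = hit
        ranked = sorted(
            best_per_family.values(), key=lambda h: (h.evalue, h.family_id)
        )
        best = ranked[0]
        enext = ranked[1].evalue if len(ranked) > 1 else enext_default
        score = _log(enext) - _log(best.evalue)
        if score <= 0:
            continue  # ties and non-winners are not assignments
        assignments.append(
            MarkerAssignment(
                species_id=species_id,
                protein_id=protein_id,
                family_id=best.family_id,
                ehit=max(best.evalue, EVALUE_FLOOR),
                enext=max(enext, EVALUE_FLOOR),
                score=score,
                confidence="high" if score >= score_high else "low",
                backend=best.backend,
            )
        )
    return assignments
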
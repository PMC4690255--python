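"""Profile build/scoring, Gumbel calibration, domtbl ingestion, assignment."""

from __future__ import annotations

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peroxiscan.alphabet import CANONICAL, encode
from peroxiscan.errors import (
    CalibrationError,
    ConfigError,
    FormatError,
    InputError,
)
from peroxiscan.io import Proteome
from peroxiscan.profiles import (
    SearchHit,
    assign_orthogroups,
    build_profile,
    calibrate_evalue,
    parse_domtbl,
    sample_null_scores,
    score_sequence,
    search_proteome,
)
from peroxiscan.synthetic import MarkerFamilySpec, generate_marker_family, substream

from conftest import format_domtbl


def oracle_score(profile, seq: str) -> float:
    """Exhaustive enumeration of every placement, partials included.

    Complete placements sum the column log-odds under each position;
    partial placements (sequence shorter than the profile) must cover at
    least half of the columns, and uncovered columns contribute their
    expected background score.
    """
    matrix = profile.matrix
    nm = profile.null_col_mean
    k = matrix.shape[0]
    idx = encode(seq)
    n = idx.size
    best = -math.inf
    if n >= k:
        for t in range(n - k + 1):
            best = max(
                best, sum(matrix[j, idx[t + j]] for j in range(k))
            )
        return best
    min_cols = -(-k // 2)
    for t in range(-(k - 1), n):
        lo, hi = max(0, t), min(n, t + k)
        if hi - lo < min_cols:
            continue
        covered = sum(matrix[p - t, idx[p]] for p in range(lo, hi))
        uncovered = sum(
            nm[j] for j in range(k) if not (lo - t) <= j < (hi - t)
        )
        best = max(best, covered + uncovered)
    return best


@pytest.fixture(scope="module")
def pex5_profile():
    spec = MarkerFamilySpec("Pex5", "peroxin", seq_length=200, divergence=0.1)
    family = generate_marker_family(spec, 3)
    profile = build_profile(family.members, "Pex5")
    return family, profile


class TestBuildProfile:
    def test_consensus_residue_attains_column_max(self):
        rows = ["ACDE", "ACDE", "ACDE"]
        profile = build_profile(rows, "fam")
        for j, aa in enumerate("ACDE"):
            col = profile.matrix[j, : len(CANONICAL)]
            assert col.argmax() == CANONICAL.index(aa)

    def test_majority_gap_column_dropped(self):
        rows = ["A-CD", "A-CD", "AEC-", "A-CD"]  # col 2: 3/4 gaps; col 4: 1/4
        profile = build_profile(rows, "fam")
        # brute-force gap fractions: [0, 0.75, 0, 0.25] -> one column dropped
        assert profile.kept_column_count == 3

    def test_ragged_alignment_rejected(self):
        with pytest.raises(FormatError, match="ragged"):
            build_profile(["ACD", "AC"], "fam")

    def test_single_row_rejected(self):
        with pytest.raises(ConfigError):
            build_profile(["ACD"], "fam")

    def test_x_scores_zero_everywhere(self):
        profile = build_profile(["ACDE", "ACDE"], "fam")
        assert np.all(profile.matrix[:, -1] == 0.0)

    def test_consensus_beats_shuffles(self, pex5_profile):
        family, profile = pex5_profile
        consensus = family.consensus
        base = score_sequence(profile, consensus)
        rng = np.random.default_rng(0)
        for _ in range(100):
            shuffled = "".join(
                rng.permutation(list(consensus))
            )
            assert score_sequence(profile, shuffled) <= base


class TestScoreSequence:
    def test_zero_divergence_consensus_hits_column_maxima(self):
        spec = MarkerFamilySpec(
            "fam", "enzyme", seq_length=50, divergence=0.0, n_seed_seqs=5
        )
        family = generate_marker_family(spec, 1)
        profile = build_profile(family.members, "fam")
        expected = profile.matrix[:, : len(CANONICAL)].max(axis=1).sum()
        assert score_sequence(profile, family.consensus) == pytest.approx(expected)

    def test_reversed_consensus_scores_lower(self, pex5_profile):
        family, profile = pex5_profile
        fwd = score_sequence(profile, family.consensus)
        rev = score_sequence(profile, family.consensus[::-1])
        assert rev < fwd

    def test_flanking_residues_do_not_change_score(self, pex5_profile):
        family, profile = pex5_profile
        base = score_sequence(profile, family.consensus)
        flanked = "GGGGG" + family.consensus + "PPPPP"
        assert score_sequence(profile, flanked) == pytest.approx(base)

    def test_empty_sequence_rejected(self, pex5_profile):
        _, profile = pex5_profile
        with pytest.raises(InputError):
            score_sequence(profile, "")

    def test_matches_exhaustive_enumeration(self):
        """Vectorized scorer equals brute-force placement enumeration."""
        rng = np.random.default_rng(5)
        spec = MarkerFamilySpec(
            "tiny", "enzyme", seq_length=10, divergence=0.3, n_seed_seqs=4
        )
        profile = build_profile(
            generate_marker_family(spec, 9).members, "tiny"
        )
        for _ in range(60):
            n = int(rng.integers(5, 51))  # spans partial and full placements
            seq = "".join(
                CANONICAL[i] for i in rng.integers(0, len(CANONICAL), size=n)
            )
            assert score_sequence(profile, seq) == pytest.approx(
                oracle_score(profile, seq)
            )


class TestCalibration:
    def test_evalue_strictly_decreasing_in_score(self, pex5_profile):
        _, profile = pex5_profile
        cal = calibrate_evalue(profile, n_null=300, rng_seed=0)
        # below ~mu - 2*beta the survival saturates to 1.0 in float64
        scores = np.linspace(cal.mu - 2 * cal.beta, cal.mu + 60, 50)
        evalues = [cal.evalue(s, 1000) for s in scores]
        assert all(a > b for a, b in zip(evalues, evalues[1:]))

    def test_evalue_at_mu_is_0632_of_database(self, pex5_profile):
        _, profile = pex5_profile
        cal = calibrate_evalue(profile, n_null=300, rng_seed=0)
        assert cal.evalue(cal.mu, 100) == pytest.approx(
            100 * (1 - math.exp(-1)), rel=1e-9
        )

    def test_degenerate_null_variance_raises(self):
        flat = build_profile(["XXXXX", "XXXXX"], "flat")  # all-zero columns
        with pytest.raises(CalibrationError):
            calibrate_evalue(flat, n_null=200, rng_seed=0)

    def test_n_null_floor(self, pex5_profile):
        _, profile = pex5_profile
        with pytest.raises(ConfigError):
            calibrate_evalue(profile, n_null=100, rng_seed=0)

    def test_fresh_null_tail_fraction(self, pex5_profile):
        """About 10% of fresh null sequences score above the p=0.1 line."""
        _, profile = pex5_profile
        cal = calibrate_evalue(profile, n_null=1000, rng_seed=substream(0, "cal"))
        fresh = sample_null_scores(
            cal, 1000, 8 * cal.kept_column_count, substream(0, "fresh")
        )
        frac = float(np.mean(cal.survival(fresh) <= 0.1))
        assert 0.06 <= frac <= 0.14


class TestSearchProteome:
    def test_empty_proteome(self, pex5_profile):
        _, profile = pex5_profile
        cal = calibrate_evalue(profile, n_null=300, rng_seed=0)
        assert search_proteome([cal], Proteome("sp", {})) == []

    def test_planted_member_recovered_and_decoys_clean(self, pex5_profile):
        family, profile = pex5_profile
        cal = calibrate_evalue(profile, n_null=300, rng_seed=0)
        rng = np.random.default_rng(17)
        consensus_idx = encode(family.consensus)
        mask = rng.random(consensus_idx.size) < 0.1
        member_idx = consensus_idx.copy()
        member_idx[mask] = (member_idx[mask] + rng.integers(
            1, 20, size=int(mask.sum()))) % 20
        member = "".join(CANONICAL[i] for i in member_idx)
        records = {"sp_Pex5": member}
        for i in range(40):
            n = int(rng.integers(80, 401))
            records[f"sp_decoy{i}"] = "".join(
                CANONICAL[j] for j in rng.integers(0, 20, size=n)
            )
        hits = search_proteome([cal], Proteome("sp", records))
        planted = [h for h in hits if h.protein_id == "sp_Pex5"]
        assert planted and planted[0].evalue <= 1e-3
        dirty = {
            h.protein_id for h in hits
            if h.protein_id != "sp_Pex5" and h.evalue <= 1e-3
        }
        assert len(dirty) <= 2  # >= 95% of 40 decoys stay clean

    def test_uncalibrated_profile_rejected(self, pex5_profile):
        _, profile = pex5_profile
        with pytest.raises(ConfigError):
            search_proteome([profile], Proteome("sp", {"p": "ACDE"}))


class TestParseDomtbl:
    def test_comment_only_stream(self):
        text = "# comment\n#another\n\n"
        assert parse_domtbl(io.StringIO(text)) == []

    def test_roundtrip_through_formatter(self):
        original = [
            SearchHit("sp", "prot1", "Pex5", 123.4, 1e-12, "builtin"),
            SearchHit("sp", "prot2", "Cat", 55.5, 2.5e-4, "builtin"),
        ]
        parsed = parse_domtbl(io.StringIO(format_domtbl(original)), species_id="sp")
        assert [(h.protein_id, h.family_id, h.evalue, h.raw_score) for h in parsed] \
            == [(h.protein_id, h.family_id, h.evalue, h.raw_score) for h in original]
        assert all(h.backend == "domtbl" for h in parsed)

    def test_duplicate_lines_all_retained(self):
        hits = [
            SearchHit("sp", "p", "fam", 10.0, 1e-5, "builtin"),
            SearchHit("sp", "p", "fam", 8.0, 1e-4, "builtin"),
        ]
        parsed = parse_domtbl(io.StringIO(format_domtbl(hits)))
        assert len(parsed) == 2
        assignments = assign_orthogroups(parsed)
        assert assignments[0].ehit == 1e-5  # downstream takes the minimum

    def test_short_line_raises_with_line_number(self):
        with pytest.raises(FormatError, match="line 2"):
            parse_domtbl(io.StringIO("# header\np1 - 100 fam\n"))

    def test_real_hmmer_output_parses(self, tmp_path):
        """A genuine HMMER3 domtbl (via pyhmmer) round-trips through the parser."""
        import pyhmmer

        spec = MarkerFamilySpec("Pex5", "peroxin", seq_length=120, divergence=0.1)
        family = generate_marker_family(spec, 3)
        abc = pyhmmer.easel.Alphabet.amino()
        msa = pyhmmer.easel.TextMSA(
            name=b"Pex5",
            sequences=[
                pyhmmer.easel.TextSequence(name=name.encode(), sequence=seq)
                for name, seq in family.members
            ],
        ).digitize(abc)
        hmm, _, _ = pyhmmer.plan7.Builder(abc).build_msa(
            msa, pyhmmer.plan7.Background(abc)
        )
        rng = np.random.default_rng(2)
        targets = [("sp_Pex5", family.consensus)] + [
            (
                f"sp_decoy{i}",
                "".join(CANONICAL[j] for j in rng.integers(0, 20, size=150)),
            )
            for i in range(5)
        ]
        block = pyhmmer.easel.DigitalSequenceBlock(
            abc,
            [
                pyhmmer.easel.TextSequence(
                    name=n.encode(), sequence=s
                ).digitize(abc)
                for n, s in targets
            ],
        )
        top = pyhmmer.plan7.Pipeline(abc).search_hmm(hmm, block)
        path = tmp_path / "sp.domtbl"
        with open(path, "wb") as fh:
            top.write(fh, format="domains", header=True)
        with open(path, encoding="utf-8") as fh:
            parsed = parse_domtbl(fh, species_id="sp")
        best = min(parsed, key=lambda h: h.evalue)
        assert best.protein_id == "sp_Pex5"
        assert best.family_id == "Pex5"
        assert best.evalue < 1e-3


class TestAssignOrthogroups:
    def _hit(self, protein, family, evalue):
        return SearchHit("sp", protein, family, 0.0, evalue, "builtin")

    def test_strict_winner_score_is_log10_separation(self):
        hits = [self._hit("p", "A", 1e-10), self._hit("p", "B", 1e-5)]
        (a,) = assign_orthogroups(hits)
        assert (a.family_id, a.ehit, a.enext) == ("A", 1e-10, 1e-5)
        assert a.score == 5.0
        assert a.confidence == "high"

    def test_tie_emits_no_assignment(self):
        hits = [self._hit("p", "A", 1e-4), self._hit("p", "B", 1e-4)]
        assert assign_orthogroups(hits) == []

    def test_lone_hit_uses_enext_default(self):
        (a,) = assign_orthogroups([self._hit("p", "A", 1e-6)])
        assert (a.enext, a.score, a.confidence) == (1e-3, 3.0, "high")

    def test_above_threshold_hit_discarded(self):
        assert assign_orthogroups([self._hit("p", "A", 5e-3)]) == []

    def test_zero_evalue_floored_not_fatal(self):
        hits = [self._hit("p", "A", 0.0), self._hit("p", "B", 1e-5)]
        (a,) = assign_orthogroups(hits)
        assert a.ehit == 1e-300
        assert a.score == 295.0

    def test_low_confidence_below_margin(self):
        hits = [self._hit("p", "A", 1e-5), self._hit("p", "B", 5e-5)]
        (a,) = assign_orthogroups(hits)
        assert 0 < a.score < 2
        assert a.confidence == "low"

    @settings(max_examples=150, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["p1", "p2"]),
                st.sampled_from(["A", "B", "C"]),
                st.floats(1e-12, 10.0),
            ),
            max_size=12,
        )
    )
    def test_sign_law(self, triples):
        """Assignments are exactly the strict winners: score > 0 <=> Ehit < Enext."""
        hits = [
            SearchHit("sp", p, f, 0.0, e, "builtin") for p, f, e in triples
        ]
        for a in assign_orthogroups(hits):
            assert a.score > 0
            assert a.ehit < a.enext
            assert a.ehit <= 1e-3
            # best surviving family for this protein is the assigned one
            survivors = [
                h for h in hits
                if h.protein_id == a.protein_id and h.evalue <= 1e-3
            ]
            assert min(s.evalue for s in survivors) == a.ehit

    def test_backend_equivalence_of_assignments(self):
        hits = [
            self._hit("p1", "A", 1e-9),
            self._hit("p1", "B", 1e-4),
            self._hit("p2", "C", 2e-4),
        ]
        via_domtbl = parse_domtbl(io.StringIO(format_domtbl(hits)), species_id="sp")
        a1 = assign_orthogroups(hits)
        a2 = assign_orthogroups(via_domtbl)
        strip = lambda xs: [
            (x.species_id, x.protein_id, x.family_id, x.ehit, x.enext,
             x.score, x.confidence)
            for x in xs
        ]
        assert strip(a1) == strip(a2)
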
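import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efam_forge.profile_hmm import (
    AMINO_ACIDS,
    BACKGROUND,
    TRANSITIONS,
    DegenerateAlignmentError,
    MultipleAlignment,
    ProfileHMM,
    align_cluster,
    assign_match_columns,
    build_profile,
    read_hmm_db,
    score_viterbi,
    write_hmm_db,
)
from efam_forge.protein_filter import ProteinRecord
from efam_forge.synth_fixtures import FixtureConfig, generate_families


def random_profile(rng, k=None):
    k = k or int(rng.integers(1, 8))
    match = rng.dirichlet(np.ones(20), size=k)
    insert = rng.dirichlet(np.ones(20), size=k + 1)
    trans = np.zeros((k + 1, 7))
    trans[:, 0:3] = rng.dirichlet(np.ones(3), size=k + 1)
    trans[:, 3:5] = rng.dirichlet(np.ones(2), size=k + 1)
    trans[:, 5:7] = rng.dirichlet(np.ones(2), size=k + 1)
    trans[k, TRANSITIONS.index("md")] = 0.0
    trans[k, TRANSITIONS.index("dd")] = 0.0
    trans[k, 0:3] /= trans[k, 0:3].sum()
    trans[k, 5:7] /= trans[k, 5:7].sum()
    return ProfileHMM(
        name=f"rand_{rng.integers(1 << 30)}",
        match_emissions=match,
        insert_emissions=insert,
        transitions=trans,
        n_seqs=int(rng.integers(2, 10)),
    )


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


class TestAlignCluster:
    def test_identical_sequences_gap_free(self):
        prots = [ProteinRecord("a", "MKTAYIAK"), ProteinRecord("b", "MKTAYIAK")]
        msa = align_cluster(prots, backend="builtin")
        assert all("-" not in seq for _, seq in msa.rows)
        assert msa.n_cols == 8

    def test_single_gap_for_one_residue_indel(self):
        prots = [ProteinRecord("a", "MKT"), ProteinRecord("b", "MKAT")]
        msa = align_cluster(prots, backend="builtin")
        assert msa.n_cols == 4
        by_id = dict(msa.rows)
        assert by_id["a"].count("-") == 1
        assert by_id["a"].replace("-", "") == "MKT"
        assert by_id["b"] == "MKAT"

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_cluster([ProteinRecord("a", "MKT")])

    def test_unknown_backend_rejected(self):
        prots = [ProteinRecord("a", "MKT"), ProteinRecord("b", "MKT")]
        with pytest.raises(ValueError):
            align_cluster(prots, backend="mystery")

    def test_deterministic_and_permutation_stable(self):
        cfg = FixtureConfig(seed=5, n_families=1, family_size_range=(4, 4),
                            divergence=0.1, indel_rate=0.02,
                            ancestor_length_range=(40, 60), n_contaminants=0)
        prots, _ = generate_families(cfg)
        msa1 = align_cluster(prots, backend="builtin")
        msa2 = align_cluster(list(reversed(prots)), backend="builtin")
        assert msa1.rows == msa2.rows

    def test_rows_preserve_sequences(self):
        cfg = FixtureConfig(seed=6, n_families=1, family_size_range=(5, 5),
                            divergence=0.15, indel_rate=0.05,
                            ancestor_length_range=(50, 80), n_contaminants=0)
        prots, _ = generate_families(cfg)
        msa = align_cluster(prots, backend="builtin")
        originals = {p.id: p.sequence for p in prots}
        for pid, row in msa.rows:
            assert row.replace("-", "") == originals[pid]


# ---------------------------------------------------------------------------
# Match column assignment
# ---------------------------------------------------------------------------


class TestAssignMatchColumns:
    def msa(self, rows):
        return MultipleAlignment("t", [(f"r{i}", s) for i, s in enumerate(rows)])

    def test_three_of_four_is_match(self):
        flags = assign_match_columns(self.msa(["A", "A", "A", "-"]))
        assert flags == [True]

    def test_one_of_four_is_insert(self):
        msa = self.msa(["AC", "A-", "A-", "A-"])
        assert assign_match_columns(msa) == [True, False]

    def test_gap_free_all_match(self):
        msa = self.msa(["ACD", "ACD"])
        assert assign_match_columns(msa) == [True, True, True]

    def test_exact_boundary_is_match(self):
        msa = self.msa(["A-", "AC"])  # 0.5 >= 0.5
        assert assign_match_columns(msa) == [True, True]

    def test_all_gap_alignment_rejected(self):
        msa = self.msa(["A---", "A---", "-C--", "--D-"])
        flags = assign_match_columns(msa)
        assert flags[0] is True
        with pytest.raises(DegenerateAlignmentError):
            assign_match_columns(self.msa(["AC", "--", "--", "--"]), symfrac=0.5)


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------


class TestBuildProfile:
    def test_laplace_arithmetic_single_row(self):
        msa = MultipleAlignment("t", [("r0", "A")])
        profile = build_profile(msa)
        a_idx = AMINO_ACIDS.index("A")
        assert profile.match_emissions[0][a_idx] == pytest.approx(2 / 21)

    def test_consensus_residue_is_argmax(self):
        msa = MultipleAlignment(
            "t", [("r0", "ACD"), ("r1", "ACD"), ("r2", "ACD")]
        )
        profile = build_profile(msa)
        for col, aa in enumerate("ACD"):
            assert (
                AMINO_ACIDS[int(np.argmax(profile.match_emissions[col]))] == aa
            )

    def test_observed_match_to_delete_transition(self):
        msa = MultipleAlignment("t", [("r0", "AC"), ("r1", "A-")])
        profile = build_profile(msa)
        md = profile.transitions[1][TRANSITIONS.index("md")]
        mm = profile.transitions[1][TRANSITIONS.index("mm")]
        # node 1 counts: one M->M (r0), one M->D (r1); +1 smoothing over 3
        assert md == pytest.approx(2 / 5)
        assert mm == pytest.approx(2 / 5)

    def test_normalization_invariants(self):
        msa = MultipleAlignment(
            "t", [("r0", "ACD-F"), ("r1", "AC-EF"), ("r2", "ACDEF")]
        )
        build_profile(msa).validate()

    def test_insert_emissions_are_background(self):
        msa = MultipleAlignment("t", [("r0", "AC"), ("r1", "A-")])
        profile = build_profile(msa)
        assert np.allclose(profile.insert_emissions, BACKGROUND)

    def test_nonstandard_residue_mapped_to_background(self):
        msa = MultipleAlignment("t", [("r0", "X"), ("r1", "X")])
        profile = build_profile(msa)
        profile.validate()
        # counts are background-weighted -> emissions stay near background
        assert np.abs(profile.match_emissions[0] - BACKGROUND).max() < 0.05


# ---------------------------------------------------------------------------
# Viterbi scoring with a brute-force path-enumeration oracle
# ---------------------------------------------------------------------------


def viterbi_bruteforce(profile, seq):
    """Enumerate all state paths through the M/I/D lattice recursively."""
    k = profile.length
    bg = profile.background

    def lt(node, key):
        p = profile.transitions[node][TRANSITIONS.index(key)]
        return math.log2(p) if p > 0 else -math.inf

    def emit(emissions, ch):
        i = AMINO_ACIDS.index(ch)
        return math.log2(emissions[i] / bg[i])

    best = -math.inf

    def walk(state, node, pos, score):
        nonlocal best
        if node == k and pos == len(seq):
            end = lt(k, {"M": "mm", "I": "im", "D": "dm"}[state])
            best = max(best, score + end)
            # an I at node k may still consume more residues; fall through
        # moves from (state, node, pos)
        prev = {"M": "m", "I": "i", "D": "d"}[state]
        if node < k and pos < len(seq):  # match next residue
            key = prev + "m"
            if key in TRANSITIONS:
                walk(
                    "M",
                    node + 1,
                    pos + 1,
                    score
                    + lt(node, key)
                    + emit(profile.match_emissions[node], seq[pos]),
                )
        if pos < len(seq) and state != "D":  # insert at current node
            key = prev + "i"
            if key in TRANSITIONS:
                walk(
                    "I",
                    node,
                    pos + 1,
                    score
                    + lt(node, key)
                    + emit(profile.insert_emissions[node], seq[pos]),
                )
        if node < k and state != "I":  # delete next node
            key = prev + "d"
            if key in TRANSITIONS:
                walk("D", node + 1, pos, score + lt(node, key))

    walk("M", 0, 0, 0.0)
    return best


class TestScoreViterbi:
    def test_matches_bruteforce_on_toys(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            profile = random_profile(rng, k=int(rng.integers(1, 4)))
            n = int(rng.integers(1, 5))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
            dp = score_viterbi(profile, seq)
            brute = viterbi_bruteforce(profile, seq)
            assert dp == pytest.approx(brute, abs=1e-9)

    def test_member_beats_reversed(self):
        msa = MultipleAlignment(
            "t", [(f"r{i}", "MKTAYIAKQR") for i in range(5)]
        )
        profile = build_profile(msa)
        s = "MKTAYIAKQR"
        assert score_viterbi(profile, s) > score_viterbi(profile, s[::-1])

    def test_uniform_profile_zero_emission_contribution(self):
        # emissions equal to background -> only transition costs remain,
        # and the all-match path dominates
        k = 4
        trans = np.zeros((k + 1, 7))
        trans[:, TRANSITIONS.index("mm")] = 1.0
        trans[:, TRANSITIONS.index("im")] = 1.0
        trans[:, TRANSITIONS.index("dm")] = 1.0
        profile = ProfileHMM(
            name="uniform",
            match_emissions=np.tile(BACKGROUND, (k, 1)),
            insert_emissions=np.tile(BACKGROUND, (k + 1, 1)),
            transitions=trans,
            n_seqs=1,
        )
        assert score_viterbi(profile, "ACDE") == pytest.approx(0.0)

    def test_empty_inputs_rejected(self):
        rng = np.random.default_rng(3)
        profile = random_profile(rng)
        with pytest.raises(ValueError):
            score_viterbi(profile, "")

    def test_member_scores_beat_shuffled(self):
        cfg = FixtureConfig(
            seed=9,
            n_families=20,
            family_size_range=(4, 6),
            divergence=0.08,
            ancestor_length_range=(60, 120),
            n_contaminants=0,
        )
        prots, truth = generate_families(cfg)
        rng = np.random.default_rng(1)
        wins = 0
        total = 0
        for fam in range(cfg.n_families):
            members = [p for p in prots if truth.family_of[p.id] == fam]
            msa = align_cluster(members, f"fam{fam}", backend="builtin")
            profile = build_profile(msa)
            member_scores, shuffled_scores = [], []
            for p in members:
                member_scores.append(score_viterbi(profile, p.sequence))
                shuffled = "".join(
                    rng.permutation(list(p.sequence)).tolist()
                )
                shuffled_scores.append(score_viterbi(profile, shuffled))
            total += 1
            if np.mean(member_scores) > np.mean(shuffled_scores):
                wins += 1
        assert wins == total


# ---------------------------------------------------------------------------
# Serialization round trips
# ---------------------------------------------------------------------------


class TestSerialization:
    def test_roundtrip_single(self, tmp_path):
        rng = np.random.default_rng(21)
        profile = random_profile(rng)
        path = tmp_path / "one.hmm"
        write_hmm_db([profile], path)
        back = read_hmm_db(path)[0]
        assert back.name == profile.name
        assert np.abs(back.match_emissions - profile.match_emissions).max() < 1e-4
        assert np.abs(back.insert_emissions - profile.insert_emissions).max() < 1e-4
        assert np.abs(back.transitions - profile.transitions).max() < 1e-4

    def test_roundtrip_many_random_profiles(self, tmp_path):
        rng = np.random.default_rng(22)
        profiles = []
        seen = set()
        while len(profiles) < 100:
            p = random_profile(rng)
            if p.name in seen:
                continue
            seen.add(p.name)
            profiles.append(p)
        path = tmp_path / "many.hmm"
        write_hmm_db(profiles, path)
        back = read_hmm_db(path)
        assert len(back) == 100
        for orig, rec in zip(profiles, back):
            assert rec.name == orig.name
            assert np.abs(rec.match_emissions - orig.match_emissions).max() < 1e-4
            assert np.abs(rec.transitions - orig.transitions).max() < 1e-4
            rec_norm = rec.match_emissions / rec.match_emissions.sum(
                axis=1, keepdims=True
            )
            assert np.allclose(rec_norm.sum(axis=1), 1.0)

    def test_zero_probability_serializes_as_star(self, tmp_path):
        rng = np.random.default_rng(23)
        profile = random_profile(rng, k=2)
        path = tmp_path / "star.hmm"
        write_hmm_db([profile], path)
        text = path.read_text()
        assert "*" in text  # terminal m->d / d->d are zero

    def test_terminator_count(self, tmp_path):
        rng = np.random.default_rng(24)
        profiles = [random_profile(rng, k=2) for _ in range(2)]
        profiles[1].name = profiles[0].name + "_b"
        path = tmp_path / "two.hmm"
        write_hmm_db(profiles, path)
        assert path.read_text().count("//") == 2

    def test_duplicate_names_rejected(self, tmp_path):
        rng = np.random.default_rng(25)
        p = random_profile(rng)
        with pytest.raises(ValueError):
            write_hmm_db([p, p], tmp_path / "dup.hmm")


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10_000))
def test_random_profiles_satisfy_normalization(seed):
    rng = np.random.default_rng(seed)
    random_profile(rng).validate()
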
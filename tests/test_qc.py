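import numpy as np
import pytest

from nifhamp.qc import (
    AttritionLog,
    Profile,
    ProfileError,
    ProteinSeq,
    Read,
    align_to_profile,
    clip_and_translate,
    dereplicate,
    filter_length_ambiguity,
    profile_align_filter,
    run_qc,
    trim_primers,
)
from nifhamp.simulate import (
    CONSENSUS,
    FWD_PRIMER,
    REV_PRIMER,
    VARIABLE_POSITIONS,
    back_translate,
    revcomp,
)

from .helpers import mutate


def _read(nt: str) -> Read:
    return Read("r1", "s1", nt)


class TestTrimPrimers:
    def test_exact_flanks_are_removed(self, rng):
        insert = back_translate(CONSENSUS, rng)
        read = _read(FWD_PRIMER + insert + revcomp(REV_PRIMER))
        out = trim_primers(read, FWD_PRIMER, REV_PRIMER)
        assert out.nt_seq == insert

    def test_missing_forward_primer_rejects(self, rng):
        read = _read("TTTT" + back_translate(CONSENSUS, rng))
        assert trim_primers(read, FWD_PRIMER, REV_PRIMER) is None

    def test_one_mismatch_in_forward_primer_is_tolerated(self, rng):
        insert = back_translate(CONSENSUS, rng)
        fwd = list(FWD_PRIMER)
        fwd[5] = "A" if fwd[5] != "A" else "C"
        read = _read("".join(fwd) + insert)
        out = trim_primers(read, FWD_PRIMER, REV_PRIMER)
        # trim point confirmed against plain string arithmetic
        assert out.nt_seq == read.nt_seq[len(FWD_PRIMER):] == insert

    def test_two_mismatches_reject(self, rng):
        insert = back_translate(CONSENSUS, rng)
        fwd = list(FWD_PRIMER)
        for i in (3, 7):
            fwd[i] = "A" if fwd[i] != "A" else "C"
        assert trim_primers(_read("".join(fwd) + insert), FWD_PRIMER, REV_PRIMER) is None

    def test_degenerate_primer_codes_match(self):
        read = _read("AG" + "ACGT" * 60)
        out = trim_primers(read, "RN", "GGGGG")
        assert out.nt_seq == "ACGT" * 60

    def test_missing_reverse_primer_is_tolerated(self, rng):
        insert = back_translate(CONSENSUS, rng)
        out = trim_primers(_read(FWD_PRIMER + insert), FWD_PRIMER, REV_PRIMER)
        assert out.nt_seq == insert


class TestLengthAmbiguityFilter:
    @pytest.mark.parametrize(
        "nt,passes,reason",
        [
            ("A" * 199, False, "short"),
            ("A" * 100 + "N" + "A" * 99, False, "ambiguous"),
            ("A" * 200, True, ""),
        ],
    )
    def test_boundaries(self, nt, passes, reason):
        ok, why = filter_length_ambiguity(_read(nt))
        assert ok is passes and why == reason


class TestClipTranslate:
    def test_sense_codons_give_60_residues(self, rng):
        nt = back_translate(CONSENSUS, rng) + "ACGTAA" * 10
        assert clip_and_translate(_read(nt)) == CONSENSUS

    def test_stop_codon_rejects(self, rng):
        nt = back_translate(CONSENSUS, rng)
        nt = nt[:18] + "TAA" + nt[21:]  # codon 7
        assert clip_and_translate(_read(nt + "A" * 60)) is None

    def test_clip_len_must_be_codon_multiple(self):
        with pytest.raises(ValueError):
            clip_and_translate(_read("A" * 300), clip_len=100)

    def test_single_deletion_frameshifts_tail(self, rng):
        nt = back_translate(CONSENSUS, rng) + back_translate(CONSENSUS, rng)
        shifted = nt[:50] + nt[51:]
        out = clip_and_translate(_read(shifted))
        if out is not None:  # no stop in the new frame: passes to profile stage
            assert out[:16] == CONSENSUS[:16]
            assert out != CONSENSUS


class TestDereplicate:
    def test_counts_are_aggregated(self):
        seqs = [("AAA", "s1"), ("AAA", "s1"), ("AAA", "s2"), ("CCC", "s2")]
        out = dereplicate(seqs)
        assert len(out) == 2
        assert out[0].aa_seq == "AAA" and out[0].per_sample_counts == {"s1": 2, "s2": 1}
        assert out[1].per_sample_counts == {"s2": 1}

    def test_empty_input(self):
        assert dereplicate([]) == []

    def test_count_conservation_on_random_input(self, rng):
        seqs = [
            (mutate(CONSENSUS, int(rng.integers(0, 3)), rng),
             f"s{rng.integers(3)}")
            for _ in range(200)
        ]
        out = dereplicate(seqs)
        assert sum(p.total for p in out) == 200


class TestProfileFilter:
    def test_consensus_is_retained(self, profile):
        score, insert_free = align_to_profile(CONSENSUS, profile)
        assert insert_free

    def test_inserted_residues_reject(self, profile):
        seq = CONSENSUS[:30] + "WWWWW" + CONSENSUS[30:]
        _, insert_free = align_to_profile(seq, profile)
        assert not insert_free

    def test_substitutions_alone_are_retained(self, profile, rng):
        conserved = [i for i in range(60) if i not in VARIABLE_POSITIONS]
        seq = list(CONSENSUS)
        for pos in rng.choice(conserved, size=3, replace=False):
            seq[pos] = "W"
        _, insert_free = align_to_profile("".join(seq), profile)
        assert insert_free

    def test_short_profile_is_config_error(self):
        small = Profile(np.zeros((10, 20)))
        with pytest.raises(ProfileError):
            profile_align_filter([ProteinSeq("p1", CONSENSUS, {"s": 1})], small)

    def test_batch_agrees_with_single_sequence_alignment(self, profile, rng):
        seqs = [mutate(CONSENSUS, int(rng.integers(0, 5)), rng) for _ in range(30)]
        seqs += [CONSENSUS[:25] + CONSENSUS[22:57]]  # shifted tail imitation
        pseqs = [ProteinSeq(f"p{i:03d}", s, {"s": 1}) for i, s in enumerate(seqs)]
        retained, rejected, audit = profile_align_filter(pseqs, profile)
        for p in pseqs:
            _, insert_free = align_to_profile(p.aa_seq, profile)
            assert insert_free == (p in retained)

    def test_profile_tsv_round_trip(self, profile, tmp_path):
        path = tmp_path / "profile.tsv"
        profile.to_tsv(path)
        back = Profile.from_tsv(path)
        np.testing.assert_allclose(back.match_scores, profile.match_scores)
        assert back.gap_open == profile.gap_open
        assert back.insert_penalty == profile.insert_penalty


class TestRunQC:
    def test_attrition_is_monotone_on_messy_input(self, profile, rng):
        reads = []
        insert = back_translate(CONSENSUS, rng) + back_translate(CONSENSUS, rng)[:145]
        reads.append(Read("good", "s", FWD_PRIMER + insert + revcomp(REV_PRIMER)))
        reads.append(Read("nofwd", "s", "T" * 250))
        reads.append(Read("short", "s", FWD_PRIMER + insert[:150]))
        reads.append(Read("ambig", "s", FWD_PRIMER + insert[:100] + "N" + insert[101:]))
        stop = insert[:18] + "TAA" + insert[21:]
        reads.append(Read("stop", "s", FWD_PRIMER + stop))
        frameshift = insert[:50] + insert[51:]
        reads.append(Read("fs", "s", FWD_PRIMER + frameshift))
        result = run_qc(reads, profile, FWD_PRIMER, REV_PRIMER)
        result.attrition.check_monotone()
        assert result.attrition.input == 6
        assert result.attrition.after_trim == 5
        assert result.attrition.after_length == 4
        assert result.attrition.after_ambiguity == 3
        stages = set(result.rejections.stage)
        assert {"trim", "length", "ambiguity"} <= stages

    def test_monotonicity_guard_raises_on_corrupt_log(self):
        log = AttritionLog(input=5, after_trim=6)
        with pytest.raises(AssertionError):
            log.check_monotone()

    def test_filter_and_dereplicate_commute(self, profile, rng):
        aas = [mutate(CONSENSUS, int(rng.integers(0, 4)), rng) for _ in range(50)]
        aas += [CONSENSUS[:20] + CONSENSUS[17:57]] * 3
        pairs = [(aa, f"s{rng.integers(2)}") for aa in aas]
        # filter each occurrence, then dereplicate
        survivors = []
        for aa, sample in pairs:
            _, free = align_to_profile(aa, profile)
            if free:
                survivors.append((aa, sample))
        direct = {p.aa_seq for p in dereplicate(survivors)}
        # dereplicate, then filter
        retained, _, _ = profile_align_filter(dereplicate(pairs), profile)
        assert direct == {p.aa_seq for p in retained}
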
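"""Masking, the iterative discovery protocol, and regex scanning."""

import numpy as np
import pytest

from limclass.annotation import DomainHit
from limclass.motifs import (
    MaskedSequence,
    MotifDefinition,
    MotifOccurrence,
    builtin_finder,
    iterative_discovery,
    mask_domains,
    mask_low_complexity,
    regex_to_pattern,
    scan_regex,
    unmasked_extension_pass,
)
from limclass.simulate import plant_motif_dataset

AA = "ACDEFGHIKLMNPQRSTVWY"


def rand_seqs(seed, n=12, length=120, prefix="Sy_R"):
    rng = np.random.default_rng(seed)
    return [
        MaskedSequence.from_plain(
            f"{prefix}{i}", "".join(rng.choice(list(AA), length))
        )
        for i in range(n)
    ]


class TestDomainMasking:
    def test_envelope_masked_with_provenance(self):
        seq = MaskedSequence.from_plain("Hs_X", "A" * 100)
        h = DomainHit("Hs_X", "PDZ", 10, 60, 10, 60, 1e-8)
        (masked,) = mask_domains([seq], [h])
        assert masked.n_masked == 51
        assert masked.provenance[9] == "pfam_domain"
        assert masked.provenance[8] == "none"
        assert len(masked.sequence) == 100

    def test_no_hits_identity(self):
        seq = MaskedSequence.from_plain("Hs_X", "ACDEF")
        (masked,) = mask_domains([seq], [])
        assert masked.sequence == "ACDEF"

    def test_overlapping_envelopes_mask_union(self):
        seq = MaskedSequence.from_plain("Hs_X", "A" * 100)
        hits = [
            DomainHit("Hs_X", "PDZ", 10, 50, 10, 50, 1e-8),
            DomainHit("Hs_X", "SH3", 40, 70, 40, 70, 1e-8),
        ]
        (masked,) = mask_domains([seq], hits)
        union = set(range(10, 51)) | set(range(40, 71))  # 1-based
        assert masked.n_masked == len(union)

    def test_out_of_range_rejected(self):
        seq = MaskedSequence.from_plain("Hs_X", "A" * 20)
        with pytest.raises(ValueError, match="out of range"):
            mask_domains([seq], [DomainHit("Hs_X", "PDZ", 5, 30, 5, 30, 1e-8)])

    def test_insignificant_hits_ignored(self):
        seq = MaskedSequence.from_plain("Hs_X", "A" * 100)
        (masked,) = mask_domains(
            [seq], [DomainHit("Hs_X", "PDZ", 10, 60, 10, 60, 0.2)]
        )
        assert masked.n_masked == 0


class TestLowComplexityMasking:
    def test_homopolymer_masked(self):
        rng = np.random.default_rng(0)
        flank = "".join(rng.choice(list(AA), 40))
        seq = MaskedSequence.from_plain("Sy_A", flank + "A" * 15 + flank)
        (masked,) = mask_low_complexity([seq])
        assert "X" * 10 in masked.sequence
        assert masked.provenance[45] == "low_complexity"

    def test_random_sequence_unchanged(self):
        seqs = rand_seqs(1, n=3, length=200)
        masked = mask_low_complexity(seqs)
        assert all(m.n_masked == 0 for m in masked)

    def test_all_x_input_unchanged(self):
        seq = MaskedSequence("Sy_A", "X" * 30, ["low_complexity"] * 30)
        (masked,) = mask_low_complexity([seq])
        assert masked.sequence == "X" * 30


class TestBuiltinFinder:
    def test_identical_word_in_all_sequences(self):
        word = "WKDHQACEFRLM"
        rng = np.random.default_rng(2)
        seqs = []
        for i in range(8):
            flank = "".join(rng.choice(list(AA), 50))
            flank2 = "".join(rng.choice(list(AA), 50))
            seqs.append(
                MaskedSequence.from_plain(f"Sy_I{i}", flank + word + flank2)
            )
        result = builtin_finder(seqs, width_range=(6, 14), seed=0)
        assert result is not None and result.evalue < 1e-10
        # every sequence's occurrence covers the planted word
        for occ in result.occurrences:
            assert occ.start <= 51 + 6 and occ.end >= 51

    def test_noisy_planted_motif_recovered(self):
        seqs, truth = plant_motif_dataset(
            seed=5, n_seqs=16, n_sites=8, width=12, subs_per_site=1
        )
        result = builtin_finder(seqs, width_range=(8, 16), seed=0)
        assert result is not None and result.evalue < 0.01
        starts = {o.protein_id: (o.start, o.end) for o in result.occurrences}
        hits = sum(
            1
            for pid, pos in truth
            if pid in starts
            and starts[pid][0] <= pos + 6
            and starts[pid][1] >= pos + 5
        )
        assert hits >= 7

    def test_random_background_rejected(self):
        seqs = rand_seqs(9, n=15, length=150)
        result = builtin_finder(seqs, width_range=(6, 18), seed=0)
        assert result is None or result.evalue > 0.01

    def test_all_masked_gives_sentinel(self):
        seqs = [
            MaskedSequence("Sy_A", "X" * 60, ["low_complexity"] * 60)
            for _ in range(5)
        ]
        assert builtin_finder(seqs, width_range=(6, 10), seed=0) is None


class TestIterativeDiscovery:
    def test_planted_motif_then_termination(self):
        seqs, truth = plant_motif_dataset(
            seed=21, n_seqs=18, n_sites=6, width=12, subs_per_site=0
        )
        motifs, masked = iterative_discovery(seqs, seed=0)
        assert len(motifs) >= 1
        occ = {o.protein_id for o in motifs[0].occurrences}
        assert sum(1 for pid, _ in truth if pid in occ) >= 5
        # accepted occurrences were masked
        first = motifs[0].occurrences[0]
        by_id = {s.protein_id: s for s in masked}
        region = by_id[first.protein_id].sequence[first.start - 1 : first.end]
        assert set(region) == {"X"}

    def test_iid_background_type_i_control(self):
        false_accepts = 0
        for seed in range(8):
            seqs = rand_seqs(300 + seed, n=12, length=100)
            motifs, _ = iterative_discovery(seqs, seed=0, max_iterations=2)
            if motifs:
                false_accepts += 1
        assert false_accepts <= 1

    def test_second_motif_found_after_first_masked(self):
        strong = "WKDHQACEFRLMPY"
        weak = "MQRLEHWDKGAC"
        rng = np.random.default_rng(33)
        seqs = []
        for i in range(10):
            f1 = "".join(rng.choice(list(AA), 30))
            f2 = "".join(rng.choice(list(AA), 30))
            f3 = "".join(rng.choice(list(AA), 30))
            seqs.append(
                MaskedSequence.from_plain(
                    f"Sy_T{i}", f1 + strong + f2 + weak + f3
                )
            )
        motifs, _ = iterative_discovery(
            seqs, seed=0, max_iterations=4, min_sites=4
        )
        assert len(motifs) >= 2
        starts = sorted(
            {o.start for m in motifs[:2] for o in m.occurrences}
        )
        # occurrences of the two motifs cover both planted regions
        assert any(s <= 31 + 7 and s + 10 >= 31 for s in starts)
        assert any(s <= 75 + 7 and s + 10 >= 75 for s in starts)


class TestUnmaskedExtension:
    def test_hidden_occurrence_recovered_but_no_new_motifs(self):
        motif = MotifDefinition(
            name="motif_1",
            width=8,
            evalue=1e-6,
            regex="WKDHQACE",
            occurrences=[MotifOccurrence("Sy_A", "motif_1", 5, 12)],
        )
        unmasked = [
            MaskedSequence.from_plain("Sy_A", "MMMM" + "WKDHQACE" + "M" * 10),
            MaskedSequence.from_plain(
                "Sy_B", "M" * 6 + "WKDHQACE" + "M" * 8
            ),  # was hidden under a domain mask
        ]
        (extended,) = unmasked_extension_pass(unmasked, [motif])
        assert extended.extended_by_unmasked_pass
        assert {(o.protein_id, o.start) for o in extended.occurrences} == {
            ("Sy_A", 5),
            ("Sy_B", 7),
        }

    def test_no_additional_matches_identity(self):
        motif = MotifDefinition(
            name="motif_1", width=8, evalue=1e-6, regex="WKDHQACE",
            occurrences=[MotifOccurrence("Sy_A", "motif_1", 5, 12)],
        )
        unmasked = [
            MaskedSequence.from_plain("Sy_A", "MMMM" + "WKDHQACE" + "M" * 4)
        ]
        (extended,) = unmasked_extension_pass(unmasked, [motif])
        assert not extended.extended_by_unmasked_pass
        assert len(extended.occurrences) == 1


class TestRegexScan:
    def test_ld_consensus_matches(self):
        seqs = [MaskedSequence.from_plain("Hs_PXN1", "MXXLDRLLAALKXX")]
        occs = scan_regex(seqs, {"LD": "LDxLLxxL"})
        assert [(o.start, o.end) for o in occs] == [(4, 11)]
        assert occs[0].source == "regex"

    def test_short_candidate_no_match(self):
        seqs = [MaskedSequence.from_plain("Hs_P", "LDRLLAA")]
        assert scan_regex(seqs, {"LD": "LDxLLxxL"}) == []

    def test_leftmost_nonoverlapping_matches_brute_force(self):
        import re as _re

        seq = "AAAC" * 20
        pattern = "A[AC]A"
        seqs = [MaskedSequence.from_plain("Sy_O", seq)]
        occs = scan_regex(seqs, {"m": pattern})
        # brute force: scan all positions left to right, skipping overlaps
        py = _re.compile("A[AC]A")
        expected, pos = [], 0
        while pos <= len(seq) - 3:
            m = py.match(seq, pos)
            if m:
                expected.append((m.start() + 1, m.end()))
                pos = m.end()
            else:
                pos += 1
        assert [(o.start, o.end) for o in occs] == expected

    def test_malformed_pattern_rejected(self):
        with pytest.raises(ValueError, match="malformed|amino"):
            regex_to_pattern("LD?LL")
        with pytest.raises(ValueError):
            regex_to_pattern("L[Z]L")

    def test_masked_positions_never_match(self):
        seqs = [MaskedSequence.from_plain("Sy_X", "LDXLLAAL")]
        assert scan_regex(seqs, {"LD": "LDxLLxxL"}) == []


class TestMaskingInvariants:
    def test_masking_preserves_length_and_counts(self):
        seqs, _ = plant_motif_dataset(seed=77, n_seqs=6, n_sites=4)
        hits = [DomainHit("SY_M0", "PDZ", 5, 40, 5, 40, 1e-6)]
        masked = mask_domains(mask_low_complexity(seqs), hits)
        for before, after in zip(seqs, masked):
            assert len(after.sequence) == len(before.sequence)
            assert after.n_masked == sum(
                1 for p in after.provenance if p != "none"
            )
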
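"""Hit filtering, overlap resolution and LIM-instance assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from limclass.annotation import (
    DomainHit,
    ProteinRecord,
    assemble_lim_instances,
    filter_hits,
    live_scan,
    read_domtblout,
    resolve_overlaps,
    select_representative_isoforms,
    write_domtblout,
)


def hit(pid="Hs_X", model="LIM", env=(10, 60), ie=1e-10, ali=None, match=""):
    ali = ali or env
    return DomainHit(
        protein_id=pid,
        model=model,
        env_start=env[0],
        env_end=env[1],
        ali_start=ali[0],
        ali_end=ali[1],
        independent_evalue=ie,
        aligned_match_string=match,
    )


def record(pid="Hs_X", n=300):
    return ProteinRecord(id=pid, species=pid[:2], sequence="A" * n)


class TestIsoformSelection:
    def test_longest_kept(self):
        recs = [
            ProteinRecord("Hs_G-1", "Hs", "A" * 300),
            ProteinRecord("Hs_G-2", "Hs", "A" * 250),
        ]
        kept, report = select_representative_isoforms(recs, policy="longest")
        assert [r.id for r in kept] == ["Hs_G-1"]
        assert report.discarded == [("Hs_G-2", "nonrepresentative_isoform")]

    def test_single_isoform_unchanged(self):
        recs = [ProteinRecord("Hs_SOLO", "Hs", "MKV")]
        kept, report = select_representative_isoforms(recs)
        assert kept == recs and len(report) == 0

    def test_equal_length_tie_is_order_independent(self):
        recs = [
            ProteinRecord(f"Hs_G-{i}", "Hs", "A" * 200) for i in (3, 1, 2)
        ]
        winners = set()
        for perm in itertools.permutations(recs):
            kept, _ = select_representative_isoforms(list(perm))
            winners.add(kept[0].id)
        assert winners == {"Hs_G-1"}

    def test_empty_input(self):
        kept, report = select_representative_isoforms([])
        assert kept == [] and len(report) == 0


class TestEvalueFilter:
    @pytest.mark.parametrize(
        "ie,kept", [(0.06, False), (0.05, True), (1e-30, True)]
    )
    def test_threshold_boundary(self, ie, kept):
        retained, report = filter_hits([hit(ie=ie)])
        assert (len(retained) == 1) is kept
        assert len(retained) + len(report) == 1

    def test_empty(self):
        retained, report = filter_hits([])
        assert retained == [] and len(report) == 0

    def test_negative_evalue_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            filter_hits([hit(ie=-1.0)])


def brute_force_overlap_resolution(hits):
    """Independent oracle: repeatedly take the global minimum-iE hit
    (ties: env_start, model) and delete everything overlapping it."""
    remaining = list(hits)
    chosen = []
    while remaining:
        best = min(
            remaining,
            key=lambda h: (h.independent_evalue, h.env_start, h.model),
        )
        chosen.append(best)
        remaining = [
            h for h in remaining if h is not best and not h.overlaps(best)
        ]
        remaining = [h for h in remaining if not h.overlaps(best)]
    return sorted(chosen, key=lambda h: h.env_start)


class TestOverlapResolution:
    def test_lowest_evalue_wins(self):
        a, b = hit(env=(10, 60), ie=1e-10), hit(env=(40, 90), ie=1e-3)
        retained, report = resolve_overlaps([a, b])
        assert retained == [a] and len(report) == 1

    def test_disjoint_hits_both_kept(self):
        a, b = hit(env=(10, 60)), hit(env=(100, 160))
        retained, report = resolve_overlaps([a, b])
        assert retained == [a, b] and len(report) == 0

    def test_chain_middle_best_keeps_middle_only(self):
        a = hit(env=(10, 50), ie=1e-5)
        b = hit(env=(40, 90), ie=1e-9)
        c = hit(env=(80, 130), ie=1e-4)
        retained, _ = resolve_overlaps([a, b, c])
        assert retained == [b]

    def test_chain_middle_worst_keeps_flanks(self):
        a = hit(env=(10, 50), ie=1e-9)
        b = hit(env=(40, 90), ie=1e-2)
        c = hit(env=(80, 130), ie=1e-8)
        retained, _ = resolve_overlaps([a, b, c])
        assert retained == [a, c]

    def test_matches_oracle_and_order_independent(self):
        rng = np.random.default_rng(7)
        for _ in range(150):
            n = int(rng.integers(1, 9))
            hits = []
            for i in range(n):
                start = int(rng.integers(1, 300))
                hits.append(
                    hit(
                        env=(start, start + int(rng.integers(10, 80))),
                        ie=float(10.0 ** -rng.uniform(1, 12)),
                        model=f"M{rng.integers(3)}",
                    )
                )
            expected = brute_force_overlap_resolution(hits)
            for perm_seed in range(3):
                order = rng.permutation(n)
                retained, report = resolve_overlaps([hits[i] for i in order])
                assert retained == expected
                assert len(retained) + len(report) == n  # conservation


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(min_value=1, max_value=150),
            st.integers(min_value=5, max_value=70),
            st.floats(min_value=1e-12, max_value=0.04, allow_nan=False),
        ),
        min_size=1,
        max_size=7,
    )
)
def test_overlap_resolution_conserves_hits_and_matches_oracle(spans):
    """Property: every hit is retained or discarded exactly once, and the
    greedy resolution equals the iterate-global-minimum oracle."""
    hits = [
        hit(env=(start, start + width), ie=ie)
        for start, width, ie in spans
    ]
    retained, report = resolve_overlaps(hits)
    assert len(retained) + len(report) == len(hits)
    assert retained == brute_force_overlap_resolution(hits)
    for a, b in itertools.combinations(retained, 2):
        assert not a.overlaps(b)


class TestLimInstances:
    def test_insert_columns_removed(self):
        h = hit(env=(10, 18), match="CkRCgq--C")
        instances, _ = assemble_lim_instances(record(), [h])
        assert instances[0].aligned_match_string == "CRC--C"

    def test_ordinals_follow_coordinates(self):
        hits = [hit(env=(100, 160)), hit(env=(10, 65))]
        instances, _ = assemble_lim_instances(record(), hits)
        assert [(i.ordinal, i.env_start) for i in instances] == [
            ("A", 10),
            ("B", 100),
        ]
        assert instances[0].label == "Hs_X.A"

    def test_highly_truncated_flagged(self):
        h = hit(env=(10, 15), match="C-----")
        instances, report = assemble_lim_instances(record(), [h])
        assert instances == []
        assert report.discarded[0][1] == "truncated"

    def test_mixed_widths_rejected(self):
        hits = [
            hit(env=(10, 20), match="CRCHCC"),
            hit(env=(100, 120), match="CRCHCCAA"),
        ]
        with pytest.raises(ValueError, match="widths"):
            assemble_lim_instances(record(), hits)

    def test_zinc_finger_misprediction_flagged(self):
        # full-width string with nearly no C/H/D/E at coordinating columns
        bad = list("A" * 55)
        bad[0] = "C"  # 1 of 8 positions occupied
        h = hit(env=(10, 64), match="".join(bad))
        instances, report = assemble_lim_instances(record(), [h])
        assert instances == []
        assert report.discarded[0][1] == "zinc_finger_mispredict"

    def test_conserved_lim_accepted(self):
        good = list("A" * 55)
        for pos, res in zip((1, 4, 24, 27, 30, 33, 50, 53), "CCHCCCCD"):
            good[pos - 1] = res
        h = hit(env=(10, 64), match="".join(good))
        instances, report = assemble_lim_instances(record(), [h])
        assert len(instances) == 1 and len(report) == 0


class TestTables:
    def test_domtblout_round_trip(self, tmp_path):
        hits = [
            hit(pid="Hs_A", env=(5, 60), ali=(7, 58), ie=1.5e-20),
            hit(pid="Nv_B", model="PDZ", env=(10, 95), ie=0.003),
        ]
        path = tmp_path / "hits.domtblout"
        write_domtblout(hits, str(path))
        back = read_domtblout(str(path))
        assert {(h.protein_id, h.model, h.env_start, h.env_end) for h in back} == {
            ("Hs_A", "LIM", 5, 60),
            ("Nv_B", "PDZ", 10, 95),
        }
        by_id = {h.protein_id: h for h in back}
        assert by_id["Hs_A"].independent_evalue == pytest.approx(1.5e-20, rel=0.1)
        assert by_id["Hs_A"].ali_start == 7

    def test_live_scan_passthrough(self, tmp_path):
        hits = [hit(pid="Hs_A", env=(5, 60))]
        table = tmp_path / "t.domtblout"
        write_domtblout(hits, str(table))
        got = live_scan("unused.fa", backend="none", table_path=str(table))
        assert len(got) == 1 and got[0].protein_id == "Hs_A"

    def test_live_scan_requires_table_or_hmm(self):
        with pytest.raises(ValueError, match="table"):
            live_scan("x.fa", backend="none")
        with pytest.raises(ValueError, match="HMM"):
            live_scan("x.fa", backend="external")


@pytest.fixture(scope="module")
def toy_hmm(tmp_path_factory):
    pyhmmer = pytest.importorskip("pyhmmer")
    alphabet = pyhmmer.easel.Alphabet.amino()
    core = "CKHCGKELTQGAKFYEHDGRPFCEHCYQKLFG"
    variants = []
    for i, sub in enumerate(["A", "S", "T", "V"]):
        s = core[:5] + sub + core[6:]
        variants.append(
            pyhmmer.easel.TextSequence(name=f"s{i}".encode(), sequence=s)
        )
    msa = pyhmmer.easel.TextMSA(name=b"TOY", sequences=variants)
    builder = pyhmmer.plan7.Builder(alphabet)
    background = pyhmmer.plan7.Background(alphabet)
    hmm, _, _ = builder.build_msa(msa.digitize(alphabet), background)
    path = tmp_path_factory.mktemp("hmm") / "toy.hmm"
    with open(path, "wb") as out:
        hmm.write(out)
    return str(path), core


class TestLiveScanHMM:
    """In-process profile search against a toy HMM built at test time."""

    def test_planted_match_recovered(self, toy_hmm, tmp_path):
        hmm_path, core = toy_hmm
        rng = np.random.default_rng(3)
        flank = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
        seq = flank + core + flank
        fasta = tmp_path / "p.fa"
        fasta.write_text(f">Sy_P1\n{seq}\n>Sy_XX\n{'X' * 120}\n")
        hits = live_scan(str(fasta), hmm_path=hmm_path, backend="external")
        assert {h.protein_id for h in hits} == {"Sy_P1"}
        h = hits[0]
        planted = (61, 60 + len(core))
        assert h.env_start <= planted[0] + 5 and h.env_end >= planted[1] - 5
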
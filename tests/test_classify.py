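"""Class-signature evaluation: criteria, families, spacing, misannotation."""

import pytest

from limclass.annotation import DomainHit, LimDomainInstance
from limclass.classify import (
    ProteinAnnotation,
    UNCLASSIFIED,
    check_spacing,
    classify_all,
    classify_protein,
    detect_misannotations,
)
from limclass.motifs import MotifOccurrence
from limclass.signatures import SignatureConfigError, load_registry


def lim(pid, ordinal, start, width=55, group=None, match=None):
    return LimDomainInstance(
        protein_id=pid,
        ordinal=ordinal,
        env_start=start,
        env_end=start + width - 1,
        ali_start=start,
        ali_end=start + width - 1,
        independent_evalue=1e-12,
        aligned_match_string=match or ("C" * width),
        homology_group=group,
    )


def dom(pid, model, start, end):
    return DomainHit(pid, model, start, end, start, end, 1e-8)


def motif(pid, name, start, width):
    return MotifOccurrence(pid, name, start, start + width - 1, source="regex")


def annotate(pid, species, lims=(), domains=(), motifs=(), length=900):
    return ProteinAnnotation(
        protein_id=pid,
        species=species,
        length=length,
        lims=list(lims),
        domains=list(domains),
        motifs=list(motifs),
    )


@pytest.fixture(scope="module")
def reg():
    return load_registry()


def four_lims(pid, groups=(None,) * 4, start=10, gap=20, width=55):
    out = []
    pos = start
    for i, g in enumerate(groups):
        out.append(lim(pid, chr(ord("A") + i), pos, width=width, group=g))
        pos += width + gap
    return out


class TestCanonicalArchitectures:
    def test_ablim_four_lims_plus_vhp(self, reg):
        pid = "Nv_AB1"
        ann = annotate(
            pid,
            "Nv",
            lims=four_lims(pid),
            domains=[dom(pid, "VHP", 400, 434)],
        )
        res = classify_protein(ann, reg, waive_group_criteria=True)
        assert (res.class_name, res.family) == ("ABLIM", "Ablim")
        assert {"count", "architecture"} <= res.criteria_satisfied

    def test_lhx_two_lims_plus_homeodomain(self, reg):
        pid = "Dm_LH1"
        ann = annotate(
            pid,
            "Dm",
            lims=four_lims(pid)[:2],
            domains=[dom(pid, "Homeobox", 300, 356)],
        )
        res = classify_protein(ann, reg, waive_group_criteria=True)
        assert (res.class_name, res.family) == ("LHX", "Lhx")

    def test_lmo_two_lims_without_homeodomain(self, reg):
        pid = "Nv_LM1"
        ann = annotate(pid, "Nv", lims=four_lims(pid)[:2])
        res = classify_protein(ann, reg, waive_group_criteria=True)
        assert (res.class_name, res.family) == ("LMO", "Lmo")

    def test_pxn_requires_ld_motif(self, reg):
        pid = "Ta_PX1"
        ann = annotate(
            pid,
            "Ta",
            lims=four_lims(pid, start=100),
            motifs=[motif(pid, "LD", 10, 8)],
        )
        res = classify_protein(ann, reg, waive_group_criteria=True)
        assert (res.class_name, res.family) == ("PXN", "Pxn")

    def test_unknown_architecture_unclassified(self, reg):
        # LIM + Ras-association domain: no signature covers it
        pid = "Dm_RA1"
        ann = annotate(
            pid,
            "Dm",
            lims=[lim(pid, "A", 10)],
            domains=[dom(pid, "RA", 200, 289), dom(pid, "Pkinase", 400, 519)],
        )
        res = classify_protein(ann, reg, waive_group_criteria=True)
        assert res.class_name == UNCLASSIFIED

    def test_empty_annotations_unclassified(self, reg):
        res = classify_protein(annotate("Sr_E1", "Sr"), reg,
                               waive_group_criteria=True)
        assert res.class_name == UNCLASSIFIED


class TestFamilyAssignment:
    @pytest.mark.parametrize(
        "n_lims,family", [(1, "Alp"), (3, "Enigma"), (4, "Tungus")]
    )
    def test_enigma_families_by_lim_count(self, reg, n_lims, family):
        pid = "Hs_EN1"
        ann = annotate(
            pid,
            "Hs",
            lims=four_lims(pid, start=200)[:n_lims],
            domains=[dom(pid, "PDZ", 10, 94)],
        )
        res = classify_protein(ann, reg, waive_group_criteria=True)
        assert (res.class_name, res.family) == ("ENIGMA", family)

    def test_etes_pet_plus_six_lims(self, reg):
        pid = "Aq_TE1"
        lims = [
            lim(pid, chr(ord("A") + i), 200 + i * 70) for i in range(6)
        ]
        ann = annotate(
            pid, "Aq", lims=lims, domains=[dom(pid, "PET", 20, 109)]
        )
        res = classify_protein(ann, reg, waive_group_criteria=True)
        assert (res.class_name, res.family) == ("TES", "Etes")

    def test_fhl_half_lim_no_pet(self, reg):
        pid = "Hs_FH1"
        ann = annotate(
            pid,
            "Hs",
            lims=four_lims(pid, start=60),
            domains=[dom(pid, "HalfLIM", 10, 34)],
        )
        res = classify_protein(ann, reg, waive_group_criteria=True)
        assert (res.class_name, res.family) == ("TES", "Fhl")

    def test_mical_vs_mical_like_by_fad_region(self, reg):
        base = dict(species="Nv", length=1200)
        pid = "Nv_MI1"
        shared = dict(
            lims=[lim(pid, "A", 500)],
            domains=[
                dom(pid, "CH", 300, 399),
                dom(pid, "DUF3585", 700, 779),
            ],
        )
        without_fad = annotate(pid, **base, **shared)
        res = classify_protein(without_fad, reg, waive_group_criteria=True)
        assert (res.class_name, res.family) == ("MICAL", "Mical-like")
        with_fad = annotate(
            pid,
            **base,
            lims=shared["lims"],
            domains=shared["domains"] + [dom(pid, "FAD_region", 50, 199)],
        )
        res = classify_protein(with_fad, reg, waive_group_criteria=True)
        assert (res.class_name, res.family) == ("MICAL", "Mical")


class TestSpacing:
    def lasp_features(self, pid, lim_start=5, neb1=67, neb2=102):
        lims = [lim(pid, "A", lim_start)]
        domains = [
            dom(pid, "Nebulin", neb1, neb1 + 29),
            dom(pid, "Nebulin", neb2, neb2 + 29),
            dom(pid, "SH3", 160, 214),
        ]
        return annotate(pid, "Ml", lims=lims, domains=domains)

    def test_canonical_lasp_spacing_passes(self, reg):
        ann = self.lasp_features("Ml_LA1")
        res = classify_protein(ann, reg, waive_group_criteria=True)
        assert (res.class_name, res.family) == ("LASP", "Lasp")
        checks = check_spacing(
            ann.features(), reg.family("LASP", "Lasp")
        )
        assert all(ok for _, ok, _ in checks)

    @pytest.mark.parametrize("lim_start", [5, 6])
    def test_lim_start_five_or_six(self, reg, lim_start):
        ann = self.lasp_features("Ml_LA1", lim_start=lim_start)
        checks = check_spacing(ann.features(), reg.family("LASP", "Lasp"))
        start_check = [c for c in checks if c[0].measure == "start"][0]
        assert start_check[1] is True

    def test_displaced_second_nebulin_fails(self, reg):
        ann = self.lasp_features("Ml_LA1", neb2=110)
        checks = check_spacing(ann.features(), reg.family("LASP", "Lasp"))
        neb2_check = checks[2]
        assert neb2_check[1] is False and neb2_check[2] == 110
        res = classify_protein(ann, reg, waive_group_criteria=True)
        assert res.class_name != "LASP"

    def test_zyx_requires_closely_spaced_lims(self, reg):
        pid = "Aq_ZY1"
        close = annotate(
            pid, "Aq",
            lims=[lim(pid, c, 100 + i * 62) for i, c in enumerate("ABC")],
        )
        res = classify_protein(close, reg, waive_group_criteria=True)
        assert res.class_name == "ZYX"
        spread = annotate(
            pid, "Aq",
            lims=[lim(pid, c, 100 + i * 150) for i, c in enumerate("ABC")],
        )
        res = classify_protein(spread, reg, waive_group_criteria=True)
        assert res.class_name != "ZYX"


class TestGroupCriteria:
    def test_groups_distinguish_ablim_from_lookalike(self, reg):
        expected = {"ABLIM": {"Ablim": (1, 2, 3, 4)}}
        pid = "Nv_AB1"
        good = annotate(
            pid, "Nv",
            lims=four_lims(pid, groups=(1, 2, 3, 4)),
            domains=[dom(pid, "VHP", 400, 434)],
        )
        res = classify_protein(good, reg, expected_groups=expected)
        assert res.class_name == "ABLIM"
        assert {"count", "groups", "order", "architecture"} <= (
            res.criteria_satisfied
        )
        bad = annotate(
            pid, "Nv",
            lims=four_lims(pid, groups=(9, 9, 9, 9)),
            domains=[dom(pid, "VHP", 400, 434)],
        )
        res = classify_protein(bad, reg, expected_groups=expected)
        assert res.class_name != "ABLIM"

    def test_partial_architecture_flag_when_optional_missing(self, reg):
        # the degraded-architecture case: four right-group LIMs, no VHP
        expected = {"ABLIM": {"Ablim": (1, 2, 3, 4)}}
        pid = "Ta_AB1"
        ann = annotate(pid, "Ta", lims=four_lims(pid, groups=(1, 2, 3, 4)))
        res = classify_protein(ann, reg, expected_groups=expected)
        assert res.class_name == "ABLIM"
        assert "partial_architecture" in res.flags


class TestMisannotation:
    def make(self, pid, species, strings):
        lims = [
            lim(pid, chr(ord("A") + i), 10 + i * 80, match=s)
            for i, s in enumerate(strings)
        ]
        return annotate(pid, species, lims=lims)

    def base_results(self, annotations, reg):
        return classify_all(annotations, reg)

    def test_within_species_subset_flagged(self, reg):
        a = self.make("Nv_C1", "Nv", ["CCHHA" * 11])
        b = self.make("Nv_C2", "Nv", ["CCHHA" * 11, "DDHHC" * 11])
        results = detect_misannotations(
            [  # minimal results
                classify_protein(x, reg, waive_group_criteria=True)
                for x in (a, b)
            ],
            [a, b],
        )
        flags = {r.protein_id: r.flags for r in results}
        assert "suspected_misannotation" in flags["Nv_C1"]
        assert "suspected_misannotation" not in flags["Nv_C2"]

    def test_cross_species_identical_not_flagged(self, reg):
        a = self.make("Nv_C1", "Nv", ["CCHHA" * 11])
        b = self.make("Aq_C2", "Aq", ["CCHHA" * 11, "DDHHC" * 11])
        results = detect_misannotations(
            [
                classify_protein(x, reg, waive_group_criteria=True)
                for x in (a, b)
            ],
            [a, b],
        )
        assert all("suspected_misannotation" not in r.flags for r in results)

    def test_unique_content_not_flagged(self, reg):
        a = self.make("Nv_C1", "Nv", ["AAHHA" * 11])
        b = self.make("Nv_C2", "Nv", ["CCHHA" * 11, "DDHHC" * 11])
        results = detect_misannotations(
            [
                classify_protein(x, reg, waive_group_criteria=True)
                for x in (a, b)
            ],
            [a, b],
        )
        assert all("suspected_misannotation" not in r.flags for r in results)


class TestClassifyAll:
    def test_order_independent_and_partitioning(self, reg):
        pids = ["Hs_L1", "Hs_L2", "Nv_L1"]
        anns = []
        for pid in pids:
            sp = pid[:2]
            anns.append(
                annotate(
                    pid, sp,
                    lims=four_lims(pid)[:2],
                    domains=[dom(pid, "Homeobox", 300, 356)],
                )
            )
        fwd = classify_all(anns, reg)
        rev = classify_all(list(reversed(anns)), reg)
        assert [(r.protein_id, r.class_name) for r in fwd] == [
            (r.protein_id, r.class_name) for r in rev
        ]
        assert len(fwd) == len(anns)

    def test_unknown_motif_in_signature_rejected(self, tmp_path):
        bad = tmp_path / "sig.yaml"
        bad.write_text(
            "domains: {PDZ: 85}\n"
            "classes:\n"
            "  FOO:\n"
            "    required_criteria: [count]\n"
            "    families:\n"
            "      Foo:\n"
            "        lim_count: 1\n"
            "        template:\n"
            "          - lim\n"
            "          - {motif: NOPE}\n"
        )
        with pytest.raises(SignatureConfigError, match="NOPE"):
            load_registry(str(bad))
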
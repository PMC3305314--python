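"""The classification engine: apply the four criteria to each protein.

A protein enters a class when it satisfies the class's required subset of
the four criteria against one of the class's family signatures:

1. *count* — same number of LIM domains as the family's human members;
2. *groups* — same complement of LIM homology groups as the human members;
3. *order* — the conserved N-to-C order of those homology groups;
4. *architecture* — the family's non-LIM domains, motifs and their
   arrangement (an ordered-subsequence match of the template, plus any
   forbidden-element and spacing constraints).

The homology-group complement of a class is anchored on its human members:
:func:`classify_all` first classifies human proteins on architecture alone,
derives each family's modal group sequence from them, and then evaluates
every protein against the full criteria. Proteins matching no class — or
several classes equally well — are reported UNCLASSIFIED with the evidence
retained.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation import DomainHit, LimDomainInstance
from .motifs import MotifOccurrence
from .signatures import (
    ClassSignature,
    FamilySignature,
    SignatureRegistry,
    SpacingConstraint,
    TemplateElement,
)

__all__ = [
    "Feature",
    "ProteinAnnotation",
    "ClassificationResult",
    "evaluate_criteria",
    "assign_family",
    "check_spacing",
    "detect_misannotations",
    "classify_all",
    "derive_group_complements",
    "write_classification_tsv",
]

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class Feature:
    """One architectural feature on a protein, in residue coordinates."""

    kind: str  # lim | domain | motif
    name: str
    start: int
    end: int

    def matches(self, elem: TemplateElement) -> bool:
        return self.kind == elem.kind and (
            elem.kind == "lim" or self.name == elem.name
        )


@dataclass
class ProteinAnnotation:
    """Everything the classifier needs to know about one protein."""

    protein_id: str
    species: str
    length: int
    lims: list[LimDomainInstance] = field(default_factory=list)
    domains: list[DomainHit] = field(default_factory=list)  # non-LIM hits
    motifs: list[MotifOccurrence] = field(default_factory=list)

    def features(self) -> list[Feature]:
        feats = [
            Feature("lim", "LIM", lim.env_start, lim.env_end)
            for lim in self.lims
        ]
        feats += [
            Feature("domain", d.model, d.env_start, d.env_end)
            for d in self.domains
        ]
        feats += [
            Feature("motif", m.motif, m.start, m.end) for m in self.motifs
        ]
        feats.sort(key=lambda f: (f.start, f.end, f.kind, f.name))
        return feats

    def group_sequence(self) -> tuple[int | None, ...]:
        """Homology groups of the LIM domains in N-to-C order."""
        return tuple(
            lim.homology_group
            for lim in sorted(self.lims, key=lambda l: l.env_start)
        )


@dataclass
class ClassificationResult:
    protein_id: str
    species: str
    class_name: str = UNCLASSIFIED
    family: str | None = None
    criteria_satisfied: frozenset[str] = frozenset()
    evidence: dict = field(default_factory=dict)
    flags: frozenset[str] = frozenset()

    @property
    def classified(self) -> bool:
        return self.class_name != UNCLASSIFIED


# ---------------------------------------------------------------------------
# template matching


def _greedy_match(
    features: Sequence[Feature], elements: Sequence[TemplateElement]
) -> list[int | None]:
    """Left-to-right earliest match of each element; None where unmatched.

    Elements are consumed in template order; an unmatched element does not
    block later ones (so the returned vector doubles as a matched-element
    count for ranking partial architectures).
    """
    out: list[int | None] = []
    pointer = 0
    for elem in elements:
        found = None
        for i in range(pointer, len(features)):
            if features[i].matches(elem):
                found = i
                break
        if found is None:
            out.append(None)
        else:
            out.append(found)
            pointer = found + 1
    return out


def match_template(
    features: Sequence[Feature], family: FamilySignature
) -> tuple[bool, list[int | None], list[TemplateElement]]:
    """Match the family template against a protein's ordered features.

    Returns (required elements all matched in order, per-element feature
    indices, unmatched optional elements). Required elements are matched
    first so that an optional element can never steal a feature a required
    one needs; optional elements are then slotted into the gaps.
    """
    required = [e for e in family.template if e.required]
    req_match = _greedy_match(features, required)
    req_ok = all(m is not None for m in req_match)

    # interleave: walk the full template, constraining optional elements to
    # the window before the next required element's match
    full: list[int | None] = []
    req_iter = iter(
        [m for m in req_match if m is not None]
        + [len(features)]  # sentinel window end
    )
    pointer = 0
    req_positions = [m for m in req_match]
    ri = 0
    for elem in family.template:
        if elem.required:
            pos = req_positions[ri]
            ri += 1
            if pos is None:
                full.append(None)
            else:
                full.append(pos)
                pointer = max(pointer, pos + 1)
        else:
            # window end: next matched required element's position
            window_end = len(features)
            for j in range(ri, len(req_positions)):
                if req_positions[j] is not None:
                    window_end = req_positions[j]
                    break
            found = None
            for i in range(pointer, window_end):
                if features[i].matches(elem):
                    found = i
                    break
            full.append(found)
            if found is not None:
                pointer = found + 1
    missing_optional = [
        e
        for e, m in zip(family.template, full)
        if m is None and not e.required
    ]
    return req_ok, full, missing_optional


def _resolve_ref(features: Sequence[Feature], ref: str) -> Feature | None:
    """Resolve 'lim:2' / 'domain:Nebulin:1' / 'motif:EM:1' to the k-th
    matching feature in N-to-C order (k defaults to 1)."""
    parts = ref.split(":")
    if parts[0] == "lim":
        kind, name = "lim", None
        k = int(parts[1]) if len(parts) > 1 else 1
    else:
        kind, name = parts[0], parts[1]
        k = int(parts[2]) if len(parts) > 2 else 1
    seen = 0
    for f in features:
        if f.kind == kind and (name is None or f.name == name):
            seen += 1
            if seen == k:
                return f
    return None


def check_spacing(
    features: Sequence[Feature], family: FamilySignature
) -> list[tuple[SpacingConstraint, bool | None, int | None]]:
    """Evaluate each spacing constraint.

    Returns (constraint, pass/fail/None, observed value); a constraint whose
    referenced elements are absent from the protein is not applicable and
    reports None.
    """
    results = []
    for sc in family.spacing:
        if sc.measure == "start":
            feat = _resolve_ref(features, sc.element)
            if feat is None:
                results.append((sc, None, None))
                continue
            observed = feat.start
        else:
            fa = _resolve_ref(features, sc.a)
            fb = _resolve_ref(features, sc.b)
            if fa is None or fb is None:
                results.append((sc, None, None))
                continue
            observed = fb.start - fa.end - 1
        results.append((sc, sc.min <= observed <= sc.max, observed))
    return results


# ---------------------------------------------------------------------------
# criteria evaluation


def evaluate_criteria(
    annotation: ProteinAnnotation,
    family: FamilySignature,
    expected_groups: Sequence[int] | None = None,
    waive_group_criteria: bool = False,
) -> tuple[frozenset[str], dict, int]:
    """Score the four criteria of one protein against one family signature.

    Returns (satisfied criteria, evidence, matched-template-element count).
    ``expected_groups`` is the family's reference group sequence (from its
    human members); when it is unknown and ``waive_group_criteria`` is set,
    the groups/order criteria are treated as satisfied-with-note so that
    group-anchored classes can still be evaluated on architecture alone.
    """
    features = annotation.features()
    satisfied: set[str] = set()
    evidence: dict = {}

    lo, hi = family.lim_count
    n_lims = len(annotation.lims)
    if lo <= n_lims <= hi:
        satisfied.add("count")
    evidence["count"] = {"observed": n_lims, "expected": [lo, hi]}

    groups = annotation.group_sequence()
    if expected_groups is not None:
        if Counter(g for g in groups if g is not None) == Counter(
            expected_groups
        ) and None not in groups:
            satisfied.add("groups")
        if tuple(groups) == tuple(expected_groups):
            satisfied.add("order")
        evidence["groups"] = {
            "observed": list(groups),
            "expected": list(expected_groups),
        }
    elif waive_group_criteria:
        satisfied.update({"groups", "order"})
        evidence["groups"] = {"observed": list(groups), "expected": "waived"}
    else:
        evidence["groups"] = {"observed": list(groups), "expected": None}

    req_ok, full_match, missing_optional = match_template(features, family)
    forbidden_hits = [
        f
        for f in features
        for elem in family.forbidden
        if f.matches(elem)
    ]
    spacing_results = check_spacing(features, family)
    spacing_ok = all(ok is not False for _, ok, _ in spacing_results)
    if req_ok and not forbidden_hits and spacing_ok:
        satisfied.add("architecture")
    matched_count = sum(1 for m in full_match if m is not None)
    matched_required = sum(
        1
        for e, m in zip(family.template, full_match)
        if e.required and m is not None
    )
    evidence["architecture"] = {
        "matched_required": matched_required,
        "template": [str(e) for e in family.template],
        "matched": [
            None
            if m is None
            else [features[m].name, features[m].start, features[m].end]
            for m in full_match
        ],
        "forbidden_present": sorted({f.name for f in forbidden_hits}),
        "spacing": [
            {"constraint": sc.describe(), "pass": ok, "observed": obs}
            for sc, ok, obs in spacing_results
        ],
        "missing_optional": [str(e) for e in missing_optional],
    }
    return frozenset(satisfied), evidence, (matched_count, matched_required)


def assign_family(
    annotation: ProteinAnnotation,
    class_sig: ClassSignature,
    expected_groups: Mapping[str, Sequence[int]] | None = None,
    waive_group_criteria: bool = False,
) -> ClassificationResult:
    """Evaluate one class: best family wins; ambiguity leaves family empty.

    The class is awarded when some family satisfies all the class's
    required criteria; among passing families the one matching the most
    template elements (then most criteria) is chosen, and an exact tie
    leaves the family unset with an ``ambiguous_family`` flag.
    """
    required = class_sig.required_criteria
    scored = []
    for fname, family in sorted(class_sig.families.items()):
        exp = None if expected_groups is None else expected_groups.get(fname)
        satisfied, evidence, matched = evaluate_criteria(
            annotation,
            family,
            expected_groups=exp,
            waive_group_criteria=waive_group_criteria,
        )
        passes = required <= satisfied
        scored.append((fname, family, satisfied, evidence, matched, passes))

    passing = [s for s in scored if s[5]]
    flags: set[str] = set()
    if not passing:
        best = max(scored, key=lambda s: (s[4], len(s[2]), s[0]))
        return ClassificationResult(
            protein_id=annotation.protein_id,
            species=annotation.species,
            class_name=UNCLASSIFIED,
            family=None,
            criteria_satisfied=best[2],
            evidence={class_sig.name: best[3]},
        )
    ranked = sorted(passing, key=lambda s: (*[-v for v in s[4]], -len(s[2]), s[0]))
    top = ranked[0]
    family_name: str | None = top[0]
    if len(ranked) > 1 and (ranked[1][4], len(ranked[1][2])) == (
        top[4],
        len(top[2]),
    ):
        family_name = None
        flags.add("ambiguous_family")
    if top[3]["architecture"]["missing_optional"] or "architecture" not in top[2]:
        flags.add("partial_architecture")
    return ClassificationResult(
        protein_id=annotation.protein_id,
        species=annotation.species,
        class_name=class_sig.name,
        family=family_name,
        criteria_satisfied=top[2],
        evidence={class_sig.name: top[3]},
        flags=frozenset(flags),
    )


def _rank_key(result: ClassificationResult) -> tuple:
    arch = next(iter(result.evidence.values()))["architecture"]
    matched = sum(1 for m in arch["matched"] if m is not None)
    return (matched, arch["matched_required"], len(result.criteria_satisfied))


def classify_protein(
    annotation: ProteinAnnotation,
    registry: SignatureRegistry,
    expected_groups: Mapping[str, Mapping[str, Sequence[int]]] | None = None,
    waive_group_criteria: bool = False,
) -> ClassificationResult:
    """Evaluate all classes; a unique best passer wins, ties unclassify."""
    candidates = []
    for cname in registry.class_names:
        res = assign_family(
            annotation,
            registry.classes[cname],
            expected_groups=None
            if expected_groups is None
            else expected_groups.get(cname, {}),
            waive_group_criteria=waive_group_criteria,
        )
        if res.classified:
            candidates.append(res)
    if not candidates:
        return ClassificationResult(
            protein_id=annotation.protein_id,
            species=annotation.species,
            evidence={"reason": "no class's required criteria satisfied"},
        )
    ranked = sorted(
        candidates,
        key=lambda r: tuple(-v for v in _rank_key(r)) + (r.class_name,),
    )
    top = ranked[0]
    if len(ranked) > 1 and _rank_key(ranked[1]) == _rank_key(top):
        return ClassificationResult(
            protein_id=annotation.protein_id,
            species=annotation.species,
            class_name=UNCLASSIFIED,
            evidence={
                "reason": "ambiguous",
                "tied_classes": sorted(
                    r.class_name
                    for r in ranked
                    if _rank_key(r) == _rank_key(top)
                ),
            },
        )
    return top


def derive_group_complements(
    annotations: Sequence[ProteinAnnotation],
    results: Sequence[ClassificationResult],
) -> dict[str, dict[str, tuple[int, ...]]]:
    """Modal homology-group sequence per (class, family), from the human
    proteins assigned to that family."""
    by_id = {a.protein_id: a for a in annotations}
    votes: dict[tuple[str, str], Counter] = {}
    for res in results:
        if not res.classified or res.family is None or res.species != "Hs":
            continue
        ann = by_id[res.protein_id]
        groups = ann.group_sequence()
        if None in groups:
            continue
        votes.setdefault((res.class_name, res.family), Counter())[groups] += 1
    out: dict[str, dict[str, tuple[int, ...]]] = {}
    for (cname, fname), counter in votes.items():
        # modal sequence; ties broken lexicographically for determinism
        best = max(counter.items(), key=lambda kv: (kv[1], [-g for g in kv[0]]))
        modal = min(
            (seq for seq, n in counter.items() if n == best[1]),
        )
        out.setdefault(cname, {})[fname] = modal
    return out


def classify_all(
    annotations: Sequence[ProteinAnnotation],
    registry: SignatureRegistry,
    expected_groups: Mapping[str, Mapping[str, Sequence[int]]] | None = None,
) -> list[ClassificationResult]:
    """Classify every protein; exactly one result per protein.

    When no reference group complements are supplied they are derived from
    the human proteins in a first architecture-anchored pass (human proteins
    themselves are always evaluated with the group criteria waived — they
    are the anchor that defines the complements). Misannotation flags are
    applied afterwards.
    """
    annotations = sorted(annotations, key=lambda a: a.protein_id)
    if expected_groups is None:
        human = [a for a in annotations if a.species == "Hs"]
        pass1 = [
            classify_protein(a, registry, waive_group_criteria=True)
            for a in human
        ]
        expected_groups = derive_group_complements(human, pass1)
    results = []
    for ann in annotations:
        results.append(
            classify_protein(
                ann,
                registry,
                expected_groups=expected_groups,
                waive_group_criteria=(ann.species == "Hs"),
            )
        )
    results = detect_misannotations(results, annotations)
    return results


def detect_misannotations(
    results: Sequence[ClassificationResult],
    annotations: Sequence[ProteinAnnotation],
) -> list[ClassificationResult]:
    """Flag proteins whose LIM content is a proper subset of a same-species
    protein's (identical aligned match strings) as suspected partial
    isoforms / misannotations. The rule is within-species only."""
    by_id = {a.protein_id: a for a in annotations}
    by_species: dict[str, list[ProteinAnnotation]] = {}
    for a in annotations:
        by_species.setdefault(a.species, []).append(a)
    flagged: set[str] = set()
    for species, group in by_species.items():
        contents = {
            a.protein_id: Counter(
                lim.aligned_match_string for lim in a.lims
            )
            for a in group
        }
        for a in group:
            ca = contents[a.protein_id]
            if not ca:
                continue
            for b in group:
                if b.protein_id == a.protein_id:
                    continue
                cb = contents[b.protein_id]
                if sum(ca.values()) < sum(cb.values()) and not ca - cb:
                    flagged.add(a.protein_id)
                    break
    out = []
    for res in results:
        if res.protein_id in flagged:
            out.append(
                ClassificationResult(
                    protein_id=res.protein_id,
                    species=res.species,
                    class_name=res.class_name,
                    family=res.family,
                    criteria_satisfied=res.criteria_satisfied,
                    evidence=res.evidence,
                    flags=res.flags | {"suspected_misannotation"},
                )
            )
        else:
            out.append(res)
    return out


def write_classification_tsv(
    results: Sequence[ClassificationResult], path: str
) -> None:
    with open(path, "w") as out:
        out.write("protein_id\tspecies\tclass\tfamily\tcriteria\tflags\n")
        for r in sorted(results, key=lambda r: r.protein_id):
            out.write(
                f"{r.protein_id}\t{r.species}\t{r.class_name}"
                f"\t{r.family or ''}"
                f"\t{','.join(sorted(r.criteria_satisfied))}"
                f"\t{','.join(sorted(r.flags))}\n"
            )
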
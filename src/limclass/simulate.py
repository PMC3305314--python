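"""Synthetic data with recorded ground truth.

Generates, under a single integer seed, everything the pipeline consumes:

* proteomes whose proteins realize the class-signature templates (LIM slots
  filled from per-homology-group consensus sequences with the eight
  zinc-coordinating positions fixed, non-LIM domains as labelled intervals,
  motifs as regex-expanded substrings at template-consistent offsets,
  including the rigid LASP spacing), with configurable architecture-dropout
  and decoy-hit noise;
* per-domain hit tables with realistic (log-uniform) independent E-values,
  plus overlapping decoy hits emulating zinc fingers mispredicted as LIM
  domains;
* gene trees in which LIM domains of the same homology group form clades,
  optionally perturbed by random NNI moves, and tree *pairs* whose strict
  consensus provably collapses the backbone while retaining every group
  clade (one random backbone, one star backbone, shared within-group
  topologies);
* presence matrices implied by planted single-gain origin/loss events.

Every generated entity is recorded in a :class:`GroundTruth` object so
recovery tests can compare pipeline output against the planted state. The
same seed gives bit-identical output; independent RNG streams are derived
per sub-generator so adding one stage never shifts another's draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .annotation import DEFAULT_ZINC_POSITIONS, DomainHit, ProteinRecord
from .motifs import AA, _REGEX_TOKEN
from .origins import SPECIES, PresenceMatrix
from .signatures import FamilySignature, SignatureRegistry, load_registry
from .trees import leaf_labels

__all__ = [
    "SyntheticConfig",
    "TrueProtein",
    "GroundTruth",
    "SyntheticProteome",
    "generate_proteome",
    "generate_gene_tree",
    "generate_tree_pair",
    "generate_presence_matrix",
    "sample_dollo_events",
    "matrix_from_events",
    "plant_motif_dataset",
]

#: canonical family generated for each class by default
CANONICAL_FAMILY = {
    "ABLIM": "Ablim",
    "CRP": "Crp",
    "ENIGMA": "Enigma",
    "EPLIN": "Eplin",
    "LASP": "Lasp",
    "LHX": "Lhx",
    "LMO": "Lmo",
    "LIMK": "Limk",
    "LMO7": "Lmo7",
    "MICAL": "Mical",
    "PXN": "Pxn",
    "PINCH": "Pinch",
    "TES": "Tes",
    "ZYX": "Zyx",
}

ZINC_PATTERN = {1: "C", 4: "C", 24: "H", 27: "C", 30: "C", 33: "C", 50: "C", 53: "D"}


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    ``per_class_counts`` maps a class name to either an int (proteins per
    species) or a species->count map; the default plants one protein per
    class per species and three human paralogs, so every homology group has
    three human members (mirroring the multi-paralog human complement real
    data shows, and giving the pruned human gene tree equal-depth group
    clades). Noise knobs: ``arch_dropout_p`` drops template elements,
    ``extra_domain_p`` adds overlapping decoy hits, ``tree_nni_moves``
    perturbs gene-tree topology.
    """

    seed: int = 0
    species: tuple[str, ...] = SPECIES
    per_class_counts: dict | None = None
    human_paralogs: int = 3
    arch_dropout_p: float = 0.0
    extra_domain_p: float = 0.0
    tree_nni_moves: int = 0
    lim_width: int = 55
    lim_mutation_rate: float = 0.08
    background: Sequence[float] | None = None
    classes: tuple[str, ...] | None = None  # default: all 14

    def __post_init__(self) -> None:
        for name, p in (
            ("arch_dropout_p", self.arch_dropout_p),
            ("extra_domain_p", self.extra_domain_p),
            ("lim_mutation_rate", self.lim_mutation_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.tree_nni_moves < 0:
            raise ValueError("tree_nni_moves must be >= 0")

    def rng(self, *stream: object) -> np.random.Generator:
        """Independent deterministic stream per sub-generator (stable
        across processes: derived from a digest, not the builtin hash)."""
        import hashlib

        digest = hashlib.sha256(repr(stream).encode()).digest()
        key = int.from_bytes(digest[:4], "big") % (2**31)
        return np.random.default_rng((self.seed, key))

    def counts_for(self, class_name: str) -> dict[str, int]:
        raw = (self.per_class_counts or {}).get(class_name)
        if raw is None:
            out = {sp: 1 for sp in self.species}
            if "Hs" in out:
                out["Hs"] = self.human_paralogs
            return out
        if isinstance(raw, int):
            return {sp: raw for sp in self.species}
        return {sp: int(raw.get(sp, 0)) for sp in self.species}


@dataclass
class TrueProtein:
    protein_id: str
    species: str
    class_name: str
    family: str
    features: list[tuple[str, str, int, int]]  # (kind, name, start, end)
    lim_groups: list[int]
    length: int

    @property
    def lim_count(self) -> int:
        return sum(1 for k, *_ in self.features if k == "lim")


@dataclass
class GroundTruth:
    proteins: dict[str, TrueProtein] = field(default_factory=dict)
    group_members: dict[int, set[str]] = field(default_factory=dict)
    group_meta: dict[int, tuple[str, str]] = field(default_factory=dict)

    def human_group_partition(self) -> set[frozenset[str]]:
        """The planted homology groups restricted to human LIM leaves."""
        out = set()
        for members in self.group_members.values():
            human = frozenset(m for m in members if m.startswith("Hs_"))
            if human:
                out.add(human)
        return out

    def group_of_leaf(self) -> dict[str, int]:
        return {
            leaf: gid
            for gid, members in self.group_members.items()
            for leaf in members
        }

    def to_json(self, path: str) -> None:
        payload = {
            "proteins": {
                pid: {
                    "species": p.species,
                    "class": p.class_name,
                    "family": p.family,
                    "features": p.features,
                    "lim_groups": p.lim_groups,
                    "length": p.length,
                }
                for pid, p in sorted(self.proteins.items())
            },
            "group_members": {
                str(g): sorted(m) for g, m in sorted(self.group_members.items())
            },
            "group_meta": {
                str(g): list(m) for g, m in sorted(self.group_meta.items())
            },
        }
        with open(path, "w") as out:
            json.dump(payload, out, indent=1, sort_keys=True)


@dataclass
class SyntheticProteome:
    records: list[ProteinRecord]
    hits: list[DomainHit]
    truth: GroundTruth
    registry: SignatureRegistry


# ---------------------------------------------------------------------------
# sequence-level helpers


def _random_sequence(rng: np.random.Generator, n: int, probs) -> str:
    return "".join(rng.choice(list(AA), size=n, p=probs))


def _regex_width(regex: str) -> int:
    return len(_REGEX_TOKEN.findall(regex))


def _expand_regex(regex: str, rng: np.random.Generator) -> str:
    out = []
    for tok in _REGEX_TOKEN.findall(regex):
        if tok == "x":
            out.append(AA[int(rng.integers(len(AA)))])
        elif tok.startswith("["):
            choices = tok.strip("[]")
            out.append(choices[int(rng.integers(len(choices)))])
        else:
            out.append(tok)
    return "".join(out)


def _group_consensus(
    gid: int, width: int, cfg: SyntheticConfig
) -> str:
    """Per-group LIM consensus: zinc-coordinating positions fixed to the
    canonical C/H/D pattern, all other positions group-specific."""
    rng = cfg.rng("consensus", gid)
    seq = list(_random_sequence(rng, width, None))
    for pos, res in ZINC_PATTERN.items():
        if pos <= width:
            seq[pos - 1] = res
    return "".join(seq)


def _mutate_lim(
    consensus: str, rng: np.random.Generator, rate: float
) -> str:
    zinc = {p - 1 for p in DEFAULT_ZINC_POSITIONS if p <= len(consensus)}
    out = list(consensus)
    for i in range(len(out)):
        if i in zinc:
            continue
        if rng.random() < rate:
            out[i] = AA[int(rng.integers(len(AA)))]
    return "".join(out)


# ---------------------------------------------------------------------------
# architecture layout


def _element_width(
    elem, cfg: SyntheticConfig, registry: SignatureRegistry
) -> int:
    if elem.kind == "lim":
        return cfg.lim_width
    if elem.kind == "domain":
        return registry.domain_widths[elem.name]
    return _regex_width(registry.motif_regexes[elem.name])


def _layout_family(
    family: FamilySignature, cfg: SyntheticConfig, registry: SignatureRegistry
) -> list[tuple[str, str, int, int]]:
    """Place every template element, honouring spacing constraints
    (start constraints pin absolute positions; gap constraints between
    consecutive elements override the default inter-element gap)."""
    default_gap = 20
    start_constraints: dict[tuple[str, str, int], int] = {}
    gap_constraints: dict[tuple[str, str, int], int] = {}
    for sc in family.spacing:
        if sc.measure == "start":
            key = _ref_key(sc.element)
            start_constraints[key] = (sc.min + sc.max) // 2
        else:
            key = _ref_key(sc.b)
            gap_constraints[key] = (sc.min + sc.max) // 2

    placed: list[tuple[str, str, int, int]] = []
    counters: dict[tuple[str, str], int] = {}
    cursor = 0  # end of previous element
    for elem in family.template:
        width = _element_width(elem, cfg, registry)
        name = "LIM" if elem.kind == "lim" else elem.name
        k = counters.get((elem.kind, name), 0) + 1
        counters[(elem.kind, name)] = k
        key = (elem.kind, name, k)
        if key in start_constraints:
            start = start_constraints[key]
        elif key in gap_constraints:
            start = cursor + gap_constraints[key] + 1
        else:
            start = cursor + default_gap + 1
        if start <= cursor:
            raise ValueError(
                f"{family.label}: impossible spacing — element {elem} at "
                f"{start} overlaps previous element ending at {cursor} "
                f"(lim_width={cfg.lim_width})"
            )
        end = start + width - 1
        placed.append((elem.kind, name, start, end))
        cursor = end
    return placed


def _ref_key(ref: str) -> tuple[str, str, int]:
    parts = ref.split(":")
    if parts[0] == "lim":
        return ("lim", "LIM", int(parts[1]) if len(parts) > 1 else 1)
    return (parts[0], parts[1], int(parts[2]) if len(parts) > 2 else 1)


# ---------------------------------------------------------------------------
# proteome generation


def generate_proteome(
    cfg: SyntheticConfig, registry: SignatureRegistry | None = None
) -> SyntheticProteome:
    """Plant one proteome: records, hit table and ground truth.

    Homology groups are global across species: group ids are allocated one
    per (class, LIM slot), so the same slot of the same class in every
    species descends from the same planted group.
    """
    registry = registry or load_registry()
    class_names = list(cfg.classes or sorted(CANONICAL_FAMILY))
    # allocate group ids per (class, slot letter)
    truth = GroundTruth()
    gid = 0
    slot_group: dict[tuple[str, str], int] = {}
    for cname in class_names:
        fam = _canonical_family(registry, cname)
        n_slots = sum(1 for e in fam.template if e.kind == "lim")
        for slot_i in range(n_slots):
            gid += 1
            ordinal = chr(ord("A") + slot_i)
            slot_group[(cname, ordinal)] = gid
            truth.group_meta[gid] = (cname, ordinal)
            truth.group_members[gid] = set()

    records: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    for cname in class_names:
        fam = _canonical_family(registry, cname)
        layout = _layout_family(fam, cfg, registry)
        counts = cfg.counts_for(cname)
        for sp in cfg.species:
            for rep in range(counts.get(sp, 0)):
                pid = f"{sp}_{cname}{rep + 1}"
                rng = cfg.rng("protein", pid)
                features = list(layout)
                if cfg.arch_dropout_p > 0:
                    kept = [
                        f for f in features if rng.random() >= cfg.arch_dropout_p
                    ]
                    if not kept:
                        kept = [features[0]]
                    features = kept
                length = features[-1][3] + 20
                seq = list(_random_sequence(rng, length, cfg.background))
                lim_groups: list[int] = []
                slot_i = 0
                for kind, name, start, end in features:
                    if kind == "lim":
                        ordinal = chr(ord("A") + slot_i)
                        g = slot_group[(cname, ordinal)]
                        lim_seq = _mutate_lim(
                            _group_consensus(g, cfg.lim_width, cfg),
                            rng,
                            cfg.lim_mutation_rate,
                        )
                        seq[start - 1 : end] = list(lim_seq)
                        lim_ordinal = chr(
                            ord("A") + len(lim_groups)
                        )  # ordinal after dropout
                        truth.group_members[g].add(f"{pid}.{lim_ordinal}")
                        lim_groups.append(g)
                        slot_i += 1
                        hits.append(
                            DomainHit(
                                protein_id=pid,
                                model="LIM",
                                env_start=start,
                                env_end=end,
                                ali_start=start,
                                ali_end=end,
                                independent_evalue=10.0
                                ** -float(rng.uniform(6, 25)),
                                score=float(rng.uniform(40, 90)),
                                aligned_match_string=lim_seq,
                            )
                        )
                        if rng.random() < cfg.extra_domain_p:
                            # decoy zinc-finger prediction overlapping the LIM
                            d_start = max(1, start - 5)
                            d_end = min(length, start + 17)
                            hits.append(
                                DomainHit(
                                    protein_id=pid,
                                    model="zf-C2H2",
                                    env_start=d_start,
                                    env_end=d_end,
                                    ali_start=d_start,
                                    ali_end=d_end,
                                    independent_evalue=float(
                                        rng.uniform(1e-4, 0.04)
                                    ),
                                    score=float(rng.uniform(8, 15)),
                                )
                            )
                    elif kind == "domain":
                        hits.append(
                            DomainHit(
                                protein_id=pid,
                                model=name,
                                env_start=start,
                                env_end=end,
                                ali_start=start,
                                ali_end=end,
                                independent_evalue=10.0
                                ** -float(rng.uniform(4, 20)),
                                score=float(rng.uniform(30, 80)),
                            )
                        )
                    else:  # motif: plant a regex-conformant substring
                        motif_seq = _expand_regex(
                            registry.motif_regexes[name], rng
                        )
                        seq[start - 1 : end] = list(motif_seq)
                records.append(
                    ProteinRecord(
                        id=pid,
                        species=sp,
                        sequence="".join(seq),
                        source_accession=pid,
                    )
                )
                truth.proteins[pid] = TrueProtein(
                    protein_id=pid,
                    species=sp,
                    class_name=cname,
                    family=fam.name,
                    features=features,
                    lim_groups=lim_groups,
                    length=length,
                )
    return SyntheticProteome(
        records=records, hits=hits, truth=truth, registry=registry
    )


def _canonical_family(
    registry: SignatureRegistry, class_name: str
) -> FamilySignature:
    fam_name = CANONICAL_FAMILY.get(class_name)
    cls = registry.classes[class_name]
    if fam_name and fam_name in cls.families:
        return cls.families[fam_name]
    return cls.families[sorted(cls.families)[0]]


# ---------------------------------------------------------------------------
# gene trees


def _random_binary(
    rng: np.random.Generator, leaves: Sequence[str], taxa: dendropy.TaxonNamespace
) -> dendropy.Node:
    nodes = []
    for label in leaves:
        node = dendropy.Node()
        node.taxon = taxa.require_taxon(label=label)
        node.edge.length = float(rng.uniform(0.1, 0.6))
        nodes.append(node)
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.uniform(0.1, 0.6))
        nodes.append(parent)
    return nodes[0]


def generate_gene_tree(
    cfg: SyntheticConfig,
    truth: GroundTruth,
    backbone: str = "random",
    backbone_stream: object = 0,
) -> dendropy.Tree:
    """Gene tree over all planted LIM leaves: each homology group forms a
    clade (before NNI noise), joined by the requested backbone shape.

    Within-group topologies depend only on (seed, group id), so trees built
    with different backbones agree on every within-group clade — the
    property the tree-pair construction relies on.
    """
    if backbone not in ("random", "star", "caterpillar"):
        raise ValueError("backbone must be random | star | caterpillar")
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    group_roots = []
    for gid in sorted(truth.group_members):
        members = sorted(truth.group_members[gid])
        if not members:
            continue
        rng = cfg.rng("genetree-group", gid)
        sub = _random_binary(rng, members, taxa)
        sub.edge.length = 2.0  # long group stem keeps clades separated
        group_roots.append(sub)
    rng_b = cfg.rng("genetree-backbone", backbone, backbone_stream)
    if backbone == "star" or len(group_roots) <= 2:
        for sub in group_roots:
            tree.seed_node.add_child(sub)
    elif backbone == "caterpillar":
        current = tree.seed_node
        remaining = list(group_roots)
        while len(remaining) > 2:
            nxt = dendropy.Node()
            nxt.edge.length = float(rng_b.uniform(0.1, 0.6))
            current.add_child(remaining.pop(0))
            current.add_child(nxt)
            current = nxt
        for sub in remaining:
            current.add_child(sub)
    else:
        nodes = list(group_roots)
        while len(nodes) > 2:
            a = nodes.pop(int(rng_b.integers(len(nodes))))
            b = nodes.pop(int(rng_b.integers(len(nodes))))
            parent = dendropy.Node()
            parent.edge.length = float(rng_b.uniform(0.1, 0.6))
            parent.add_child(a)
            parent.add_child(b)
            nodes.append(parent)
        for node in nodes:
            tree.seed_node.add_child(node)
    tree.is_rooted = True
    if cfg.tree_nni_moves:
        _apply_nni(tree, cfg.rng("genetree-nni", backbone, backbone_stream),
                   cfg.tree_nni_moves)
    return tree


def _apply_nni(
    tree: dendropy.Tree, rng: np.random.Generator, n_moves: int
) -> None:
    for _ in range(n_moves):
        internal = [
            n
            for n in tree.preorder_node_iter()
            if n.parent_node is not None
            and not n.is_leaf()
            and len(n.parent_node.child_nodes()) >= 2
        ]
        if not internal:
            return
        v = internal[int(rng.integers(len(internal)))]
        p = v.parent_node
        siblings = [c for c in p.child_nodes() if c is not v]
        children = v.child_nodes()
        if not siblings or not children:
            continue
        b = siblings[int(rng.integers(len(siblings)))]
        a = children[int(rng.integers(len(children)))]
        # swap subtrees a and b
        p.remove_child(b)
        v.remove_child(a)
        p.add_child(a)
        v.add_child(b)


def generate_tree_pair(
    cfg: SyntheticConfig, truth: GroundTruth
) -> tuple[dendropy.Tree, dendropy.Tree]:
    """A (random-backbone, star-backbone) gene-tree pair.

    Pruned to human leaves and fed to strict consensus, the star backbone
    guarantees that no between-group split survives, while the shared
    within-group topologies guarantee every group clade does — emulating a
    consensus whose deep backbone is unsupported but whose shallow clades
    are consistently recovered.
    """
    return (
        generate_gene_tree(cfg, truth, backbone="random"),
        generate_gene_tree(cfg, truth, backbone="star"),
    )


# ---------------------------------------------------------------------------
# presence matrices


def _node_leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def matrix_from_events(
    species_tree: dendropy.Tree,
    events: Mapping[str, tuple[frozenset[str], Sequence[frozenset[str]]]],
) -> PresenceMatrix:
    """Presence matrix implied by planted (origin clade, loss clades) rows.

    Events must be canonical for a single-gain model — losses pairwise
    disjoint and strictly inside the origin clade, every loss's sibling
    subtrees retaining a present leaf, and at least two origin-clade child
    subtrees present (so the origin really is the MRCA of the present set);
    inconsistent events raise ValueError.
    """
    species = tuple(
        sorted(leaf_labels(species_tree), key=lambda s: SPECIES.index(s))
        if set(leaf_labels(species_tree)) <= set(SPECIES)
        else sorted(leaf_labels(species_tree))
    )
    clades = {_node_leafset(n): n for n in species_tree.preorder_node_iter()}
    rows: dict[str, dict[str, str]] = {}
    for label, (origin, losses) in events.items():
        if origin not in clades:
            raise ValueError(f"{label}: origin {sorted(origin)} is not a clade")
        for loss in losses:
            if loss not in clades:
                raise ValueError(f"{label}: loss {sorted(loss)} is not a clade")
            if not loss < origin:
                raise ValueError(
                    f"{label}: loss {sorted(loss)} not strictly inside origin"
                )
        for i, a in enumerate(losses):
            for b in list(losses)[i + 1 :]:
                if a & b:
                    raise ValueError(f"{label}: overlapping losses")
        present = set(origin)
        for loss in losses:
            present -= loss
        if not present:
            raise ValueError(f"{label}: losses cover the whole origin clade")
        # canonicality: recompute (origin, losses) from the leaf states
        mrca = species_tree.mrca(taxon_labels=sorted(present))
        canon_losses: list[frozenset[str]] = []

        def walk(node: dendropy.Node) -> None:
            clade = _node_leafset(node)
            if not (clade & present):
                canon_losses.append(clade)
                return
            for child in node.child_nodes():
                walk(child)

        for child in mrca.child_nodes():
            walk(child)
        if _node_leafset(mrca) != origin or set(canon_losses) != set(losses):
            raise ValueError(
                f"{label}: events are not canonical for the implied states "
                f"(origin would be {sorted(_node_leafset(mrca))}, losses "
                f"{[sorted(c) for c in canon_losses]})"
            )
        rows[label] = {
            sp: ("present" if sp in present else "absent") for sp in species
        }
    return PresenceMatrix.from_rows(rows, species=species)


def sample_dollo_events(
    rng: np.random.Generator,
    species_tree: dendropy.Tree,
    loss_p: float = 0.25,
    max_tries: int = 200,
) -> tuple[frozenset[str], list[frozenset[str]]]:
    """Sample one canonical (origin, losses) event pair by rejection."""
    nodes = [
        n for n in species_tree.preorder_node_iter() if not n.is_leaf()
    ]
    for _ in range(max_tries):
        origin_node = nodes[int(rng.integers(len(nodes)))]
        origin = _node_leafset(origin_node)
        losses: list[frozenset[str]] = []

        def walk(node: dendropy.Node) -> None:
            if node.is_leaf():
                if rng.random() < loss_p:
                    losses.append(_node_leafset(node))
                return
            if rng.random() < loss_p / 2:
                losses.append(_node_leafset(node))
                return
            for child in node.child_nodes():
                walk(child)

        for child in origin_node.child_nodes():
            walk(child)
        try:
            matrix_from_events(species_tree, {"row": (origin, losses)})
        except ValueError:
            continue
        return origin, losses
    raise RuntimeError("could not sample canonical Dollo events")


def generate_presence_matrix(
    cfg: SyntheticConfig,
    species_tree: dendropy.Tree,
    events: Mapping[str, tuple[frozenset[str], Sequence[frozenset[str]]]]
    | None = None,
    n_rows: int = 14,
) -> tuple[PresenceMatrix, dict]:
    """Presence matrix from planted events (sampled when not supplied)."""
    if events is None:
        rng = cfg.rng("presence")
        events = {
            f"row{i + 1}": sample_dollo_events(rng, species_tree)
            for i in range(n_rows)
        }
    return matrix_from_events(species_tree, events), dict(events)


# ---------------------------------------------------------------------------
# motif datasets


def plant_motif_dataset(
    seed: int,
    n_seqs: int = 20,
    seq_len: int = 150,
    width: int = 12,
    n_sites: int = 8,
    subs_per_site: int = 0,
) -> tuple[list, list[tuple[str, int]]]:
    """Sequences with one planted motif instance in the first ``n_sites``
    sequences, each copy carrying ``subs_per_site`` random substitutions.
    Returns (MaskedSequence list, [(protein_id, planted 1-based start)])."""
    from .motifs import MaskedSequence

    rng = np.random.default_rng(seed)
    motif = "".join(rng.choice(list(AA), size=width))
    seqs = []
    truth = []
    for i in range(n_seqs):
        s = list("".join(rng.choice(list(AA), size=seq_len)))
        pid = f"SY_M{i}"
        if i < n_sites:
            pos = int(rng.integers(0, seq_len - width))
            copy = list(motif)
            for _ in range(subs_per_site):
                j = int(rng.integers(width))
                copy[j] = AA[int(rng.integers(len(AA)))]
            s[pos : pos + width] = copy
            truth.append((pid, pos + 1))
        seqs.append(MaskedSequence.from_plain(pid, "".join(s)))
    return seqs, truth
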
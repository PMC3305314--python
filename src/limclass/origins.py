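"""Presence matrices and single-gain (Dollo) origin/loss mapping.

Each LIM class (or family) is scored present / partial / absent in each
sampled species; under Dollo parsimony a character is gained exactly once —
on the stem edge of the most recent common ancestor of the species that
have it — and explained absences are losses, placed on the deepest edges
whose entire subtended leaf set lacks the character. For a single-gain
model this loss set is the unique minimum.

The default nine-species tree follows the ParaHoxozoa hypothesis:
(Co,((Sr,Mb),(Aq,(Ml,(Ta,(Nv,(Dm,Hs))))))) — Capsaspora outside a
choanoflagellate + metazoan clade, sponge then ctenophore branching before
the Placozoa+Cnidaria+Bilateria clade. The Porifera/Ctenophora order is
configurable; metazoan-stem conclusions do not depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .trees import TreeError, leaf_labels, read_newick

__all__ = [
    "PresenceMatrix",
    "OriginReport",
    "build_presence_matrix",
    "dollo_map",
    "summarize_origins",
    "default_species_tree",
    "clade_name",
    "NAMED_CLADES",
    "SPECIES",
    "STATES",
]

SPECIES = ("Co", "Sr", "Mb", "Aq", "Ml", "Ta", "Nv", "Dm", "Hs")
STATES = ("present", "partial", "absent")

NAMED_CLADES: dict[frozenset[str], str] = {
    frozenset(SPECIES): "Holozoa-root",
    frozenset({"Sr", "Mb", "Aq", "Ml", "Ta", "Nv", "Dm", "Hs"}): (
        "Choanoflagellata+Metazoa"
    ),
    frozenset({"Sr", "Mb"}): "Choanoflagellata",
    frozenset({"Aq", "Ml", "Ta", "Nv", "Dm", "Hs"}): "Metazoa",
    frozenset({"Ml", "Ta", "Nv", "Dm", "Hs"}): "Metazoa-minus-Porifera",
    frozenset({"Ta", "Nv", "Dm", "Hs"}): "ParaHoxozoa",
    frozenset({"Nv", "Dm", "Hs"}): "Cnidaria+Bilateria",
    frozenset({"Dm", "Hs"}): "Bilateria",
}


def default_species_tree() -> dendropy.Tree:
    path = resources.files("limclass.data") / "species_tree.nwk"
    tree = read_newick(str(path), rooted=True)
    return tree


def clade_name(clade: frozenset[str]) -> str:
    if clade in NAMED_CLADES:
        return NAMED_CLADES[clade]
    return "+".join(sorted(clade))


@dataclass
class PresenceMatrix:
    """Class/family x species presence states, backed by a DataFrame with
    values in {present, partial, absent}."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.data.values.ravel()) - set(STATES)
        if bad:
            raise ValueError(f"invalid presence states {sorted(bad)}")

    def row(self, label: str) -> dict[str, str]:
        return dict(self.data.loc[label])

    @property
    def rows(self) -> list[str]:
        return list(self.data.index)

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index_label="row")

    @classmethod
    def from_rows(
        cls, rows: Mapping[str, Mapping[str, str]], species: Sequence[str] = SPECIES
    ) -> "PresenceMatrix":
        frame = pd.DataFrame(
            [[rows[r].get(sp, "absent") for sp in species] for r in rows],
            index=list(rows),
            columns=list(species),
        )
        return cls(frame)


@dataclass
class OriginReport:
    """Single-gain explanation of one presence row: the stem edge where the
    character originated (identified by the subtended leaf set) and the
    minimal loss edges inside the origin clade."""

    row_label: str
    origin_clade: frozenset[str] | None
    loss_clades: list[frozenset[str]] = field(default_factory=list)
    notes: str = ""

    @property
    def origin_name(self) -> str | None:
        return None if self.origin_clade is None else clade_name(self.origin_clade)

    @property
    def loss_names(self) -> list[str]:
        return [clade_name(c) for c in self.loss_clades]


def build_presence_matrix(
    results: Sequence,
    species: Sequence[str] = SPECIES,
    class_names: Sequence[str] | None = None,
    include_families: bool = True,
) -> PresenceMatrix:
    """Score classes (and families, as ``CLASS/Family`` rows) per species.

    A row is *present* in a species when at least one protein of that
    class/family carries no partial-architecture flag; *partial* when only
    flagged proteins exist; *absent* otherwise. ``results`` are
    :class:`~limclass.classify.ClassificationResult` objects.
    """
    known = set(species)
    for r in results:
        if r.species not in known:
            raise ValueError(f"unknown species code {r.species!r}")
    rows: dict[str, dict[str, str]] = {}
    labels = set(class_names or ())
    for r in results:
        if not r.classified:
            continue
        labels.add(r.class_name)
        if include_families and r.family:
            labels.add(f"{r.class_name}/{r.family}")
    for label in labels:
        rows[label] = {sp: "absent" for sp in species}
    for r in results:
        if not r.classified:
            continue
        targets = [r.class_name]
        if include_families and r.family:
            targets.append(f"{r.class_name}/{r.family}")
        state = (
            "partial" if "partial_architecture" in r.flags else "present"
        )
        for label in targets:
            current = rows[label][r.species]
            if state == "present" or current == "absent":
                rows[label][r.species] = state
    ordered = dict(sorted(rows.items()))
    return PresenceMatrix.from_rows(ordered, species=species)


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def dollo_map(
    row: Mapping[str, str],
    species_tree: dendropy.Tree,
    treat_partial: str = "present",
    row_label: str = "",
) -> OriginReport | None:
    """Single-gain origin and minimal losses for one presence row.

    ``treat_partial`` decides whether partial evidence counts as presence
    (the default: a degraded architecture still evidences the class) or
    absence. Returns None (the no-origin sentinel) for an all-absent row.
    The origin is the stem edge of the MRCA of the present species; losses
    are the maximal subtrees inside the origin clade whose leaves all lack
    the character — the unique minimal loss set under a single gain.
    """
    if treat_partial not in ("present", "absent"):
        raise ValueError("treat_partial must be 'present' or 'absent'")
    if not species_tree.is_rooted:
        raise TreeError("dollo_map requires a rooted species tree")
    tips = leaf_labels(species_tree)
    unknown = set(row) - set(tips)
    if unknown:
        raise ValueError(f"row references unknown species {sorted(unknown)}")
    present = {
        sp
        for sp, state in row.items()
        if state == "present" or (state == "partial" and treat_partial == "present")
    }
    if not present:
        return None
    mrca = species_tree.mrca(taxon_labels=sorted(present))
    losses: list[frozenset[str]] = []

    def walk(node: dendropy.Node) -> None:
        clade = _leafset(node)
        if not (clade & present):
            losses.append(clade)
            return
        for child in node.child_nodes():
            walk(child)

    for child in mrca.child_nodes():
        walk(child)
    losses.sort(key=lambda c: (-len(c), sorted(c)))
    return OriginReport(
        row_label=row_label,
        origin_clade=_leafset(mrca),
        loss_clades=losses,
    )


def dollo_map_matrix(
    matrix: PresenceMatrix,
    species_tree: dendropy.Tree,
    treat_partial: str = "present",
) -> dict[str, OriginReport | None]:
    return {
        label: dollo_map(
            matrix.row(label),
            species_tree,
            treat_partial=treat_partial,
            row_label=label,
        )
        for label in matrix.rows
    }


def summarize_origins(
    reports: Iterable[OriginReport | None],
    focal_clade: frozenset[str] | Iterable[str],
) -> tuple[int, list[str]]:
    """Count and list the rows whose origin is the stem of ``focal_clade``."""
    focal = frozenset(focal_clade)
    labels = sorted(
        r.row_label
        for r in reports
        if r is not None and r.origin_clade == focal
    )
    return len(labels), labels


def summarize_losses(
    reports: Iterable[OriginReport | None],
    focal_clade: frozenset[str] | Iterable[str],
) -> tuple[int, list[str]]:
    """Count and list the rows with a loss on the stem of ``focal_clade``."""
    focal = frozenset(focal_clade)
    labels = sorted(
        r.row_label
        for r in reports
        if r is not None and focal in r.loss_clades
    )
    return len(labels), labels


def write_origins_tsv(
    reports: Mapping[str, OriginReport | None], path: str
) -> None:
    with open(path, "w") as out:
        out.write("row\torigin\tlosses\tnotes\n")
        for label in sorted(reports):
            rep = reports[label]
            if rep is None:
                out.write(f"{label}\t(no origin)\t\t\n")
            else:
                out.write(
                    f"{label}\t{rep.origin_name}"
                    f"\t{';'.join(rep.loss_names)}\t{rep.notes}\n"
                )
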
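"""End-to-end orchestration: annotate -> motifs -> trees/groups ->
classify -> origins, with a machine-readable run manifest.

The pipeline can run from files (FASTA + domain tables + Newick gene
trees) or from the synthetic generator; both paths share the same stage
functions so synthetic recovery exercises the production code. A
supplementary-reproduction mode recomputes the headline tree-derived
counts when the published gene-tree files are supplied.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy

from . import __version__
from .annotation import (
    DomainHit,
    ProteinRecord,
    assemble_lim_instances,
    filter_hits,
    live_scan,
    read_domtblout,
    read_fasta,
    resolve_overlaps,
    select_representative_isoforms,
    write_hits_tsv,
)
from .classify import (
    ClassificationResult,
    ProteinAnnotation,
    classify_all,
    write_classification_tsv,
)
from .homology import (
    AssignmentResult,
    HomologyGroup,
    assign_nonhuman,
    build_homology_groups,
    is_human_leaf,
    write_groups_tsv,
)
from .motifs import MaskedSequence, MotifOccurrence, scan_regex
from .origins import (
    PresenceMatrix,
    build_presence_matrix,
    default_species_tree,
    dollo_map_matrix,
    write_origins_tsv,
)
from .signatures import SignatureRegistry, load_registry
from .trees import (
    leaf_labels,
    midpoint_root,
    prune_to,
    read_newick,
    strict_consensus,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "annotate_proteins",
    "compute_groups",
    "attach_groups",
    "run_pipeline",
    "run_synthetic",
    "reproduce_supplementary",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class PipelineConfig:
    fasta: str | None = None
    hit_table: str | None = None
    hmm: str | None = None
    gene_tree: str | None = None  # multi-species Newick
    human_tree: str | None = None  # human-only Newick
    species_tree: str | None = None  # defaults to the packaged topology
    signatures: str | None = None
    motif_table: str | None = None
    ie_max: float = 0.05
    midpoint_lengths: str = "unit"
    treat_partial: str = "present"
    isoform_policy: str = "longest"
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        for label, path in (
            ("fasta", self.fasta),
            ("hit_table", self.hit_table),
            ("hmm", self.hmm),
            ("gene_tree", self.gene_tree),
            ("human_tree", self.human_tree),
            ("species_tree", self.species_tree),
            ("signatures", self.signatures),
            ("motif_table", self.motif_table),
        ):
            if path is not None and not Path(path).exists():
                raise PipelineError(f"validation: {label} path {path} not found")
        if self.fasta is None:
            raise PipelineError("validation: a proteome FASTA is required")
        if self.hit_table is None and self.hmm is None:
            raise PipelineError(
                "validation: either a pre-computed hit table or an HMM for "
                "live scanning is required"
            )
        if not 0 <= self.ie_max:
            raise PipelineError("validation: ie_max must be >= 0")


@dataclass
class PipelineResult:
    annotations: list[ProteinAnnotation]
    results: list[ClassificationResult]
    groups: list[HomologyGroup]
    assignments: list[AssignmentResult]
    matrix: PresenceMatrix | None
    origin_reports: dict
    manifest: dict


# ---------------------------------------------------------------------------
# stages


def annotate_proteins(
    records: Sequence[ProteinRecord],
    hits: Sequence[DomainHit],
    registry: SignatureRegistry,
    ie_max: float = 0.05,
    isoform_policy: str = "longest",
) -> tuple[list[ProteinAnnotation], dict]:
    """Annotation stage: isoform selection, E-value filter, per-protein
    overlap resolution, LIM-instance assembly, and regex motif scanning."""
    records, iso_report = select_representative_isoforms(
        records, policy=isoform_policy
    )
    retained, ev_report = filter_hits(hits, ie_max=ie_max)
    by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    for h in retained:
        by_protein[h.protein_id].append(h)

    seqs = [MaskedSequence.from_plain(r.id, r.sequence) for r in records]
    occurrences = scan_regex(seqs, registry.motif_regexes)
    occ_by: dict[str, list[MotifOccurrence]] = defaultdict(list)
    for occ in occurrences:
        occ_by[occ.protein_id].append(occ)

    annotations = []
    n_overlap = n_instance_drop = 0
    for rec in sorted(records, key=lambda r: r.id):
        try:
            resolved, ov_report = resolve_overlaps(by_protein.get(rec.id, []))
            lims, inst_report = assemble_lim_instances(rec, resolved)
        except ValueError as exc:
            raise PipelineError(f"annotate: {rec.id}: {exc}") from exc
        n_overlap += len(ov_report)
        n_instance_drop += len(inst_report)
        annotations.append(
            ProteinAnnotation(
                protein_id=rec.id,
                species=rec.species,
                length=len(rec.sequence),
                lims=lims,
                domains=[h for h in resolved if h.model != "LIM"],
                motifs=sorted(occ_by.get(rec.id, []), key=lambda o: o.start),
            )
        )
    counts = {
        "proteins_in": len(records) + len(iso_report),
        "proteins_kept": len(records),
        "isoforms_discarded": len(iso_report),
        "hits_in": len(hits),
        "hits_evalue_filtered": len(ev_report),
        "hits_overlap_filtered": n_overlap,
        "lim_hits_discarded": n_instance_drop,
        "lim_instances": sum(len(a.lims) for a in annotations),
        "motif_occurrences": len(occurrences),
    }
    return annotations, counts


def compute_groups(
    multi_tree: dendropy.Tree,
    human_tree: dendropy.Tree | None = None,
    midpoint_lengths: str = "unit",
) -> tuple[list[HomologyGroup], list[AssignmentResult], dict]:
    """Tree stage: human consensus, midpoint rooting, basal clades,
    nearest-neighbor assignment of non-human LIM leaves.

    When a human-only tree is supplied the groups come from the strict
    consensus of it with the human restriction of the multi-species tree;
    otherwise from the human restriction alone.
    """
    human_leaves = sorted(
        l for l in leaf_labels(multi_tree) if is_human_leaf(l)
    )
    if len(human_leaves) < 2:
        raise PipelineError("groups: multi-species tree has <2 human leaves")
    pruned = prune_to(multi_tree, human_leaves)
    if human_tree is not None:
        if leaf_labels(human_tree) != frozenset(human_leaves):
            raise PipelineError(
                "groups: human tree leaves do not match the human leaves of "
                "the multi-species tree"
            )
        consensus = strict_consensus(pruned, human_tree)
    else:
        consensus = pruned
    rooted_consensus = midpoint_root(consensus, lengths=midpoint_lengths)
    groups = build_homology_groups(rooted_consensus)

    has_lengths = all(
        e.length is not None
        for e in multi_tree.preorder_edge_iter()
        if e.head_node is not multi_tree.seed_node
    )
    rooted_multi = midpoint_root(
        multi_tree, lengths="branch" if has_lengths else "unit"
    )
    assignments = assign_nonhuman(rooted_multi, groups)
    counts = {
        "human_leaves": len(human_leaves),
        "homology_groups": len(groups),
        "human_small_group_taxa": sum(
            len(g.members_human)
            for g in groups
            if len(g.members_human) <= 3
        ),
        "nonhuman_leaves": len(assignments),
        "assigned": sum(1 for a in assignments if a.status == "assigned"),
        "unclassifiable": sum(
            1 for a in assignments if a.status == "unclassifiable"
        ),
    }
    return groups, assignments, counts


def attach_groups(
    annotations: Sequence[ProteinAnnotation],
    groups: Sequence[HomologyGroup],
    assignments: Sequence[AssignmentResult],
) -> list[ProteinAnnotation]:
    """Write homology-group ids onto each LIM instance (by leaf label)."""
    human_group = {
        label: g.id for g in groups for label in g.members_human
    }
    assigned = {a.leaf: a.group for a in assignments}
    out = []
    for ann in annotations:
        lims = []
        for lim in ann.lims:
            gid = human_group.get(lim.label, assigned.get(lim.label))
            lims.append(replace(lim, homology_group=gid))
        out.append(
            ProteinAnnotation(
                protein_id=ann.protein_id,
                species=ann.species,
                length=ann.length,
                lims=lims,
                domains=ann.domains,
                motifs=ann.motifs,
            )
        )
    return out


# ---------------------------------------------------------------------------
# drivers


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order and (optionally) write the output
    tables plus a manifest recording seed, thresholds and per-stage
    counts."""
    config.validate()
    registry = load_registry(config.signatures, config.motif_table)
    records = read_fasta(config.fasta)
    if config.hit_table:
        hits = live_scan(
            config.fasta, backend="none", table_path=config.hit_table
        )
    else:
        hits = live_scan(config.fasta, hmm_path=config.hmm, backend="external")
    return _run_stages(records, hits, registry, config)


def run_synthetic(cfg, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the pipeline on a generated proteome + gene-tree pair."""
    from .simulate import generate_proteome, generate_tree_pair

    config = config or PipelineConfig()
    proteome = generate_proteome(cfg)
    t_random, t_star = generate_tree_pair(cfg, proteome.truth)
    return _run_stages(
        proteome.records,
        proteome.hits,
        proteome.registry,
        config,
        multi_tree=t_random,
        second_tree=t_star,
    )


def _run_stages(
    records: Sequence[ProteinRecord],
    hits: Sequence[DomainHit],
    registry: SignatureRegistry,
    config: PipelineConfig,
    multi_tree: dendropy.Tree | None = None,
    second_tree: dendropy.Tree | None = None,
) -> PipelineResult:
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "ie_max": config.ie_max,
            "midpoint_lengths": config.midpoint_lengths,
            "treat_partial": config.treat_partial,
        },
        "stages": {},
    }
    annotations, counts = annotate_proteins(
        records,
        hits,
        registry,
        ie_max=config.ie_max,
        isoform_policy=config.isoform_policy,
    )
    manifest["stages"]["annotate"] = counts

    groups: list[HomologyGroup] = []
    assignments: list[AssignmentResult] = []
    if multi_tree is None and config.gene_tree:
        multi_tree = read_newick(config.gene_tree)
    if second_tree is None and config.human_tree:
        second_tree = read_newick(config.human_tree)
    if multi_tree is not None:
        human_tree = None
        if second_tree is not None:
            human_leaves = [
                l for l in leaf_labels(second_tree) if is_human_leaf(l)
            ]
            human_tree = (
                prune_to(second_tree, human_leaves)
                if frozenset(human_leaves) != leaf_labels(second_tree)
                else second_tree
            )
        groups, assignments, gcounts = compute_groups(
            multi_tree,
            human_tree=human_tree,
            midpoint_lengths=config.midpoint_lengths,
        )
        manifest["stages"]["groups"] = gcounts
        annotations = attach_groups(annotations, groups, assignments)

    results = classify_all(annotations, registry)
    manifest["stages"]["classify"] = {
        "classified": sum(1 for r in results if r.classified),
        "unclassified": sum(1 for r in results if not r.classified),
        "flagged_partial": sum(
            1 for r in results if "partial_architecture" in r.flags
        ),
        "flagged_misannotation": sum(
            1 for r in results if "suspected_misannotation" in r.flags
        ),
    }

    species_tree = (
        read_newick(config.species_tree, rooted=True)
        if config.species_tree
        else default_species_tree()
    )
    observed_species = {r.species for r in results}
    matrix = None
    origin_reports: dict = {}
    if observed_species <= set(leaf_labels(species_tree)):
        matrix = build_presence_matrix(
            results, species=tuple(sorted(leaf_labels(species_tree)))
        )
        origin_reports = dollo_map_matrix(
            matrix, species_tree, treat_partial=config.treat_partial
        )
        manifest["stages"]["origins"] = {
            "rows": len(matrix.rows),
            "rows_with_origin": sum(
                1 for r in origin_reports.values() if r is not None
            ),
        }
    if config.outdir:
        _write_outputs(
            config.outdir,
            manifest,
            annotations,
            results,
            groups,
            assignments,
            matrix,
            origin_reports,
        )
    return PipelineResult(
        annotations=annotations,
        results=results,
        groups=groups,
        assignments=assignments,
        matrix=matrix,
        origin_reports=origin_reports,
        manifest=manifest,
    )


def _write_outputs(
    outdir: str,
    manifest: dict,
    annotations,
    results,
    groups,
    assignments,
    matrix,
    origin_reports,
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    all_hits = [h for a in annotations for h in a.domains] + [
        DomainHit(
            protein_id=l.protein_id,
            model="LIM",
            env_start=l.env_start,
            env_end=l.env_end,
            ali_start=l.ali_start,
            ali_end=l.ali_end,
            independent_evalue=l.independent_evalue,
        )
        for a in annotations
        for l in a.lims
    ]
    write_hits_tsv(all_hits, str(out / "retained_hits.tsv"))
    write_classification_tsv(results, str(out / "classification.tsv"))
    if groups:
        write_groups_tsv(groups, assignments, str(out / "groups.tsv"))
    if matrix is not None:
        matrix.to_tsv(str(out / "presence.tsv"))
        write_origins_tsv(origin_reports, str(out / "origins.tsv"))
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# supplementary reproduction


#: headline counts printed in the published analysis, for side-by-side
#: display in the reproduction report (display only — never used in any
#: computation)
PUBLISHED_COUNTS = {
    "homology_groups": 38,
    "human_leaves": 171,
    "human_small_group_taxa": 12,
    "nonhuman_leaves": 473,
    "assigned": 392,
    "classified_proteins": 206,
    "total_proteins": 265,
}


def reproduce_supplementary(
    multi_tree_path: str,
    human_tree_path: str,
    classification_table: str | None = None,
    midpoint_lengths: str = "unit",
) -> dict:
    """Recompute the tree-derived headline counts from the deposited
    Newick gene trees (and, when a classification-table export is
    supplied, the classified/unclassified protein tally).

    Returns {"computed": ..., "published": ..., "notes": [...]}.
    """
    notes = []
    try:
        multi = read_newick(multi_tree_path)
    except Exception as exc:
        raise PipelineError(
            f"reproduce: cannot parse {multi_tree_path}: {exc}"
        ) from exc
    try:
        human = read_newick(human_tree_path)
    except Exception as exc:
        raise PipelineError(
            f"reproduce: cannot parse {human_tree_path}: {exc}"
        ) from exc
    human_labels = [l for l in leaf_labels(human) if is_human_leaf(l)]
    if frozenset(human_labels) != leaf_labels(human):
        human = prune_to(human, human_labels)
        notes.append("human tree contained non-human leaves; pruned")
    groups, assignments, counts = compute_groups(
        multi, human_tree=human, midpoint_lengths=midpoint_lengths
    )
    computed = dict(counts)
    if classification_table:
        classified = unclassified = 0
        with open(classification_table) as handle:
            header = handle.readline().rstrip("\n").split("\t")
            try:
                class_col = header.index("class")
            except ValueError:
                raise PipelineError(
                    "reproduce: classification table needs a 'class' column"
                )
            for line in handle:
                fields = line.rstrip("\n").split("\t")
                if len(fields) <= class_col:
                    continue
                if fields[class_col].upper() == "UNCLASSIFIED":
                    unclassified += 1
                else:
                    classified += 1
        computed["classified_proteins"] = classified
        computed["total_proteins"] = classified + unclassified
    else:
        notes.append("no classification table supplied; protein tally skipped")
    return {
        "computed": computed,
        "published": dict(PUBLISHED_COUNTS),
        "notes": notes,
    }
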
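"""Proteome and domain-hit handling.

Reads proteome FASTA files and profile-HMM hit tables (HMMER per-domain
tabular output, "domtblout"), applies the pipeline's hit filtering
(independent E-value threshold, overlap resolution by lowest independent
E-value) and assembles ordered LIM-domain instances per protein, dropping
insert-state residues so every instance carries a fixed-width match-state
string.

Coordinates are 1-based inclusive everywhere (the HMMER convention); the
envelope interval encloses the alignment interval. Every filtering stage
returns a :class:`FilterReport` so that input hits are conserved:
``|input| == |retained| + |discarded|``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SearchIO, SeqIO

__all__ = [
    "ProteinRecord",
    "DomainHit",
    "LimDomainInstance",
    "FilterReport",
    "read_fasta",
    "read_domtblout",
    "write_domtblout",
    "write_hits_tsv",
    "select_representative_isoforms",
    "filter_hits",
    "resolve_overlaps",
    "assemble_lim_instances",
    "live_scan",
    "DEFAULT_ZINC_POSITIONS",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
_ID_RE = re.compile(r"^[A-Z][a-z]_")

#: Match-state columns (1-based) holding the eight zinc-coordinating
#: residues of the canonical LIM domain under the default 55-column model.
#: The final two correspond to the ultra-conserved cysteine at position 50
#: and the C/D/H at position 53; configurable for other models.
DEFAULT_ZINC_POSITIONS = (1, 4, 24, 27, 30, 33, 50, 53)
ZINC_RESIDUES = frozenset("CHDE")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence, named ``<2-letter species>_<accession>``."""

    id: str
    species: str
    sequence: str
    source_accession: str = ""
    representative_isoform: bool = True

    def __post_init__(self) -> None:
        if not _ID_RE.match(self.id):
            raise ValueError(
                f"protein id {self.id!r} must start with a two-letter "
                "species prefix and underscore (e.g. 'Hs_LASP1')"
            )
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id}")
        bad = set(self.sequence.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: non-amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gene_key(self) -> str:
        """Gene identifier shared by isoforms: the id up to the last hyphen
        (isoforms are named ``<gene>-<isoform>``)."""
        base, sep, _ = self.id.rpartition("-")
        return base if sep else self.id


@dataclass(frozen=True)
class DomainHit:
    """One profile-model match on a protein.

    ``independent_evalue`` is the per-domain significance treated as if the
    domain were the only hit in the sequence; ``env_*`` is the envelope,
    ``ali_*`` the alignment interval (1-based inclusive,
    env_start <= ali_start <= ali_end <= env_end).
    """

    protein_id: str
    model: str
    env_start: int
    env_end: int
    ali_start: int
    ali_end: int
    independent_evalue: float
    score: float = 0.0
    aligned_match_string: str = ""

    def __post_init__(self) -> None:
        if not (
            1 <= self.env_start <= self.ali_start <= self.ali_end <= self.env_end
        ):
            raise ValueError(
                f"{self.protein_id}/{self.model}: invalid coordinates "
                f"env {self.env_start}-{self.env_end}, "
                f"ali {self.ali_start}-{self.ali_end}"
            )

    def overlaps(self, other: "DomainHit") -> bool:
        """Envelope intervals share at least one residue."""
        return (
            self.env_start <= other.env_end and other.env_start <= self.env_end
        )


@dataclass(frozen=True)
class LimDomainInstance:
    """An accepted LIM domain: ordinal letter in amino-to-carboxyl order and
    a fixed-width aligned match-state string (upper-case residues and '-')."""

    protein_id: str
    ordinal: str
    env_start: int
    env_end: int
    ali_start: int
    ali_end: int
    independent_evalue: float
    aligned_match_string: str
    homology_group: int | None = None

    @property
    def label(self) -> str:
        """Leaf label used in gene trees, e.g. ``Hs_ABLIM2.B``."""
        return f"{self.protein_id}.{self.ordinal}"


@dataclass
class FilterReport:
    """Record of everything a filtering stage discarded, with a reason in
    {evalue, overlap, truncated, zinc_finger_mispredict,
    nonrepresentative_isoform}."""

    discarded: list[tuple[str, str]] = field(default_factory=list)

    VALID_REASONS = frozenset(
        {
            "evalue",
            "overlap",
            "truncated",
            "zinc_finger_mispredict",
            "nonrepresentative_isoform",
        }
    )

    def add(self, item_id: str, reason: str) -> None:
        if reason not in self.VALID_REASONS:
            raise ValueError(f"unknown discard reason {reason!r}")
        self.discarded.append((item_id, reason))

    def __len__(self) -> int:
        return len(self.discarded)


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta(path: str, species_from_id: bool = True) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        species = rec.id[:2] if species_from_id else ""
        records.append(
            ProteinRecord(
                id=rec.id,
                species=species,
                sequence=str(rec.seq).upper(),
                source_accession=rec.description.split(" ", 1)[-1]
                if " " in rec.description
                else rec.id,
            )
        )
    return records


def read_domtblout(path: str) -> list[DomainHit]:
    """Read a HMMER3 per-domain table (``hmmsearch --domtblout`` style)."""
    hits: list[DomainHit] = []
    with open(path) as handle:
        for query in SearchIO.parse(handle, "hmmsearch3-domtab"):
            for hit in query:
                for hsp in hit:
                    hits.append(
                        DomainHit(
                            protein_id=hit.id,
                            model=query.id,
                            env_start=hsp.env_start + 1,
                            env_end=hsp.env_end,
                            ali_start=hsp.hit_start + 1,
                            ali_end=hsp.hit_end,
                            independent_evalue=float(hsp.evalue),
                            score=float(hsp.bitscore),
                        )
                    )
    return hits


_DOMTBL_HEADER = (
    "# target name        accession   tlen query name           accession"
    "   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias"
    "  from    to  from    to  from    to  acc description of target\n"
)


def write_domtblout(
    hits: Sequence[DomainHit],
    path: str,
    protein_lengths: dict[str, int] | None = None,
    model_lengths: dict[str, int] | None = None,
) -> None:
    """Write hits in hmmsearch ``--domtblout`` column layout."""
    protein_lengths = protein_lengths or {}
    model_lengths = model_lengths or {}
    by_protein_model: dict[tuple[str, str], list[DomainHit]] = {}
    for h in hits:
        by_protein_model.setdefault((h.protein_id, h.model), []).append(h)
    with open(path, "w") as out:
        out.write(_DOMTBL_HEADER)
        for (pid, model), group in by_protein_model.items():
            group = sorted(group, key=lambda h: h.env_start)
            total = len(group)
            for i, h in enumerate(group, start=1):
                qlen = model_lengths.get(model, len(h.aligned_match_string) or 0)
                out.write(
                    f"{pid:<20s} -          {protein_lengths.get(pid, 0):>5d} "
                    f"{model:<20s} -          {qlen:>5d} "
                    f"{h.independent_evalue:>9.2g} {h.score:>6.1f} {0.0:>5.1f} "
                    f"{i:>3d} {total:>3d} "
                    f"{h.independent_evalue:>9.2g} {h.independent_evalue:>9.2g} "
                    f"{h.score:>6.1f} {0.0:>5.1f} "
                    f"{1:>5d} {max(qlen, 1):>5d} "
                    f"{h.ali_start:>5d} {h.ali_end:>5d} "
                    f"{h.env_start:>5d} {h.env_end:>5d} 0.99 -\n"
                )


def write_hits_tsv(hits: Sequence[DomainHit], path: str) -> None:
    """TSV of retained hits; coordinates 1-based inclusive."""
    with open(path, "w") as out:
        out.write(
            "protein_id\tmodel\tenv_start\tenv_end\tali_start\tali_end"
            "\tindependent_evalue\tscore\n"
        )
        for h in sorted(hits, key=lambda h: (h.protein_id, h.env_start)):
            out.write(
                f"{h.protein_id}\t{h.model}\t{h.env_start}\t{h.env_end}"
                f"\t{h.ali_start}\t{h.ali_end}\t{h.independent_evalue:g}"
                f"\t{h.score:g}\n"
            )


# ---------------------------------------------------------------------------
# filtering


def select_representative_isoforms(
    records: Sequence[ProteinRecord], policy: str = "longest"
) -> tuple[list[ProteinRecord], FilterReport]:
    """Keep one record per gene.

    ``policy='longest'`` keeps the longest isoform (ties: lexicographically
    smallest id, so the result is independent of input order);
    ``policy='named'`` keeps the isoform flagged ``representative_isoform``
    (falling back to 'longest' within genes that have no flagged record).
    """
    if policy not in ("longest", "named"):
        raise ValueError("policy must be 'longest' or 'named'")
    by_gene: dict[str, list[ProteinRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_key, []).append(rec)
    kept: list[ProteinRecord] = []
    report = FilterReport()
    for gene in sorted(by_gene):
        group = by_gene[gene]
        if policy == "named" and any(r.representative_isoform for r in group):
            candidates = [r for r in group if r.representative_isoform]
        else:
            candidates = group
        winner = max(candidates, key=lambda r: (len(r.sequence), r.id))
        # ties on length: smallest id wins
        best_len = len(winner.sequence)
        winner = min(
            (r for r in candidates if len(r.sequence) == best_len),
            key=lambda r: r.id,
        )
        kept.append(winner)
        for r in group:
            if r is not winner:
                report.add(r.id, "nonrepresentative_isoform")
    return kept, report


def filter_hits(
    hits: Sequence[DomainHit], ie_max: float = 0.05
) -> tuple[list[DomainHit], FilterReport]:
    """Exclude hits whose independent E-value is above ``ie_max``.

    A hit exactly at the threshold is retained. Negative E-values mark the
    input as malformed.
    """
    report = FilterReport()
    retained: list[DomainHit] = []
    for h in hits:
        if h.independent_evalue < 0:
            raise ValueError(
                f"{h.protein_id}/{h.model}: negative independent E-value"
            )
        if h.independent_evalue <= ie_max:
            retained.append(h)
        else:
            report.add(f"{h.protein_id}:{h.env_start}-{h.env_end}", "evalue")
    return retained, report


def resolve_overlaps(
    hits: Sequence[DomainHit],
) -> tuple[list[DomainHit], FilterReport]:
    """Resolve overlapping domain envelopes on one protein.

    Within each maximal cluster of mutually chained overlaps, hits are
    selected greedily in ascending independent E-value (ties: lower
    env_start, then model name); every hit overlapping a selected one is
    dropped. The outcome is independent of input order.
    """
    report = FilterReport()
    pids = {h.protein_id for h in hits}
    if len(pids) > 1:
        raise ValueError("resolve_overlaps expects hits from a single protein")
    remaining = sorted(
        hits, key=lambda h: (h.independent_evalue, h.env_start, h.model)
    )
    retained: list[DomainHit] = []
    while remaining:
        best = remaining.pop(0)
        retained.append(best)
        still = []
        for h in remaining:
            if h.overlaps(best):
                report.add(f"{h.protein_id}:{h.env_start}-{h.env_end}", "overlap")
            else:
                still.append(h)
        remaining = still
    retained.sort(key=lambda h: h.env_start)
    return retained, report


def _match_columns(aligned: str) -> str:
    """Drop insert-state (lower-case) characters, keeping match-state
    residues (upper-case) and deletion columns ('-')."""
    return "".join(c for c in aligned if not c.islower())


def assemble_lim_instances(
    protein: ProteinRecord,
    hits: Sequence[DomainHit],
    lim_model: str = "LIM",
    max_deletion_fraction: float = 0.5,
    zinc_positions: Sequence[int] | None = DEFAULT_ZINC_POSITIONS,
    min_zinc_occupied: int = 6,
) -> tuple[list[LimDomainInstance], FilterReport]:
    """Turn accepted LIM hits into ordered LIM-domain instances.

    Insert-state residues are removed from each hit's aligned string so all
    instances share the model's match-state width. Hits whose match string
    is more than ``max_deletion_fraction`` deletion columns are discarded as
    truncated; hits occupying fewer than ``min_zinc_occupied`` of the
    canonical zinc-coordinating positions with C/H/D/E are discarded as
    mispredicted zinc fingers (set ``zinc_positions=None`` to disable).
    Carboxy-terminal incompleteness below the truncation threshold is
    tolerated as-is — missing columns are never imputed.
    """
    report = FilterReport()
    lim_hits = [h for h in hits if h.model == lim_model]
    widths = {
        len(_match_columns(h.aligned_match_string))
        for h in lim_hits
        if h.aligned_match_string
    }
    if len(widths) > 1:
        raise ValueError(
            f"{protein.id}: inconsistent match-state widths {sorted(widths)} "
            "(hits from different HMMs?)"
        )
    accepted: list[DomainHit] = []
    matches: dict[int, str] = {}
    for idx, h in enumerate(sorted(lim_hits, key=lambda h: h.env_start)):
        if h.env_end > len(protein):
            raise ValueError(
                f"{protein.id}: hit envelope {h.env_start}-{h.env_end} "
                f"exceeds protein length {len(protein)}"
            )
        m = _match_columns(h.aligned_match_string)
        if m:
            if m.count("-") / len(m) > max_deletion_fraction:
                report.add(f"{protein.id}:{h.env_start}-{h.env_end}", "truncated")
                continue
            # the zinc check needs a match string wide enough to cover the
            # canonical coordinating positions (narrow custom models skip it)
            if zinc_positions is not None and len(m) >= max(zinc_positions):
                occupied = sum(
                    1 for pos in zinc_positions if m[pos - 1] in ZINC_RESIDUES
                )
                if occupied < min_zinc_occupied:
                    report.add(
                        f"{protein.id}:{h.env_start}-{h.env_end}",
                        "zinc_finger_mispredict",
                    )
                    continue
        matches[len(accepted)] = m
        accepted.append(h)
    instances = []
    for i, h in enumerate(accepted):
        if i >= 26:
            raise ValueError(f"{protein.id}: more than 26 LIM domains")
        instances.append(
            LimDomainInstance(
                protein_id=protein.id,
                ordinal=chr(ord("A") + i),
                env_start=h.env_start,
                env_end=h.env_end,
                ali_start=h.ali_start,
                ali_end=h.ali_end,
                independent_evalue=h.independent_evalue,
                aligned_match_string=matches[i],
            )
        )
    return instances, report


# ---------------------------------------------------------------------------
# live scanning


def live_scan(
    fasta_path: str,
    hmm_path: str | None = None,
    backend: str = "external",
    table_path: str | None = None,
) -> list[DomainHit]:
    """Produce domain hits either by running a profile-HMM search or by
    parsing a pre-computed per-domain table.

    ``backend='external'`` runs an in-process HMMER search (pyhmmer) of
    ``hmm_path`` against the proteome with default settings;
    ``backend='none'`` parses ``table_path`` instead. Both paths yield the
    same :class:`DomainHit` schema.
    """
    if backend == "none":
        if table_path is None:
            raise ValueError(
                "backend='none' requires a pre-computed domain table "
                "(table_path)"
            )
        return read_domtblout(table_path)
    if backend != "external":
        raise ValueError("backend must be 'external' or 'none'")
    if hmm_path is None:
        raise ValueError("backend='external' requires an HMM file (hmm_path)")
    try:
        import pyhmmer
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise RuntimeError(
            "live scanning requires the pyhmmer package; install it or "
            "supply a pre-computed domain table with backend='none'"
        ) from exc

    alphabet = pyhmmer.easel.Alphabet.amino()
    with pyhmmer.plan7.HMMFile(hmm_path) as hf:
        hmms = list(hf)
    with pyhmmer.easel.SequenceFile(
        fasta_path, digital=True, alphabet=alphabet
    ) as sf:
        seqs = sf.read_block()
    def _text(value) -> str:
        return value.decode() if isinstance(value, bytes) else str(value)

    hits: list[DomainHit] = []
    for tophits in pyhmmer.hmmer.hmmsearch(hmms, seqs):
        model = _text(tophits.query.name)
        for hit in tophits:
            for dom in hit.domains.reported:
                ali = dom.alignment
                hits.append(
                    DomainHit(
                        protein_id=_text(hit.name),
                        model=model,
                        env_start=dom.env_from,
                        env_end=dom.env_to,
                        ali_start=ali.target_from,
                        ali_end=ali.target_to,
                        independent_evalue=dom.i_evalue,
                        score=dom.score,
                        aligned_match_string=ali.target_sequence,
                    )
                )
    hits.sort(key=lambda h: (h.protein_id, h.env_start, h.model))
    return hits
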
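"""Masked iterative motif discovery and regex-based motif scanning.

The discovery protocol: low-complexity regions and significant domain hits
are masked out of every protein, a single-motif finder is run on the masked
set, each accepted motif (E-value at or below the stopping threshold, at
least ``min_sites`` supporting proteins) is masked in turn, and the loop
repeats until the first rejected motif. A final pass over the *unmasked*
sequences may add occurrences of already-accepted motifs that were hidden
under a mask, but never introduces new motifs.

The builtin finder is a deterministic ZOOPS ("zero or one occurrence per
sequence") expectation-maximization over a position weight matrix, with an
approximate significance model, so the protocol can run without any
third-party discovery binary; an external finder can be plugged in as any
callable with the same signature. Masked residues are 'X' and are never
matched by either finder.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MaskedSequence",
    "MotifOccurrence",
    "MotifDefinition",
    "mask_domains",
    "mask_low_complexity",
    "builtin_finder",
    "iterative_discovery",
    "unmasked_extension_pass",
    "scan_regex",
    "regex_to_pattern",
]

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {c: i for i, c in enumerate(AA)}

MASK_PROVENANCES = ("low_complexity", "pfam_domain", "discovered_motif", "none")


@dataclass
class MaskedSequence:
    """A protein sequence with masked positions replaced by 'X'.

    ``provenance[i]`` records why position i is masked (or 'none'); masking
    never changes sequence length.
    """

    protein_id: str
    sequence: str
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = [
                "none" if c != "X" else "low_complexity" for c in self.sequence
            ]
        if len(self.provenance) != len(self.sequence):
            raise ValueError("provenance must cover every position")

    @classmethod
    def from_plain(cls, protein_id: str, sequence: str) -> "MaskedSequence":
        return cls(protein_id, sequence, ["none"] * len(sequence))

    def mask(self, start: int, end: int, provenance: str) -> None:
        """Mask 1-based inclusive interval [start, end]."""
        if provenance not in MASK_PROVENANCES:
            raise ValueError(f"unknown mask provenance {provenance!r}")
        if start < 1 or end > len(self.sequence) or start > end:
            raise ValueError(
                f"{self.protein_id}: mask interval {start}-{end} out of "
                f"range for length {len(self.sequence)}"
            )
        seq = list(self.sequence)
        for i in range(start - 1, end):
            if seq[i] != "X":
                seq[i] = "X"
                self.provenance[i] = provenance
        self.sequence = "".join(seq)

    def copy(self) -> "MaskedSequence":
        return MaskedSequence(
            self.protein_id, self.sequence, list(self.provenance)
        )

    @property
    def n_masked(self) -> int:
        return self.sequence.count("X")


@dataclass(frozen=True)
class MotifOccurrence:
    """One motif match; coordinates 1-based inclusive; ``source`` says
    whether it came from de novo discovery or a regex scan."""

    protein_id: str
    motif: str
    start: int
    end: int
    source: str = "discovery"

    def __post_init__(self) -> None:
        if self.source not in ("discovery", "regex"):
            raise ValueError(f"invalid occurrence source {self.source!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.protein_id}/{self.motif}: bad interval "
                f"{self.start}-{self.end}"
            )


@dataclass
class MotifDefinition:
    """A discovered or curated motif: width, significance, a regular
    expression that matches every recorded occurrence, and the occurrence
    list itself."""

    name: str
    width: int
    evalue: float
    regex: str
    occurrences: list[MotifOccurrence] = field(default_factory=list)
    extended_by_unmasked_pass: bool = False

    def __post_init__(self) -> None:
        if self.width < 4:
            raise ValueError("motif width must be >= 4")


# ---------------------------------------------------------------------------
# masking


def mask_domains(
    seqs: Sequence[MaskedSequence],
    hits: Iterable,
    e_max: float = 0.05,
) -> list[MaskedSequence]:
    """Mask every residue inside a qualifying domain envelope.

    ``hits`` are :class:`~limclass.annotation.DomainHit` objects; only hits
    with independent E-value at or below ``e_max`` qualify. Overlapping
    envelopes mask their union once.
    """
    by_protein: dict[str, list] = {}
    for h in hits:
        if h.independent_evalue <= e_max:
            by_protein.setdefault(h.protein_id, []).append(h)
    out = []
    for seq in seqs:
        masked = seq.copy()
        for h in by_protein.get(seq.protein_id, ()):
            masked.mask(h.env_start, h.env_end, "pfam_domain")
        out.append(masked)
    return out


def shannon_entropy(counts: Mapping[str, int]) -> float:
    total = sum(counts.values())
    if total == 0:
        return 0.0
    ent = 0.0
    for c in counts.values():
        if c:
            p = c / total
            ent -= p * math.log2(p)
    return ent


def mask_low_complexity(
    seqs: Sequence[MaskedSequence],
    backend: str = "builtin",
    window: int = 10,
    entropy_threshold: float = 1.5,
    external: Callable[[str], str] | None = None,
) -> list[MaskedSequence]:
    """Mask low-complexity / tandem-repeat regions.

    The builtin heuristic slides a window and masks any window whose Shannon
    entropy (bits) falls below the threshold — homopolymers and short tandem
    repeats score near zero, while random 20-letter windows sit around 3
    bits. ``backend='external'`` delegates to a user-supplied callable that
    returns the sequence with masked positions lower-cased or 'X'-ed.
    """
    if backend not in ("builtin", "external"):
        raise ValueError("backend must be 'builtin' or 'external'")
    if backend == "external":
        if external is None:
            raise ValueError("backend='external' requires the masker callable")
        out = []
        for seq in seqs:
            masked = seq.copy()
            result = external(seq.sequence)
            if len(result) != len(seq.sequence):
                raise ValueError("external masker changed sequence length")
            for i, (orig, new) in enumerate(zip(seq.sequence, result)):
                if new == "X" or (new.islower() and orig.isupper()):
                    masked.mask(i + 1, i + 1, "low_complexity")
            out.append(masked)
        return out

    out = []
    for seq in seqs:
        masked = seq.copy()
        s = seq.sequence
        to_mask: list[int] = []
        for start in range(0, max(len(s) - window + 1, 0)):
            win = s[start : start + window]
            if "X" in win:
                continue
            counts: dict[str, int] = {}
            for c in win:
                counts[c] = counts.get(c, 0) + 1
            if shannon_entropy(counts) < entropy_threshold:
                to_mask.extend(range(start, start + window))
        for i in sorted(set(to_mask)):
            masked.mask(i + 1, i + 1, "low_complexity")
        out.append(masked)
    return out


# ---------------------------------------------------------------------------
# builtin ZOOPS-EM finder


@dataclass
class FinderResult:
    consensus: str
    width: int
    evalue: float
    occurrences: list[MotifOccurrence]
    score: float
    regex: str


def _background(seqs: Sequence[str]) -> np.ndarray:
    counts = np.ones(20)
    for s in seqs:
        for c in s:
            i = AA_INDEX.get(c)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()


def _all_window_llrs(idx: np.ndarray, w: int, log_odds: np.ndarray) -> np.ndarray:
    """Log-likelihood ratio of every length-w window; -inf where a window
    contains a masked ('X') position."""
    m = len(idx) - w + 1
    if m < 1:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    safe = np.where(windows >= 0, windows, 0)
    llrs = log_odds[np.arange(w)[None, :], safe].sum(axis=1)
    llrs[(windows < 0).any(axis=1)] = -np.inf
    return llrs


def _em_zoops(
    seq_idx: list[np.ndarray],
    w: int,
    seed_window: np.ndarray,
    bg: np.ndarray,
    n_iter: int = 15,
) -> tuple[np.ndarray, float]:
    """Run ZOOPS EM from a seed window; returns (PWM, gamma)."""
    pwm = np.full((w, 20), 0.5 / 19)
    pwm[np.arange(w), seed_window] = 0.5
    gamma = 0.5
    log_bg = np.log(bg)
    for _ in range(n_iter):
        log_odds = np.log(pwm) - log_bg[None, :]
        counts = np.full((w, 20), 0.25)  # pseudocounts
        z_total = 0.0
        n_seq = 0
        for idx in seq_idx:
            llrs = _all_window_llrs(idx, w, log_odds)
            m = len(llrs)
            if m < 1:
                continue
            n_seq += 1
            finite = np.isfinite(llrs)
            if not finite.any():
                continue
            top = llrs[finite].max()
            ratios = np.zeros(m)
            ratios[finite] = np.exp(llrs[finite] - top)
            scale = math.exp(min(top, 700))
            prior = gamma / m
            num = prior * ratios * scale
            denom = (1 - gamma) + num.sum()
            post = num / denom
            z_total += post.sum()
            windows = np.lib.stride_tricks.sliding_window_view(idx, w)
            use = np.nonzero(post > 1e-6)[0]
            if len(use):
                np.add.at(
                    counts,
                    (np.arange(w)[None, :], np.where(windows[use] >= 0, windows[use], 0)),
                    post[use][:, None],
                )
        pwm = counts / counts.sum(axis=1, keepdims=True)
        gamma = min(max(z_total / max(n_seq, 1), 0.05), 0.95)
    return pwm, gamma


def _regex_from_occurrences(substrings: Sequence[str]) -> str:
    """Build a regex (over the 20-letter alphabet with 'x' wildcard plus
    character classes) matching every occurrence substring."""
    cols = list(zip(*substrings))
    parts = []
    for col in cols:
        residues = sorted(set(col))
        if len(residues) == 1:
            parts.append(residues[0])
        elif len(residues) <= 4:
            parts.append("[" + "".join(residues) + "]")
        else:
            parts.append("x")
    return "".join(parts)


def builtin_finder(
    seqs: Sequence[MaskedSequence],
    width_range: tuple[int, int] = (6, 30),
    min_sites: int = 4,
    seed: int = 0,
) -> FinderResult | None:
    """Report the best single motif over the width range, or ``None``.

    Deterministic under a fixed seed: EM is started from a seeded sample of
    candidate windows for each width and the restart with the best adjusted
    score wins. The significance approximation penalizes the summed site
    log-likelihood ratio by the per-site alignment multiplicity and a
    BIC-style model-complexity term, then converts to an E-value against
    the total number of scanned windows.
    """
    rng = np.random.default_rng(seed)
    strings = [s.sequence for s in seqs]
    seq_idx = [
        np.array([AA_INDEX.get(c, -1) for c in s], dtype=int) for s in strings
    ]
    bg = _background(strings)
    wmin, wmax = width_range
    widths = sorted({w for w in range(wmin, wmax + 1, 3)} | {wmin, wmax})

    best: FinderResult | None = None
    for w in widths:
        # candidate seed windows: X-free windows sampled deterministically
        candidates: list[np.ndarray] = []
        order = rng.permutation(len(seq_idx))
        for si in order:
            idx = seq_idx[si]
            m = len(idx) - w + 1
            if m < 1:
                continue
            starts = rng.permutation(m)[: max(1, m // 10)]
            for j in starts:
                win = idx[j : j + w]
                if (win >= 0).all():
                    candidates.append(win)
                    break
            if len(candidates) >= 6:
                break
        if not candidates:
            continue
        usable = sum(1 for idx in seq_idx if len(idx) >= w)
        if usable < min_sites:
            continue
        for seed_win in candidates:
            pwm, _ = _em_zoops(seq_idx, w, seed_win, bg)
            result = _score_pwm(seqs, seq_idx, pwm, bg, w, min_sites)
            if result is not None and (best is None or result.score > best.score):
                best = result
    return best


def _score_pwm(
    seqs: Sequence[MaskedSequence],
    seq_idx: list[np.ndarray],
    pwm: np.ndarray,
    bg: np.ndarray,
    w: int,
    min_sites: int,
) -> FinderResult | None:
    log_odds = np.log(pwm) - np.log(bg)[None, :]
    occs: list[tuple[int, int, float]] = []  # (seq index, start, llr)
    total_positions = 0
    for si, idx in enumerate(seq_idx):
        m = len(idx) - w + 1
        if m < 1:
            continue
        total_positions += m
        llrs = _all_window_llrs(idx, w, log_odds)
        j_best = int(np.argmax(llrs))
        if np.isfinite(llrs[j_best]) and llrs[j_best] > 0:
            occs.append((si, j_best, float(llrs[j_best]) - math.log(m)))
    occs.sort(key=lambda t: -t[2])
    # keep sites contributing positive multiplicity-corrected LLR
    kept = [o for o in occs if o[2] > 0]
    if len(kept) < min_sites:
        return None
    n = len(kept)
    raw = sum(o[2] for o in kept)
    # Model-complexity correction: fitting 19 free frequencies per column
    # inflates the total log-likelihood ratio by about 19/2 nats per column
    # (likelihood-ratio asymptotics), on top of the per-site log(m)
    # alignment-multiplicity term already subtracted above. The extra
    # per-site term absorbs the selection of the best-scoring site subset.
    penalty = 0.5 * 19 * w + 2.0 * n
    score = raw - penalty
    evalue = max(total_positions, 1) * math.exp(-min(score, 700))
    substrings = [
        seqs[si].sequence[j : j + w] for si, j, _ in kept
    ]
    consensus = "".join(AA[int(c)] for c in pwm.argmax(axis=1))
    occurrences = [
        MotifOccurrence(
            protein_id=seqs[si].protein_id,
            motif="",
            start=j + 1,
            end=j + w,
            source="discovery",
        )
        for si, j, _ in kept
    ]
    return FinderResult(
        consensus=consensus,
        width=w,
        evalue=evalue,
        occurrences=occurrences,
        score=score,
        regex=_regex_from_occurrences(substrings),
    )


# ---------------------------------------------------------------------------
# the iterative protocol


def iterative_discovery(
    seqs: Sequence[MaskedSequence],
    finder: Callable[..., FinderResult | None] | None = None,
    min_sites: int = 4,
    e_stop: float = 0.01,
    max_iterations: int = 50,
    seed: int = 0,
    name_prefix: str = "motif",
) -> tuple[list[MotifDefinition], list[MaskedSequence]]:
    """Mask-discover-repeat until the first rejected motif.

    Each accepted motif (E-value <= ``e_stop`` with at least ``min_sites``
    sites) is masked with provenance ``discovered_motif`` before the next
    round. Returns accepted motifs in discovery order together with the
    final masked sequences.
    """
    working = [s.copy() for s in seqs]
    motifs: list[MotifDefinition] = []
    find = finder or builtin_finder
    for iteration in range(max_iterations):
        result = find(working, min_sites=min_sites, seed=seed + iteration)
        if result is None or result.evalue > e_stop:
            break
        name = f"{name_prefix}_{len(motifs) + 1}"
        occurrences = [replace(o, motif=name) for o in result.occurrences]
        motifs.append(
            MotifDefinition(
                name=name,
                width=result.width,
                evalue=result.evalue,
                regex=result.regex,
                occurrences=occurrences,
            )
        )
        by_protein = {s.protein_id: s for s in working}
        for occ in occurrences:
            by_protein[occ.protein_id].mask(
                occ.start, occ.end, "discovered_motif"
            )
    return motifs, working


def unmasked_extension_pass(
    unmasked: Sequence[MaskedSequence],
    motifs: Sequence[MotifDefinition],
) -> list[MotifDefinition]:
    """Recover occurrences of *existing* motifs hidden under masks.

    Each motif's regex is re-scanned against the unmasked sequences; newly
    found, non-overlapping occurrences are appended and the motif flagged
    as extended. No new motifs are introduced.
    """
    out: list[MotifDefinition] = []
    for motif in motifs:
        extended = MotifDefinition(
            name=motif.name,
            width=motif.width,
            evalue=motif.evalue,
            regex=motif.regex,
            occurrences=list(motif.occurrences),
            extended_by_unmasked_pass=motif.extended_by_unmasked_pass,
        )
        pattern = re.compile(regex_to_pattern(motif.regex))
        existing = {
            (o.protein_id, o.start, o.end) for o in extended.occurrences
        }
        spans = {}
        for o in extended.occurrences:
            spans.setdefault(o.protein_id, []).append((o.start, o.end))
        added = False
        for seq in unmasked:
            for m in pattern.finditer(seq.sequence):
                start, end = m.start() + 1, m.end()
                if (seq.protein_id, start, end) in existing:
                    continue
                if any(
                    start <= e and s <= end
                    for s, e in spans.get(seq.protein_id, ())
                ):
                    continue
                extended.occurrences.append(
                    MotifOccurrence(
                        protein_id=seq.protein_id,
                        motif=motif.name,
                        start=start,
                        end=end,
                        source="regex",
                    )
                )
                spans.setdefault(seq.protein_id, []).append((start, end))
                added = True
        if added:
            extended.extended_by_unmasked_pass = True
        out.append(extended)
    return out


# ---------------------------------------------------------------------------
# regex scanning


_REGEX_TOKEN = re.compile(r"[A-Z]|x|\[[A-Z]+\]")


def regex_to_pattern(motif_regex: str) -> str:
    """Translate a motif regex over the 20-letter alphabet with 'x'
    wildcards and character classes into a Python re pattern."""
    pos = 0
    parts = []
    for m in _REGEX_TOKEN.finditer(motif_regex):
        if m.start() != pos:
            raise ValueError(
                f"malformed motif regex {motif_regex!r} at offset {pos}"
            )
        tok = m.group()
        if tok == "x":
            parts.append("[ACDEFGHIKLMNPQRSTVWY]")
        else:
            for c in tok.strip("[]"):
                if c not in AA_INDEX:
                    raise ValueError(
                        f"motif regex {motif_regex!r}: {c!r} is not one of "
                        "the 20 amino acids"
                    )
            parts.append(tok)
        pos = m.end()
    if pos != len(motif_regex):
        raise ValueError(
            f"malformed motif regex {motif_regex!r} at offset {pos}"
        )
    return "".join(parts)


def scan_regex(
    seqs: Sequence[MaskedSequence],
    regexes: Mapping[str, str],
) -> list[MotifOccurrence]:
    """All left-to-right non-overlapping matches of each named regex."""
    occurrences: list[MotifOccurrence] = []
    compiled = {
        name: re.compile(regex_to_pattern(rx)) for name, rx in regexes.items()
    }
    for seq in seqs:
        for name in sorted(compiled):
            for m in compiled[name].finditer(seq.sequence):
                occurrences.append(
                    MotifOccurrence(
                        protein_id=seq.protein_id,
                        motif=name,
                        start=m.start() + 1,
                        end=m.end(),
                        source="regex",
                    )
                )
    return occurrences
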
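"""Genome scanning for GacA upstream activating sequence (UAS) boxes.

The response regulator GacA activates transcription of Rsm small RNA genes
through a conserved palindromic upstream activating sequence.  This module
locates UAS boxes in genomic sequence by a mismatch-tolerant scan on both
strands, calls downstream sRNA candidate loci using a Rho-independent
terminator heuristic, and detects tandem-duplicated candidate pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_UAS = "TATAGCGAAACGCTTACA"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GENOME_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide contig; coordinates are 0-based on the forward strand."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self):
        if not self.seq:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.seq) - GENOME_ALPHABET
        if bad:
            raise ValueError(f"genome {self.id!r}: illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class UASHit:
    """One UAS box occurrence.

    ``start`` is the 0-based forward-strand offset of the matched window;
    ``matched_seq`` is read on the reported strand, so its Hamming distance
    to the query equals ``mismatches``.
    """

    genome_id: str
    start: int
    strand: str
    matched_seq: str
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + len(self.matched_seq)


@dataclass
class SrnaCandidate:
    """A called sRNA locus: 0-based half-open interval on the forward strand.

    ``seq`` is the strand-resolved genomic subsequence in the DNA alphabet
    (the folding module transliterates T to U).
    """

    genome_id: str
    start: int
    end: int
    strand: str
    seq: str
    uas: UASHit
    terminator_found: bool
    truncated: bool = False
    id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TandemPair:
    a: "SrnaCandidate"
    b: "SrnaCandidate"
    gap: int
    identity: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _mismatch_profile(arr: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Hamming distance of every window of ``arr`` against ``query``."""
    q = len(query)
    n = len(arr) - q + 1
    mm = np.zeros(n, dtype=np.int32)
    for j in range(q):
        mm += arr[j : j + n] != query[j]
    return mm


def scan_uas(
    genome: GenomeSequence,
    query: str = DEFAULT_UAS,
    max_mismatch: int = 3,
) -> list[UASHit]:
    """Scan both strands for windows within ``max_mismatch`` of ``query``.

    Returns every qualifying position (overlaps included), sorted by
    (start, strand) with '+' ordered before '-'.  On circular genomes the
    scan wraps across the origin; wrapped hits report their forward-strand
    start modulo the contig length.
    """
    query = query.upper()
    if set(query) - set("ACGT"):
        raise ValueError("query must be over {A,C,G,T} (no N or other symbols)")
    if max_mismatch > 6:
        raise ValueError("max_mismatch must be <= 6")
    q = len(query)
    if len(genome) < q:
        logger.warning(
            "genome %s (%d nt) shorter than query (%d nt); no scan performed",
            genome.id, len(genome), q,
        )
        return []

    seq = genome.seq
    if genome.circular:
        seq = seq + genome.seq[: q - 1]
    arr = _encode(seq)
    hits: list[UASHit] = []
    for strand, qseq in (("+", query), ("-", reverse_complement(query))):
        mm = _mismatch_profile(arr, _encode(qseq))
        for pos in np.nonzero(mm <= max_mismatch)[0]:
            pos = int(pos)
            window = seq[pos : pos + q]
            matched = window if strand == "+" else reverse_complement(window)
            hits.append(
                UASHit(genome.id, pos % len(genome), strand, matched, int(mm[pos]))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# --- Rho-independent terminator heuristic -------------------------------

@dataclass(frozen=True)
class TerminatorParams:
    """Heuristic for Rho-independent terminators: a hairpin stem followed by
    a U-tract (>= ``min_u`` T's within the next ``u_window`` nt)."""

    min_stem: int = 4
    max_stem: int = 12
    min_loop: int = 3
    max_loop: int = 10
    min_u: int = 4
    u_window: int = 8


def _find_terminator(seq: str, params: TerminatorParams) -> Optional[int]:
    """Return the end offset (exclusive) of the first terminator U-tract in
    ``seq``, or None.  ``seq`` is the DNA-sense candidate region."""
    n = len(seq)
    for i in range(n):
        for stem in range(params.max_stem, params.min_stem - 1, -1):
            for loop in range(params.min_loop, params.max_loop + 1):
                j = i + stem + loop  # start of the 3' arm
                end3 = j + stem
                if end3 > n:
                    continue
                arm5 = seq[i : i + stem]
                arm3 = seq[j:end3]
                if reverse_complement(arm5) != arm3:
                    continue
                window = seq[end3 : end3 + params.u_window]
                if window.count("T") >= params.min_u:
                    last_t = max(k for k, c in enumerate(window) if c == "T")
                    return end3 + last_t + 1
    return None


def call_candidates(
    genome: GenomeSequence,
    hits: list[UASHit],
    window: int = 400,
    default_len: int = 120,
    offset: int = 0,
    term_params: TerminatorParams | None = None,
    id_prefix: str = "srna",
) -> list[SrnaCandidate]:
    """Call one sRNA candidate downstream of each UAS hit.

    The candidate starts ``offset`` nt downstream of the UAS box on the hit
    strand (the promoter spacer between the box and the transcription start).
    Within the next ``window`` nt, the first Rho-independent terminator fixes
    the 3' end; otherwise the candidate is ``default_len`` nt.  Candidates
    running off a linear contig are truncated and flagged; circular genomes
    wrap.
    """
    if window < default_len:
        raise ValueError("window must be >= default_len")
    term_params = term_params or TerminatorParams()
    n = len(genome)
    doubled = genome.seq * 2
    out: list[SrnaCandidate] = []
    for k, hit in enumerate(hits):
        # strand-resolved downstream region, 5'->3' on the hit strand
        if hit.strand == "+":
            gstart = hit.end + offset
            if genome.circular:
                gstart %= n
                region = doubled[gstart : gstart + window]
            else:
                region = genome.seq[gstart : gstart + window]
        else:
            gend = hit.start - offset
            if genome.circular:
                gend %= n
                region = reverse_complement(doubled[gend + n - window : gend + n])
            else:
                region = reverse_complement(genome.seq[max(gend - window, 0) : max(gend, 0)])

        term_end = _find_terminator(region, term_params)
        if term_end is not None:
            length, terminator_found = term_end, True
        else:
            length, terminator_found = default_len, False
        truncated = False
        if length > len(region):
            length = len(region)
            truncated = True
        if length <= 0:
            continue
        seq = region[:length]

        if hit.strand == "+":
            start = gstart
            end = (start + length) % n if genome.circular and start + length > n else start + length
        else:
            end = gend
            start = (end - length) % n if genome.circular and end - length < 0 else end - length
        out.append(
            SrnaCandidate(
                genome_id=genome.id,
                start=start,
                end=end,
                strand=hit.strand,
                seq=seq,
                uas=hit,
                terminator_found=terminator_found,
                truncated=truncated,
                id=f"{id_prefix}_{k + 1}",
            )
        )
    return out


def detect_tandem(
    cands: list[SrnaCandidate],
    max_gap: int = 1000,
    min_identity: float = 0.6,
) -> list[TandemPair]:
    """Report every unordered candidate pair closer than ``max_gap`` nt with
    percent identity >= ``min_identity``, sorted by gap.

    Identity is the global-alignment percent identity of the strand-resolved
    sequences (see :mod:`rsmkit.homology_phylo`).
    """
    from .homology_phylo import global_align

    if len(cands) < 2:
        return []
    pairs: list[TandemPair] = []
    for a, b in combinations(cands, 2):
        if a.genome_id != b.genome_id:
            raise ValueError("tandem detection expects candidates from one genome")
        first, second = (a, b) if a.start <= b.start else (b, a)
        gap = max(0, second.start - first.end)
        if gap > max_gap:
            continue
        identity = global_align(a.seq, b.seq).identity
        if identity >= min_identity:
            pairs.append(TandemPair(first, second, gap, identity))
    pairs.sort(key=lambda p: p.gap)
    return pairs
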
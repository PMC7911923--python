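"""RNA secondary structure and CsrA/RsmA recognition-motif exposure.

Rsm small RNAs sequester CsrA/RsmA-family translational repressors by
presenting (A)NGGA motifs in the single-stranded loops of stem-loop
structures.  This module folds a sequence by base-pair maximization
(Watson-Crick plus GU wobble, nested structures, minimum hairpin loop of
3 nt), imports externally predicted structures in dot-bracket notation,
finds AGGA/ANGGA motifs, and classifies each motif as exposed in a hairpin
loop, unpaired elsewhere, or (partly) paired.

Base-pair maximization is used rather than a thermodynamic model: it is
self-contained and exactly checkable against exhaustive enumeration, and
published structures from thermodynamic folders can be imported via
:func:`parse_dotbracket` when exact reproduction is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

MIN_LOOP = 3

_CAN_PAIR = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

RNA_ALPHABET = frozenset("ACGU")


def to_rna(seq: str) -> str:
    """Uppercase and transliterate T -> U."""
    return seq.upper().replace("T", "U")


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _CAN_PAIR


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested base-pairing of an RNA sequence.

    ``pairs`` holds (i, j) with i < j; pairs are non-crossing, each index
    occurs at most once, and j - i > MIN_LOOP.
    """

    seq: str
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self):
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"sequence contains non-RNA characters {sorted(bad)}")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < len(self.seq)):
                raise ValueError(f"pair ({i},{j}) out of range")
            if j - i <= MIN_LOOP:
                raise ValueError(f"pair ({i},{j}) violates minimum loop size")
            if i in seen or j in seen:
                raise ValueError("an index participates in two pairs")
            seen.update((i, j))
        plist = sorted(self.pairs)
        for a in range(len(plist)):
            i1, j1 = plist[a]
            for b in range(a + 1, len(plist)):
                i2, j2 = plist[b]
                if i1 < i2 < j1 < j2:
                    raise ValueError("crossing base pairs (pseudoknot) not allowed")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def dotbracket(self) -> str:
        db = ["."] * len(self.seq)
        for i, j in self.pairs:
            db[i], db[j] = "(", ")"
        return "".join(db)

    def partner(self) -> list[int | None]:
        """partner[i] = j if (i,j) or (j,i) is a pair, else None."""
        p: list[int | None] = [None] * len(self.seq)
        for i, j in self.pairs:
            p[i], p[j] = j, i
        return p

    def hairpin_loops(self) -> list[tuple[int, int]]:
        """Half-open unpaired intervals each enclosed by exactly one pair.

        A hairpin loop of closing pair (i, j) is the run i+1..j-1 with every
        position unpaired.
        """
        p = self.partner()
        loops = []
        for i, j in sorted(self.pairs):
            if all(p[k] is None for k in range(i + 1, j)):
                loops.append((i + 1, j))
        return loops


def _pair_matrix(seq: str) -> list[list[bool]]:
    n = len(seq)
    return [[can_pair(seq[i], seq[j]) for j in range(n)] for i in range(n)]


def _nussinov_table(seq: str) -> list[list[int]]:
    """best[i][j] = max pairs in seq[i..j] (inclusive), nested, min loop 3."""
    n = len(seq)
    pairable = _pair_matrix(seq)
    best = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            v = best[i + 1][j]  # i unpaired
            for k in range(i + MIN_LOOP + 1, j + 1):
                if pairable[i][k]:
                    inner = best[i + 1][k - 1] if k - 1 > i else 0
                    rest = best[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + inner + rest
                    if cand > v:
                        v = cand
            best[i][j] = v
    return best


def fold_maxpair(seq: str) -> SecondaryStructure:
    """Fold by base-pair maximization with deterministic traceback.

    Among co-optimal structures the traceback pairs the 5'-most free base
    whenever it can participate in an optimal structure, with the smallest
    admissible partner, recursively.
    """
    seq = to_rna(seq)
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - RNA_ALPHABET:
        raise ValueError("sequence must be over {A,C,G,U} (T accepted on input)")
    n = len(seq)
    if n <= MIN_LOOP + 1:
        return SecondaryStructure(seq, frozenset())
    best = _nussinov_table(seq)
    pairable = _pair_matrix(seq)
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= MIN_LOOP:
            continue
        target = best[i][j]
        if target == 0:
            continue
        chosen = None
        for k in range(i + MIN_LOOP + 1, j + 1):
            if not pairable[i][k]:
                continue
            inner = best[i + 1][k - 1] if k - 1 > i else 0
            rest = best[k + 1][j] if k + 1 <= j else 0
            if 1 + inner + rest == target:
                chosen = k
                break
        if chosen is None:
            stack.append((i + 1, j))
        else:
            pairs.append((i, chosen))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
    return SecondaryStructure(seq, frozenset(pairs))


def enumerate_cooptimal(seq: str, cap: int = 50) -> list[SecondaryStructure]:
    """All structures attaining the maximum pair count, up to ``cap``.

    Used to report exposed-motif counts as an interval across co-optimal
    structures, mirroring the ranges published when several folding tools
    (or suboptimal structures) disagree.
    """
    seq = to_rna(seq)
    n = len(seq)
    if n <= MIN_LOOP + 1:
        return [SecondaryStructure(seq, frozenset())]
    best = _nussinov_table(seq)
    pairable = _pair_matrix(seq)

    def rec(i: int, j: int) -> list[frozenset[tuple[int, int]]]:
        if i >= j or j - i <= MIN_LOOP or best[i][j] == 0:
            return [frozenset()]
        target = best[i][j]
        results: list[frozenset[tuple[int, int]]] = []
        if best[i + 1][j] == target:
            results.extend(rec(i + 1, j))
        for k in range(i + MIN_LOOP + 1, j + 1):
            if not pairable[i][k]:
                continue
            inner = best[i + 1][k - 1] if k - 1 > i else 0
            rest = best[k + 1][j] if k + 1 <= j else 0
            if 1 + inner + rest != target:
                continue
            for left in rec(i + 1, k - 1):
                for right in rec(k + 1, j):
                    results.append(left | right | {(i, k)})
                    if len(results) >= cap:
                        break
                if len(results) >= cap:
                    break
            if len(results) >= cap:
                break
        # dedupe while keeping deterministic order
        seen: set[frozenset] = set()
        uniq = []
        for r in results:
            if r not in seen:
                seen.add(r)
                uniq.append(r)
        return uniq[:cap]

    return [SecondaryStructure(seq, p) for p in rec(0, n - 1)[:cap]]


def parse_dotbracket(seq: str, db: str) -> SecondaryStructure:
    """Reconstruct a structure from dot-bracket notation by stack matching."""
    seq = to_rna(seq)
    if len(db) != len(seq):
        raise ValueError("structure and sequence lengths differ")
    if set(db) - set("()."):
        raise ValueError("dot-bracket may only contain '(', ')' and '.'")
    stack: list[int] = []
    pairs = set()
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.add((stack.pop(), i))
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(seq, frozenset(pairs))


# --- motif finding and exposure -----------------------------------------

HAIRPIN_EXPOSED = "hairpin_exposed"
UNPAIRED_NONHAIRPIN = "unpaired_nonhairpin"
PAIRED = "paired"


@dataclass(frozen=True)
class MotifSite:
    start: int
    pattern: str  # "AGGA" or "ANGGA"
    exposure: str | None = None

    @property
    def span(self) -> int:
        return len(self.pattern)

    @property
    def core_start(self) -> int:
        """Start of the GGA core within the parent sequence."""
        return self.start + (1 if self.pattern == "AGGA" else 2)


def find_motifs(seq: str) -> list[MotifSite]:
    """All AGGA and ANGGA occurrences (N = any base), deduplicated.

    An ANGGA whose GGA core coincides with a reported AGGA's core is
    suppressed, so each GGA core is counted once.  Accepts DNA or RNA.
    """
    s = to_rna(seq)
    agga: list[MotifSite] = []
    angga: list[MotifSite] = []
    for i in range(len(s) - 3):
        if s[i] == "A" and s[i + 1 : i + 4] == "GGA":
            agga.append(MotifSite(i, "AGGA"))
    for i in range(len(s) - 4):
        if s[i] == "A" and s[i + 2 : i + 5] == "GGA":
            angga.append(MotifSite(i, "ANGGA"))
    cores = {m.core_start for m in agga}
    sites = agga + [m for m in angga if m.core_start not in cores]
    sites.sort(key=lambda m: (m.start, m.pattern))
    return sites


def classify_exposure(
    struct: SecondaryStructure, sites: list[MotifSite]
) -> list[MotifSite]:
    """Set each site's exposure from the structure.

    hairpin_exposed: every motif base unpaired and inside one hairpin loop;
    unpaired_nonhairpin: all bases unpaired but not within a single hairpin
    loop; paired: at least one base paired.
    """
    partner = struct.partner()
    loops = struct.hairpin_loops()
    out = []
    for site in sites:
        idxs = range(site.start, site.start + site.span)
        if site.start < 0 or site.start + site.span > len(struct.seq):
            raise ValueError(f"motif site at {site.start} out of range")
        if any(partner[k] is not None for k in idxs):
            exposure = PAIRED
        elif any(lo <= site.start and site.start + site.span <= hi for lo, hi in loops):
            exposure = HAIRPIN_EXPOSED
        else:
            exposure = UNPAIRED_NONHAIRPIN
        out.append(MotifSite(site.start, site.pattern, exposure))
    return out


@dataclass(frozen=True)
class MotifSummary:
    n_total: int
    n_exposed: int
    sites: tuple[MotifSite, ...]
    exposed_range: tuple[int, int] | None = None  # across co-optimal structures


def motif_summary(
    seq: str,
    struct: SecondaryStructure | None = None,
    cooptimal_range: bool = False,
    cap: int = 50,
) -> MotifSummary:
    """Count GGA motifs and how many are exposed in hairpin loops.

    With ``cooptimal_range`` the exposed count is additionally reported as a
    (min, max) interval over co-optimal maximum-pair structures (capped).
    """
    rna = to_rna(seq)
    if struct is None:
        struct = fold_maxpair(rna)
    sites = classify_exposure(struct, find_motifs(rna))
    n_exposed = sum(1 for s in sites if s.exposure == HAIRPIN_EXPOSED)
    rng = None
    if cooptimal_range:
        # interval across co-optimal structures; the cap can truncate the
        # enumeration, so the point estimate's own structure is always counted
        counts = [n_exposed]
        for st in enumerate_cooptimal(rna, cap=cap):
            cl = classify_exposure(st, find_motifs(rna))
            counts.append(sum(1 for s in cl if s.exposure == HAIRPIN_EXPOSED))
        rng = (min(counts), max(counts))
    return MotifSummary(len(sites), n_exposed, tuple(sites), rng)
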
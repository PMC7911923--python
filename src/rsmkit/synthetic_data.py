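"""Synthetic genomes, Rsm-like sRNA families and decay time courses.

Every pipeline stage can be exercised against exact ground truth: genomes
with UAS boxes, sRNA genes and terminators planted at known coordinates;
sRNA sequence families with controlled within/between divergence; and
rifampicin-chase qPCR time courses simulated from a known half-life.

Rsm-like templates are constructed, not sampled: stem-loop modules are
assembled so that the base-pair-maximization fold of the full template
exposes exactly the designed number of AGGA motifs in hairpin loops (random
sequences rarely fold predictably).  Construction is verified against the
folding engine at build time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_scan import DEFAULT_UAS, GenomeSequence, reverse_complement
from .structure_motif import HAIRPIN_EXPOSED, find_motifs, motif_summary

BASES = "ACGT"

# Stem-loop modules exposing a single AGGA motif in the terminal loop.  Each
# module exists in two arm "orientations" (G-rich 5' arm vs C-rich 5' arm);
# alternating orientations between neighbouring modules removes most
# count-neutral cross-module pairings, and the assembler searches orientation
# patterns until the full-template fold reproduces the designed exposure.
LOOP_MODULES = ("GGGCAGGAAGCCC", "CCCGAGGAACGGG")
LOOP_MODULES_COMPACT = ("GGGCAGGAGCCC", "CCCGAGGACGGG")
# Modules carrying a single stem-embedded AGGA: the leading A of the motif is
# the last paired base of the stem, the GGA spills into the loop, so at least
# one motif base is paired.
STEM_MODULES = ("GGCAGGAAATGCC", "CCGAGGAAATCGG")
STEM_MODULES_COMPACT = ("GCAGGAATGC", "CGAGGAATCG")
# Rho-independent terminator: palindromic 6-bp stem, 4-nt loop, then a
# U-tract spanning the full 8-nt detection window so the called 3' end does
# not depend on the background sequence that follows.
TERMINATOR = "GCCGGCGAAAGCCGGC" + "TTTTTTTT"
LINKER = "A"
LEADER = "AA"


@dataclass(frozen=True)
class RsmTemplate:
    """A designed Rsm-like sRNA template (DNA sense, terminator excluded).

    ``loop_motifs`` AGGA sites are exposed in hairpin loops of the maximum-
    pair fold and ``stem_motifs`` additional sites are (partly) paired.  The
    Rho-independent terminator is appended by the genome builder, so that the
    motif ground truth of the template itself is exact.
    """

    id: str
    seq: str
    loop_motifs: int
    stem_motifs: int

    @property
    def n_motifs(self) -> int:
        return self.loop_motifs + self.stem_motifs


def _module_order(loop_motifs: int, stem_motifs: int) -> list[str]:
    """Interleave loop- and stem-motif modules ('L'/'S')."""
    order: list[str] = []
    li, si = 0, 0
    for k in range(loop_motifs + stem_motifs):
        if k % 2 == 0 and li < loop_motifs:
            order.append("L")
            li += 1
        elif si < stem_motifs:
            order.append("S")
            si += 1
        else:
            order.append("L")
            li += 1
    return order


def build_template(
    template_id: str,
    loop_motifs: int,
    stem_motifs: int,
    length: int | None = None,
    compact: bool = False,
    verify: bool = True,
) -> RsmTemplate:
    """Assemble a template from stem-loop modules and verify its ground truth.

    Loop-motif and stem-motif modules are interleaved, joined by single-A
    linkers, and padded with leading A's to ``length`` (A runs are inert in
    this alphabet).  ``compact`` selects shorter modules so many motifs fit a
    typical sRNA length.  Because base-pair maximization is degenerate, the
    assembler deterministically searches module arm orientations and returns
    the first pattern whose full-template fold reproduces the designed
    (total, exposed) motif counts exactly; the search itself is part of the
    construction and independent of any downstream analysis.
    """
    loop_mods = LOOP_MODULES_COMPACT if compact else LOOP_MODULES
    stem_mods = STEM_MODULES_COMPACT if compact else STEM_MODULES
    kinds = _module_order(loop_motifs, stem_motifs)
    n = len(kinds)
    base_len = (
        len(LEADER)
        + sum(len((loop_mods if k == "L" else stem_mods)[0]) for k in kinds)
        + (n - 1) * len(LINKER)
    )
    if length is not None and length < base_len:
        raise ValueError(f"requested length {length} below assembled size {base_len}")
    pad = "A" * (length - base_len) if length is not None else ""

    last_error: RsmTemplate | None = None
    for mask in range(2**n):
        mods = [
            (loop_mods if k == "L" else stem_mods)[(mask >> i) & 1]
            for i, k in enumerate(kinds)
        ]
        seq = pad + LEADER + LINKER.join(mods)
        tpl = RsmTemplate(template_id, seq, loop_motifs, stem_motifs)
        if not verify:
            return tpl
        summary = motif_summary(seq)
        if summary.n_total == tpl.n_motifs and summary.n_exposed == tpl.loop_motifs:
            return tpl
        last_error = tpl
    raise AssertionError(
        f"template {template_id}: no module orientation realizes "
        f"({loop_motifs + stem_motifs} total, {loop_motifs} exposed); "
        f"last tried {last_error.seq if last_error else ''}"
    )


def default_templates() -> list[RsmTemplate]:
    """Four presets mirroring the motif makeup of RsmX-1/X-2/Y/Z.

    Total motif counts 6, 6, 7 and 10; exposed counts 3, 3, 4 and 8; template
    lengths in the 110-125 nt range typical of Rsm sRNAs.
    """
    return [
        build_template("rsmX1_like", 3, 3, length=111),
        build_template("rsmX2_like", 3, 3, length=110),
        build_template("rsmY_like", 4, 3, length=124),
        build_template("rsmZ_like", 8, 2, compact=True),
    ]


# --- genome construction --------------------------------------------------

@dataclass(frozen=True)
class PlantSpec:
    """One planted locus: UAS box + promoter spacer + (diverged) gene.

    ``position`` is the forward-strand offset of the construct; on the minus
    strand the whole construct is reverse-complemented in place.
    """

    position: int
    strand: str = "+"
    uas_mismatches: int = 0
    template: RsmTemplate | None = None
    divergence: float = 0.0
    spacer: int = 25
    terminator: bool = True  # template already ends in one; kept for truth

    def __post_init__(self):
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


@dataclass(frozen=True)
class GenomeSpec:
    length: int
    gc: float = 0.5
    seed: int = 0
    plants: tuple[PlantSpec, ...] = ()
    uas: str = DEFAULT_UAS
    genome_id: str = "synthetic_contig"
    circular: bool = False

    def __post_init__(self):
        if self.length < 200:
            raise ValueError("genome length must be >= 200")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")


@dataclass(frozen=True)
class PlantTruth:
    """Realized coordinates and identities of one planted locus."""

    uas_start: int
    uas_end: int
    strand: str
    uas_mismatches: int
    gene_start: int
    gene_end: int
    template_id: str
    identity_to_template: float
    terminator: bool
    gene_seq: str = ""  # strand-resolved planted gene (incl. terminator)


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, float]:
    """Per-site substitution at ``rate``; returns (mutant, realized identity)."""
    chars = list(seq)
    changed = 0
    for i, c in enumerate(chars):
        if rng.random() < rate:
            alt = [b for b in BASES if b != c]
            chars[i] = alt[rng.integers(len(alt))]
            changed += 1
    return "".join(chars), 1.0 - changed / len(seq)


def _mutate_exactly(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    if n_sub == 0:
        return seq
    chars = list(seq)
    positions = rng.choice(len(chars), size=n_sub, replace=False)
    for i in positions:
        alt = [b for b in BASES if b != chars[i]]
        chars[i] = alt[rng.integers(len(alt))]
    return "".join(chars)


def make_genome(spec: GenomeSpec) -> tuple[GenomeSequence, list[PlantTruth]]:
    """Generate a genome with planted loci and an exact truth table.

    The background is i.i.d. at the requested GC content; each plant
    overwrites a segment with UAS + spacer + diverged gene template (the
    template's own terminator provides the 3' end).  Gene bodies are
    diverged at the plant's per-site substitution rate; the terminator is
    kept intact so boundary calling stays well-defined.
    """
    rng = np.random.default_rng(spec.seed)
    arr = _random_background(rng, spec.length, spec.gc)
    truths: list[PlantTruth] = []
    occupied: list[tuple[int, int]] = []
    for plant in spec.plants:
        if plant.template is None:
            raise ValueError("every plant needs a gene template")
        uas = _mutate_exactly(rng, spec.uas, plant.uas_mismatches)
        body, identity = _mutate(rng, plant.template.seq, plant.divergence)
        gene = body + (TERMINATOR if plant.terminator else "")
        construct = uas + "A" * plant.spacer + gene
        start, end = plant.position, plant.position + len(construct)
        if end > spec.length:
            raise ValueError(f"plant at {plant.position} runs past the genome end")
        for o_s, o_e in occupied:
            if start < o_e and o_s < end:
                raise ValueError("planted features must not overlap")
        occupied.append((start, end))
        if plant.strand == "-":
            construct = reverse_complement(construct)
            uas_start = end - len(spec.uas)
            gene_end_fwd = start + len(gene)
            gene_iv = (start, gene_end_fwd)
        else:
            uas_start = start
            gene_iv = (end - len(gene), end)
        arr[start:end] = np.frombuffer(construct.encode(), dtype=np.uint8)
        truths.append(
            PlantTruth(
                uas_start=uas_start,
                uas_end=uas_start + len(spec.uas),
                strand=plant.strand,
                uas_mismatches=plant.uas_mismatches,
                gene_start=gene_iv[0],
                gene_end=gene_iv[1],
                template_id=plant.template.id,
                identity_to_template=identity,
                terminator=plant.terminator,
                gene_seq=gene,
            )
        )
    genome = GenomeSequence(spec.genome_id, arr.tobytes().decode(), spec.circular)
    return genome, truths


def make_tandem_genome(
    seed: int = 0,
    divergence: float = 0.25,
    gap: int = 101,
    length: int = 5000,
    template: RsmTemplate | None = None,
) -> tuple[GenomeSequence, list[PlantTruth]]:
    """Convenience genome with two tandem copies of one template.

    The second copy is diverged from the template at ``divergence``
    (0.25 on the gene body yields ~75-80% identity between copies, the
    hallmark of a recently duplicated rsmX pair); ``gap`` is the distance
    between the end of the first cassette and the start of the second.
    The default template body (86 nt) plus 24-nt terminator gives 110-nt
    genes;
    ``gap`` is measured from the end of the first gene to the start of the
    second gene (the second UAS and spacer sit inside it), so it must exceed
    the UAS-plus-spacer footprint (43 nt by default).
    """
    template = template or build_template("rsmX_like", 3, 3, length=110 - len(TERMINATOR))
    upstream = len(DEFAULT_UAS) + 25
    cassette = upstream + len(template.seq) + len(TERMINATOR)
    if gap <= upstream:
        raise ValueError(f"gap must exceed the UAS+spacer footprint ({upstream} nt)")
    p1 = 1000
    p2 = p1 + cassette + gap - upstream
    spec = GenomeSpec(
        length=length,
        seed=seed,
        plants=(
            PlantSpec(position=p1, template=template, divergence=0.0),
            PlantSpec(position=p2, template=template, divergence=divergence,
                      uas_mismatches=2),
        ),
    )
    return make_genome(spec)


# --- sequence families ----------------------------------------------------

def make_rsm_family(
    n_per_family: int,
    n_families: int = 3,
    within_div: float = 0.05,
    between_div: float = 0.35,
    seed: int = 0,
    root_length: int = 110,
) -> dict[str, str]:
    """Labelled sequences from ``n_families`` star-shaped families.

    Family ancestors are independent mutants of one random root at the
    between-family divergence; members are mutants of their ancestor at the
    within-family divergence, so expected within-family identity exceeds
    between-family identity whenever within_div < between_div.
    Labels are 'fam<k>_<i>'.
    """
    if not within_div < between_div:
        raise ValueError("within_div must be < between_div")
    rng = np.random.default_rng(seed)
    root = "".join(BASES[i] for i in rng.integers(4, size=root_length))
    seqs: dict[str, str] = {}
    for f in range(n_families):
        ancestor, _ = _mutate(rng, root, between_div)
        for i in range(n_per_family):
            member, _ = _mutate(rng, ancestor, within_div)
            seqs[f"fam{f + 1}_{i + 1}"] = member
    return seqs


# --- decay simulation -----------------------------------------------------

from .decay_kinetics import PAPER_TIMEPOINTS, DecayTimeCourse, Replicate  # noqa: E402


@dataclass(frozen=True)
class DecaySpec:
    srna_id: str = "srna"
    true_t_half: float = 20.0
    times: tuple[float, ...] = PAPER_TIMEPOINTS
    n_replicates: int = 3
    noise_cv: float = 0.1
    efficiency: float = 2.0
    seed: int = 0
    reference_ct: float = 10.0
    baseline_dct: float = 8.0

    def __post_init__(self):
        if self.true_t_half <= 0:
            raise ValueError("true_t_half must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def simulate_decay(spec: DecaySpec) -> DecayTimeCourse:
    """Exponential decay with multiplicative lognormal replicate noise.

    True abundance is 2**(-t / t_half); each observation is multiplied by a
    mean-one lognormal factor with the requested coefficient of variation and
    converted to a (Ct_target, Ct_reference) pair by inverting the
    delta-delta-Ct model at the spec's amplification efficiency.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times, dtype=float)
    sigma = np.sqrt(np.log1p(spec.noise_cv**2))
    log_eff = np.log(spec.efficiency)
    reps = []
    for _ in range(spec.n_replicates):
        true = 2.0 ** (-t / spec.true_t_half)
        if sigma > 0:
            noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=len(t))
        else:
            noise = np.ones(len(t))
        obs = true * noise
        dct = spec.baseline_dct - np.log(obs) / log_eff
        ct_ref = np.full(len(t), spec.reference_ct)
        ct_tgt = ct_ref + dct
        reps.append(Replicate(tuple(ct_tgt), tuple(ct_ref)))
    return DecayTimeCourse(spec.srna_id, tuple(t), tuple(reps), spec.efficiency)
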
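# Methods

## Scope and model overview

rsmkit treats the discovery and characterization of GacA-controlled Rsm
small RNAs as four coupled computational problems: (1) locating the
palindromic GacA upstream activating sequence (UAS) in genomic DNA and
delimiting the sRNA gene downstream of it, (2) predicting which CsrA/RsmA
recognition motifs an sRNA exposes in single-stranded loops, (3) measuring
sequence relatedness among sRNA copies and families, and (4) estimating RNA
decay half-lives from rifampicin-chase qPCR data. Each stage is specified
precisely enough to be checked against an independent oracle (brute-force
enumeration or closed form) in the test suite.

## UAS scanning and candidate calling

The scan reports every window on either strand whose Hamming distance to
the UAS query is at most `max_mismatch` (default 3, upper bound 6).
Substitution-only matching reflects how near-identical UAS variants of
duplicated rsm genes differ — by point mutations, not indels. Overlapping
and palindromic self-matches are all reported; hits on opposite strands are
never merged. Circular contigs are scanned across the origin.

A candidate locus starts `spacer_offset` nt downstream of the UAS box
(default 25 nt, the promoter spacer the synthetic generator also uses) and
ends at the first Rho-independent terminator within a 400-nt window:
a hairpin of stem 4–12 bp and loop 3–10 nt followed by ≥ 4 T within the
next 8 nt; the called 3' end is the last T of that window. Without a
terminator the candidate defaults to 120 nt, covering the 107–113 nt range
typical of rsmX-like genes. Candidates running off a linear contig are
truncated and flagged. Real 5'/3' ends are fixed experimentally (5'RACE,
Northern blots); this heuristic is a reproducible stand-in, and the
`spacer_offset`/`default_len` parameters are the knobs to adjust when
transcript ends are known.

Tandem detection reports every candidate pair on one contig with inter-gene
gap ≤ 1000 nt and global-alignment identity ≥ 0.6 — permissive enough to
catch diverged duplicates at ~75 % identity while excluding unrelated loci.

## Secondary structure and motif exposure

Folding maximizes the number of nested Watson–Crick plus GU pairs with a
minimum hairpin loop of 3 nt (Nussinov-style dynamic programming), rather
than minimizing thermodynamic free energy. The choice is deliberate: the
maximization problem has an exact, enumerable optimum, so the folder is
verified against exhaustive enumeration for all short sequences, and
externally predicted structures can be imported as dot-bracket when exact
reproduction of a published fold is required. Base-pair maximization is
highly degenerate; the traceback is made deterministic by always pairing
the 5'-most base that can participate in an optimal structure with its
smallest admissible partner, recursively.

Motifs are all AGGA and ANGGA occurrences, deduplicated so each GGA core is
counted once (an ANGGA whose core coincides with a reported AGGA is
suppressed). A motif is `hairpin_exposed` iff every base is unpaired and
lies inside one hairpin loop — a maximal unpaired run closed by exactly one
pair — which is the configuration competent for CsrA/RsmA sequestration;
`unpaired_nonhairpin` covers exterior/interior loops, `paired` everything
else. Exposure is computed on the single deterministic optimal structure;
optionally an interval over co-optimal structures (enumeration capped at
50, always including the point estimate's structure) mirrors the ranges
published when multiple folding tools disagree.

## Homology and UPGMA

Global alignment uses match +1, mismatch −1, linear gap −2, with
deterministic traceback (diagonal over up over left on ties). Percent
identity divides matching columns by the full alignment length including
gap columns; this denominator convention is declared here because published
identity tables rarely state theirs. Distances are `1 − identity`; UPGMA
merges the closest cluster pair (ties broken by the lexicographically
smallest min-leaf-label pair), places the new node at height `d/2`, and
updates distances by size-weighted arithmetic means. The result is
ultrametric by construction (tested to 1e-9). A "modified UPGMA" as bundled
with multiple-alignment toolkits is sometimes used for such trees; the
modification being unspecified, classic UPGMA is implemented and the scipy
average-linkage heights serve as an independent check.

## Decay kinetics

Relative abundance follows the ΔΔCt model
`rel(t) = E^−(ΔCt(t) − ΔCt(0))`, ΔCt = Ct_target − Ct_reference, with
amplification efficiency `E ∈ (1, 2]` (default 2 = perfect doubling).
The time grid is t = 0 (normalization anchor) plus the 11 chase sampling
points 1, 2, 5, 10, 15, 20, 30, 45, 60, 90, 120 min. Because the fit
includes an intercept, it is invariant to constant shifts in the reference
channel and to noise in the t = 0 normalization.

Half-lives come from ordinary least squares on ln(rel) vs time — the
standard analysis for first-order rifampicin-chase decay and analytically
checkable — after excluding points at or below a detection floor of 1e-3
relative abundance. If the fitted decay rate is non-positive or the implied
half-life exceeds `censor_at` (default: the last sampled time, 120 min),
the estimate is right-censored and reported as `≥ bound`, reproducing how
chase experiments report RNAs too stable to quantify. Replicates are fitted
first and then summarized as mean ± sample sd (ddof 1); whether published
"±" values are sd or sem is usually unstated, and sample sd is the
assumption here. A summary containing any censored replicate is censored at
the smallest replicate bound and flagged if mixed.

The motif-stability association uses Spearman correlation on mid-ranks,
with censored half-lives ranked above all uncensored values and among
themselves by bound — the natural partial order for right-censored data at
these sample sizes (n = 4 sRNAs); survival-model alternatives would be
over-parameterized here.

## Synthetic data generator

The generator emulates the study conditions so that every stage has exact
ground truth:

- **Genomes** — i.i.d. background at a requested GC content; each planted
  cassette is UAS (mutated at exactly the requested Hamming distance) +
  25-nt poly-A promoter spacer + gene. Plants must not overlap; the truth
  table records realized coordinates, strand, divergence and sequences.
- **Rsm-like templates** — constructed, not sampled: stem-loop modules with
  an AGGA in the terminal loop (exposed) or with the motif's leading A as
  the last stem pair (paired), joined by single-A linkers with A padding.
  Module alphabets are chosen so A-runs are inert, and each module exists
  in two arm orientations (G-rich vs C-rich 5' arm); because base-pair
  maximization is degenerate, the assembler searches orientation patterns
  deterministically and returns the first whose full-template fold
  reproduces the designed (total, exposed) counts exactly — construction
  fails loudly rather than ship a template whose truth does not hold.
  The four presets carry 6/6/7/10 motifs with 3/3/4/8 exposed at lengths
  111/110/124/127 nt, mirroring the published motif makeup of
  RsmX-1/X-2/Y/Z. The Rho-independent terminator (6-bp palindromic stem,
  4-nt loop, 8-nt U-tract exactly filling the detector's window) is
  appended by the genome builder, not part of the folded template, because
  its U-tract would otherwise cross-pair with loop adenines and invalidate
  the exposure truth.
- **Families** — a random root diverged into family ancestors at the
  between-family rate and members at the within-family rate (per-site
  substitution), giving controllable within/between identity for clade-
  recovery tests (defaults 0.05 / 0.35, 3 families × 4 members).
- **Decay** — true abundance `2^(−t/t½)` with mean-one multiplicative
  lognormal noise at a requested coefficient of variation (default 0.1,
  a realistic qPCR replicate scatter), inverted through the ΔΔCt model to
  Ct pairs at a fixed reference Ct.

What the generator does *not* emulate: transcription-start heterogeneity,
sequence-dependent RNase accessibility, protein (RsmA/E, Hfq) protection,
amplification-efficiency drift between target and reference, and genomic
repeat structure. Passing tests therefore demonstrate correctness of the
algorithms under the stated models, not performance on real genomes or
chase data.

## Numerical and design choices

- Coordinates are 0-based half-open internally; GFF3 export is 1-based
  inclusive. Published tandem-locus tables are imported as
  length = |end − begin| with begin > end encoding the minus strand — the
  only reading that reproduces every printed size column — and that
  non-standard convention is confined to the import/export layer.
- Alignment and fold scores are small exact floats; tie-breaking relies on
  exact equality, which is safe for these integer-valued scores.
- UPGMA heights are stored on tree nodes; branch lengths are height
  differences, so trees are ultrametric up to floating-point rounding.
- The half-life estimator evaluated on noise-free exponentials is exact to
  machine precision for any t½ in [1, 200] min (censoring disabled for
  that check, since censoring is a reporting rule, not an estimator
  property).
- Problem sizes used in tests and the acceptance script — 10–50 kb
  genomes, 1000 simulated chase courses, 20 seeded family datasets —
  keep every oracle comparison exhaustive or statistically stable while
  the whole suite runs in well under a minute per module.

## Known limitations

- Base-pair maximization is not a thermodynamic model; for real sRNAs the
  predicted structure (and hence exposure counts) can differ from MFE
  predictions. Import dot-bracket structures from a thermodynamic folder
  when fidelity to a published structure matters.
- Candidate 5' ends are parameterized, not predicted; terminator detection
  is a heuristic with no hairpin-stability scoring.
- Identity is pairwise-global only; no multiple sequence alignment.
- The censoring rule ties bounds to the sampling window, not to assay
  detection limits, which may differ in practice.
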
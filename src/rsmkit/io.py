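"""File formats: FASTA, GFF3, dot-bracket, TSV/CSV tables.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open on the forward strand.  GFF3
output follows the GFF3 convention (1-based inclusive).  Published locus
tables for tandem rsmX copies use a begin/end pair where the gene length is
|end - begin| and begin > end encodes the minus strand; the loader converts
that convention on import.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .decay_kinetics import DecayTimeCourse, Replicate
from .genome_scan import GenomeSequence, SrnaCandidate, TandemPair, UASHit


# --- FASTA ----------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    return [
        GenomeSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# --- GFF3 -----------------------------------------------------------------

def write_gff3(
    path: str | Path,
    hits: Iterable[UASHit],
    cands: Iterable[SrnaCandidate],
    source: str = "rsmkit",
) -> None:
    """UAS boxes and sRNA candidates as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        hit_ids: dict[tuple, str] = {}
        for n, h in enumerate(hits, 1):
            hid = f"uas_{n}"
            hit_ids[(h.genome_id, h.start, h.strand)] = hid
            attrs = f"ID={hid};mismatches={h.mismatches};matched_seq={h.matched_seq}"
            fh.write(
                f"{h.genome_id}\t{source}\tUAS_box\t{h.start + 1}\t{h.end}\t"
                f"{h.mismatches}\t{h.strand}\t.\t{attrs}\n"
            )
        for c in cands:
            parent = hit_ids.get((c.uas.genome_id, c.uas.start, c.uas.strand), ".")
            attrs = (
                f"ID={c.id};Parent={parent};terminator_found={str(c.terminator_found).lower()};"
                f"truncated={str(c.truncated).lower()}"
            )
            fh.write(
                f"{c.genome_id}\t{source}\tsRNA_candidate\t{c.start + 1}\t{c.end}\t"
                f".\t{c.strand}\t.\t{attrs}\n"
            )


@dataclass(frozen=True)
class Gff3Feature:
    seqid: str
    source: str
    type: str
    start: int  # converted back to 0-based
    end: int  # half-open
    strand: str
    attributes: dict[str, str]


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    feats = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version"):
            raise ValueError("missing ##gff-version directive")
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            feats.append(
                Gff3Feature(f[0], f[1], f[2], int(f[3]) - 1, int(f[4]), f[6], attrs)
            )
    return feats


# --- dot-bracket ----------------------------------------------------------

def write_dotbracket(path: str | Path, records: dict[str, tuple[str, str]]) -> None:
    """Records of id -> (sequence, dot-bracket), three lines each."""
    with open(path, "w") as fh:
        for name, (seq, db) in records.items():
            fh.write(f">{name}\n{seq}\n{db}\n")


def read_dotbracket(path: str | Path) -> dict[str, tuple[str, str]]:
    out: dict[str, tuple[str, str]] = {}
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected header at line {i + 1}")
        name = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise ValueError(f"truncated record {name!r}")
        out[name] = (lines[i + 1], lines[i + 2])
        i += 3
    return out


# --- locus tables (published begin/end convention) --------------------------

@dataclass(frozen=True)
class Locus:
    gene: str
    start: int  # 0-based half-open, forward strand
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


def load_locus_table(path_or_buf: str | Path | TextIO) -> list[Locus]:
    """Load a published-style locus TSV with columns gene, begin, end.

    ``begin``/``end`` are 1-based; gene length is |end - begin| and
    begin > end encodes the minus strand (this reproduces every printed size
    in tandem-rsmX locus tables, where the convention is implicit).
    Rows with begin = end are rejected.
    """
    df = pd.read_csv(path_or_buf, sep="\t")
    required = {"gene", "begin", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"locus table needs columns {sorted(required)}")
    loci = []
    for idx, row in df.iterrows():
        begin, end = int(row["begin"]), int(row["end"])
        if begin == end:
            raise ValueError(f"row {idx}: degenerate interval begin == end == {begin}")
        if end > begin:
            strand, lo, hi = "+", begin, end
        else:
            strand, lo, hi = "-", end, begin
        # 1-based begin/end span |end-begin| nt exclusive of one endpoint in
        # the published convention; convert to 0-based half-open directly.
        loci.append(Locus(str(row["gene"]), lo - 1, hi - 1, strand))
    return loci


# --- tabular exports --------------------------------------------------------

def hits_to_frame(hits: list[UASHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": h.genome_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "matched_seq": h.matched_seq,
                "mismatches": h.mismatches,
            }
            for h in hits
        ]
    )


def tandem_to_frame(pairs: list[TandemPair], n_copies: int | None = None) -> pd.DataFrame:
    """Published-style tandem table: begin/end in the 1-based convention
    where begin > end encodes the minus strand."""
    rows = []
    for p in pairs:
        for cand in (p.a, p.b):
            begin, end = cand.start + 1, cand.end + 1
            if cand.strand == "-":
                begin, end = end, begin
            rows.append(
                {
                    "gene": cand.id,
                    "begin": begin,
                    "end": end,
                    "size_nt": cand.length,
                    "identity_pct": round(100 * p.identity, 1),
                    "gap_nt": p.gap,
                    "n_copies": n_copies if n_copies is not None else 2,
                }
            )
    return pd.DataFrame(rows)


# --- decay CSV schema -------------------------------------------------------

DECAY_COLUMNS = [
    "srna_id",
    "condition",
    "phase",
    "time_min",
    "replicate",
    "Ct_target",
    "Ct_reference",
]


def write_decay_csv(
    path: str | Path, courses: list[tuple[str, str, DecayTimeCourse]]
) -> None:
    """(condition, phase, course) triples flattened to the decay CSV schema."""
    rows = []
    for condition, phase, tc in courses:
        for r, rep in enumerate(tc.replicates, 1):
            for t, ct_t, ct_r in zip(tc.times, rep.ct_target, rep.ct_reference):
                rows.append(
                    {
                        "srna_id": tc.srna_id,
                        "condition": condition,
                        "phase": phase,
                        "time_min": t,
                        "replicate": r,
                        "Ct_target": ct_t,
                        "Ct_reference": ct_r,
                    }
                )
    pd.DataFrame(rows, columns=DECAY_COLUMNS).to_csv(path, index=False)


def read_decay_csv(
    path: str | Path, efficiency: float = 2.0
) -> dict[tuple[str, str, str], DecayTimeCourse]:
    """Parse the decay CSV into time courses keyed by (srna, condition, phase)."""
    df = pd.read_csv(path)
    missing = set(DECAY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"decay CSV missing columns {sorted(missing)}")
    bad = df[df["time_min"].isna() | df["Ct_target"].isna()]
    if len(bad):
        raise ValueError(f"malformed decay CSV row at line {bad.index[0] + 2}")
    out: dict[tuple[str, str, str], DecayTimeCourse] = {}
    for (srna, cond, phase), grp in df.groupby(
        ["srna_id", "condition", "phase"], sort=True
    ):
        times = tuple(sorted(grp["time_min"].unique()))
        reps = []
        for _, rep_grp in grp.groupby("replicate", sort=True):
            rep_grp = rep_grp.sort_values("time_min")
            if tuple(rep_grp["time_min"]) != times:
                raise ValueError(
                    f"{srna}/{cond}/{phase}: replicate time grids differ"
                )
            reps.append(
                Replicate(
                    tuple(rep_grp["Ct_target"]), tuple(rep_grp["Ct_reference"])
                )
            )
        out[(str(srna), str(cond), str(phase))] = DecayTimeCourse(
            str(srna), times, tuple(reps), efficiency
        )
    return out
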
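"""End-to-end orchestration: discovery and decay report bundles.

``run_discover`` chains UAS scanning, candidate calling, motif/structure
summaries, tandem detection and UPGMA clustering into a reproducible output
directory; ``run_decay`` turns rifampicin-chase CSV time courses into a
half-life table (with censored entries rendered ">=bound"), fold-change
ratios between phases, and a motif-stability correlation when motif counts
are available.  All outputs are plain text and deterministic for a fixed
config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .decay_kinetics import (
    HalfLifeEstimate,
    fit_halflife,
    fold_change,
    rank_correlation,
    relative_abundance,
    summarize_replicates,
)
from .genome_scan import DEFAULT_UAS, TerminatorParams, call_candidates, detect_tandem, scan_uas
from .homology_phylo import distance_matrix, upgma
from .io import (
    load_locus_table,  # noqa: F401  (re-exported pipeline entry point)
    read_decay_csv,
    read_fasta,
    tandem_to_frame,
    write_dotbracket,
    write_gff3,
)
from .structure_motif import fold_maxpair, motif_summary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative parameters for a pipeline run, echoed into the outputs."""

    fasta: str | None = None
    decay_csv: str | None = None
    out_dir: str = "rsmkit_out"
    uas_query: str = DEFAULT_UAS
    max_mismatch: int = 3
    window: int = 400
    default_len: int = 120
    spacer_offset: int = 25
    max_gap: int = 1000
    min_identity: float = 0.6
    efficiency: float = 2.0
    censor_at: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.max_mismatch <= 6:
            raise ValueError("max_mismatch must be in [0, 6]")
        if self.window < self.default_len:
            raise ValueError("window must be >= default_len")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must be in (1, 2]")


def _echo_config(config: RunConfig, out: Path) -> None:
    with open(out / "config.json", "w") as fh:
        json.dump(
            {"rsmkit_version": __version__, **asdict(config)}, fh, indent=2, sort_keys=True
        )
        fh.write("\n")


def run_discover(config: RunConfig) -> dict[str, Path]:
    """UAS scan -> candidates -> structures/motifs -> tandem pairs -> tree.

    Writes GFF3 candidates, TSV hit/motif/tandem tables, dot-bracket
    structures and (for >= 2 candidates) a Newick tree; returns the paths.
    """
    config.validate()
    if not config.fasta or not Path(config.fasta).exists():
        raise FileNotFoundError(f"input FASTA not found: {config.fasta!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _echo_config(config, out)

    genomes = read_fasta(config.fasta)
    all_hits, all_cands = [], []
    for genome in genomes:
        hits = scan_uas(genome, config.uas_query, config.max_mismatch)
        cands = call_candidates(
            genome,
            hits,
            window=config.window,
            default_len=config.default_len,
            offset=config.spacer_offset,
            term_params=TerminatorParams(),
            id_prefix=f"{genome.id}_srna",
        )
        all_hits.extend(hits)
        all_cands.extend(cands)
        logger.info("%s: %d UAS hits, %d candidates", genome.id, len(hits), len(cands))

    paths = {
        "gff3": out / "candidates.gff3",
        "hits": out / "uas_hits.tsv",
        "motifs": out / "motif_summary.tsv",
        "tandem": out / "tandem_pairs.tsv",
        "structures": out / "structures.db.txt",
        "tree": out / "tree.nwk",
    }
    write_gff3(paths["gff3"], all_hits, all_cands)
    from .io import hits_to_frame

    hits_to_frame(all_hits).to_csv(paths["hits"], sep="\t", index=False)

    motif_rows, structures = [], {}
    for cand in all_cands:
        struct = fold_maxpair(cand.seq)
        summary = motif_summary(cand.seq, struct=struct)
        structures[cand.id] = (struct.seq, struct.dotbracket)
        motif_rows.append(
            {
                "candidate_id": cand.id,
                "length_nt": cand.length,
                "n_motifs": summary.n_total,
                "n_exposed": summary.n_exposed,
                "terminator_found": cand.terminator_found,
            }
        )
    pd.DataFrame(
        motif_rows,
        columns=["candidate_id", "length_nt", "n_motifs", "n_exposed", "terminator_found"],
    ).to_csv(paths["motifs"], sep="\t", index=False)
    write_dotbracket(paths["structures"], structures)

    tandem_frames = []
    for genome in genomes:
        g_cands = [c for c in all_cands if c.genome_id == genome.id]
        pairs = detect_tandem(g_cands, config.max_gap, config.min_identity)
        if pairs:
            tandem_frames.append(tandem_to_frame(pairs, n_copies=len(g_cands)))
    tandem = (
        pd.concat(tandem_frames, ignore_index=True)
        if tandem_frames
        else pd.DataFrame(
            columns=["gene", "begin", "end", "size_nt", "identity_pct", "gap_nt", "n_copies"]
        )
    )
    tandem.to_csv(paths["tandem"], sep="\t", index=False)

    if len(all_cands) >= 2:
        dm = distance_matrix({c.id: c.seq for c in all_cands})
        tree = upgma(dm)
        tree.write(str(paths["tree"]))
    else:
        paths["tree"].write_text("")
    return paths


def _render(est: HalfLifeEstimate) -> dict:
    return {
        "t_half_min": "" if est.censored else round(est.t_half, 2),
        "sd_min": "" if est.censored else round(est.sd, 2),
        "censored": est.censored,
        "bound": f">={est.censor_bound:g}" if est.censored else "",
    }


def run_decay(
    config: RunConfig, motif_counts: dict[str, int] | None = None
) -> dict[str, Path]:
    """Half-life table, phase fold changes and motif-stability correlation."""
    config.validate()
    if not config.decay_csv or not Path(config.decay_csv).exists():
        raise FileNotFoundError(f"decay CSV not found: {config.decay_csv!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _echo_config(config, out)

    courses = read_decay_csv(config.decay_csv, efficiency=config.efficiency)
    summaries: dict[tuple[str, str, str], HalfLifeEstimate] = {}
    rows = []
    for (srna, cond, phase), tc in sorted(courses.items()):
        fits = [
            fit_halflife(series, censor_at=config.censor_at)
            for series in relative_abundance(tc)
        ]
        est = summarize_replicates(fits)
        summaries[(srna, cond, phase)] = est
        rows.append(
            {"srna_id": srna, "condition": cond, "phase": phase, **_render(est)}
        )
    paths = {
        "halflives": out / "halflives.tsv",
        "fold_changes": out / "fold_changes.tsv",
        "correlation": out / "correlation.tsv",
    }
    pd.DataFrame(rows).to_csv(paths["halflives"], sep="\t", index=False)

    fc_rows = []
    keys = {(s, c) for s, c, _ in summaries}
    for srna, cond in sorted(keys):
        stat = summaries.get((srna, cond, "stationary"))
        expo = summaries.get((srna, cond, "exponential"))
        if stat is None or expo is None or (stat.censored and expo.censored):
            continue
        fc = fold_change(stat, expo)
        fc_rows.append(
            {
                "srna_id": srna,
                "condition": cond,
                "fold_change_stat_vs_expo": str(fc),
            }
        )
    pd.DataFrame(
        fc_rows, columns=["srna_id", "condition", "fold_change_stat_vs_expo"]
    ).to_csv(paths["fold_changes"], sep="\t", index=False)

    corr_rows = []
    if motif_counts:
        for cond in sorted({c for _, c, _ in summaries}):
            for phase in sorted({p for _, _, p in summaries}):
                sel = [
                    (srna, summaries[(srna, cond, phase)])
                    for srna in sorted(motif_counts)
                    if (srna, cond, phase) in summaries
                ]
                if len(sel) < 3:
                    continue
                rho = rank_correlation(
                    [motif_counts[s] for s, _ in sel], [e for _, e in sel]
                )
                corr_rows.append(
                    {
                        "condition": cond,
                        "phase": phase,
                        "n": len(sel),
                        "spearman_rho": round(rho, 4),
                    }
                )
    pd.DataFrame(
        corr_rows, columns=["condition", "phase", "n", "spearman_rho"]
    ).to_csv(paths["correlation"], sep="\t", index=False)
    return paths
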
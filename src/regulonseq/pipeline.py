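"""End-to-end pipeline: simulate -> peaks -> DEGs -> motifs -> regulon.

Also houses the reference-table replay: recomputing the direct-regulon
bookkeeping (unique loci, upstream-peak genes, singular vs operon-first
counts, activated/repressed split, divergent pairs, dyad-consensus matches)
from the packaged published table rather than trusting any stored total.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .differential_expression import (CountMatrix, LFC_THRESHOLD,
                                      Q_THRESHOLD, deg_table, rpkm,
                                      run_deg_analysis)
from .genome_model import GenomeAnnotation, read_fasta, read_gff, \
    with_sequence
from .motif_analysis import CRP_DYAD, build_pwm, genome_background, \
    scan_dyad, scan_pwm
from .peak_calling import (DEFAULT_P_CUTOFF, call_peaks_nb_gc,
                           call_peaks_poisson, consensus_peaks, number_peaks,
                           write_narrowpeak)
from .regulon_integration import (PROMOTER_WINDOW, OPERON_MAX_EXPR_DELTA,
                                  OPERON_MAX_GAP, assign_regulation,
                                  classify_peaks, infer_operons, load_table1,
                                  regulon_table, summarize_regulon)
from .synthetic_data import SimulationConfig, read_bedgraph, \
    simulate_counts, simulate_coverage, write_dataset

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_DATA = 3


@dataclass
class PipelineConfig:
    """All thresholds and paths of one pipeline run."""

    outdir: str = "regulonseq_out"
    peak_p_cutoff: float = DEFAULT_P_CUTOFF
    motif_p_threshold: float = 0.01
    lfc_threshold: float = LFC_THRESHOLD
    q_threshold: float = Q_THRESHOLD
    window: tuple[int, int] = PROMOTER_WINDOW
    operon_gap: int = OPERON_MAX_GAP
    expr_delta: float = OPERON_MAX_EXPR_DELTA
    seed: int = 1
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.peak_p_cutoff <= 0 or self.motif_p_threshold <= 0 \
                or self.lfc_threshold <= 0 or self.q_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not self.window[0] < self.window[1]:
            raise ValueError("window lower bound must be below upper bound")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        self.window = tuple(self.window)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Simulate (or load) a dataset, run every stage, write all outputs.

    Returns the summary report dict; every stage artefact lands under
    ``cfg.outdir``.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    logger.info("simulating dataset (seed=%d) under %s", cfg.seed, out)
    truth = write_dataset(out / "data", sim)

    ann = read_gff(out / "data" / "annotation.gff3")
    ann = with_sequence(ann, read_fasta(out / "data" / "genome.fasta"))
    ip = read_bedgraph(out / "data" / "ip.bedgraph", ann.genome_length)
    inp = read_bedgraph(out / "data" / "input.bedgraph", ann.genome_length)

    logger.info("calling peaks (p <= %g, both background models)",
                cfg.peak_p_cutoff)
    pa = call_peaks_poisson(ip, inp, cfg.peak_p_cutoff,
                            fragment_size=sim.fragment_size)
    pb = call_peaks_nb_gc(ip, inp, ann.sequence, cfg.peak_p_cutoff,
                          fragment_size=sim.fragment_size)
    peaks = number_peaks(consensus_peaks(pa, pb))
    write_narrowpeak(peaks, out / "peaks.narrowPeak", ann.seqid)

    logger.info("differential expression (|lfc| >= %.2f, q < %.2f)",
                cfg.lfc_threshold, cfg.q_threshold)
    cm = CountMatrix.from_tsv(out / "data" / "counts.tsv")
    degs = run_deg_analysis(cm, cfg.lfc_threshold, cfg.q_threshold)
    deg_table(degs).to_csv(out / "degs.tsv", sep="\t")

    logger.info("motif scan over %d consensus peaks", len(peaks))
    bg = genome_background(ann.sequence)
    motif_hits = {}
    site_seqs = []
    for p in peaks:
        region = ann.sequence[p.interval.start:p.interval.end]
        hits = scan_dyad(CRP_DYAD, region)
        if hits:
            site_seqs.append(hits[0].matched)
        motif_hits[p.peak_id] = hits
    if len(site_seqs) >= 2:
        pwm = build_pwm(site_seqs, background=bg)
        for p in peaks:
            if not motif_hits[p.peak_id]:
                region = ann.sequence[p.interval.start:p.interval.end]
                motif_hits[p.peak_id] = scan_pwm(
                    pwm, region, cfg.motif_p_threshold)
    hit_rows = [
        {"peak_id": pid, "position": h.position, "strand": h.strand,
         "matched": h.matched, "score": h.score, "p": h.p, "kind": h.kind}
        for pid, hits in motif_hits.items() for h in hits]
    pd.DataFrame(hit_rows, columns=["peak_id", "position", "strand",
                                    "matched", "score", "p", "kind"]
                 ).to_csv(out / "motif_hits.tsv", sep="\t", index=False)

    logger.info("integrating peaks, DEGs and operons")
    expr = rpkm(cm)[cm.samples("wt")].mean(axis=1).to_dict()
    operons = infer_operons(ann, expr, cfg.operon_gap, cfg.expr_delta)
    ctxs = classify_peaks(peaks, ann, cfg.window)
    records = assign_regulation(ctxs, degs, operons, cfg.window, ann,
                                motif_hits)
    regulon_table(records, ann).to_csv(out / "regulon.tsv", sep="\t",
                                       index=False)
    summary = summarize_regulon(records, ctxs, ann)
    summary["truth"] = {
        "planted_sites": len(truth.planted_sites),
        "direct_targets": len(truth.direct_targets),
        "indirect_targets": len(truth.indirect_targets),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "peak_p_cutoff": cfg.peak_p_cutoff,
            "motif_p_threshold": cfg.motif_p_threshold,
            "lfc_threshold": cfg.lfc_threshold,
            "q_threshold": cfg.q_threshold,
            "window": list(cfg.window),
            "operon_gap": cfg.operon_gap,
            "expr_delta": cfg.expr_delta,
        },
        "python": sys.version.split()[0],
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return summary


# ---------------------------------------------------------------------------
# Reference-table replay
# ---------------------------------------------------------------------------

def replay_table1(fixture: str | Path | pd.DataFrame | None = None) -> dict:
    """Recompute the direct-regulon bookkeeping from the reference table.

    Rows bearing a summit-to-start distance are the genes with a peak
    directly upstream (roles single or first-in-operon); loci are counted
    once even when printed under two functional categories.  Divergent
    pairs are peaks shared by two opposite-strand distance-bearing loci;
    dyad matches count distinct peaks whose predicted site contains the
    strict TGTGA-N6-TCACA palindrome.
    """
    if isinstance(fixture, pd.DataFrame):
        df = fixture
    else:
        df = load_table1(fixture)
    df = df.copy()
    has_distance = df["distance"].astype(str).str.strip() != ""

    unique_loci = int(df["locus_id"].nunique())
    direct = df[has_distance].drop_duplicates("locus_id")
    singular = direct[direct["role"] == "single"]
    first_op = direct[direct["role"] == "first_in_operon"]
    activated = direct[direct["log2fc"] < 0]
    repressed = direct[direct["log2fc"] > 0]

    divergent_pairs = 0
    for _pid, grp in direct.groupby("peak_id"):
        if set(grp["strand"]) == {"+", "-"}:
            divergent_pairs += 1

    dyad_peaks = {
        str(row.peak_id) for row in df.itertuples()
        if scan_dyad(CRP_DYAD, str(row.site_seq))}

    return {
        "unique_loci": unique_loci,
        "direct_genes": int(len(direct)),
        "singular_genes": int(len(singular)),
        "first_in_operon_genes": int(len(first_op)),
        "activated": int(len(activated)),
        "repressed": int(len(repressed)),
        "divergent_pairs": divergent_pairs,
        "distinct_peaks": int(df["peak_id"].nunique()),
        "dyad_consensus_peaks": len(dyad_peaks),
    }
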
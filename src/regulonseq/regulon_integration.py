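"""Integration of binding peaks with differential expression.

This is the heart of the analysis: each consensus ChIP-seq peak is placed in
its genomic context, summit-to-start-codon distances are measured along the
gene's own strand, operons are inferred from gene spacing plus expression
similarity, and differentially expressed genes are split into directly bound
targets (summit within the promoter window, -1000..+50 bp of the start
codon), operon followers of a directly bound first gene, and indirect
targets.  The output mirrors a per-gene regulon table with summary
statistics, including the intergenic-enrichment binomial test.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .differential_expression import DEGRecord
from .genome_model import Gene, GenomeAnnotation, intergenic_fraction, \
    is_intergenic
from .motif_analysis import MotifHit
from .peak_calling import Peak

PROMOTER_WINDOW = (-1000, 50)   # bp relative to the start codon
OPERON_MAX_GAP = 50             # bp between same-strand neighbours
OPERON_MAX_EXPR_DELTA = 1.0     # log2 units of mean expression

CATEGORIES = ("intergenic_upstream", "intergenic_divergent",
              "intragenic_upstream", "intragenic", "rna_locus")


@dataclass
class PeakContext:
    peak: Peak
    category: str
    candidate_genes: list[tuple[Gene, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "intergenic_divergent":
            strands = {g.strand for g, _ in self.candidate_genes}
            if len(self.candidate_genes) != 2 or strands != {"+", "-"}:
                raise ValueError(
                    "divergent context needs exactly two opposite-strand "
                    "candidates")


@dataclass
class RegulonRecord:
    locus_id: str
    peak_id: str                    # empty for indirect targets
    distance: int | None            # signed summit-to-start bp
    operon_role: str                # single | first_in_operon | in_operon
    log2fc: float
    mode: str                       # activated | repressed
    matched_site: str | None
    regulation: str                 # direct | direct_via_operon | indirect


def summit_to_start_distance(peak: Peak, gene: Gene) -> int:
    """Signed distance from summit to the start codon, along the gene.

    Negative means the summit lies upstream of the start codon; the summit
    is converted to 1-based coordinates so a summit exactly on the start
    codon gives 0.
    """
    summit_1b = peak.summit + 1
    if gene.strand == "+":
        return summit_1b - gene.start
    return gene.end - summit_1b


def _in_window(d: int, window: tuple[int, int]) -> bool:
    return window[0] <= d <= window[1]


def classify_peaks(peaks: list[Peak], ann: GenomeAnnotation,
                   window: tuple[int, int] = PROMOTER_WINDOW
                   ) -> list[PeakContext]:
    """Assign each peak to one of five mutually exclusive context classes.

    Priority: a summit inside an rRNA/tRNA gene is ``rna_locus``; an
    intergenic summit between a divergent gene pair with both starts in the
    window is ``intergenic_divergent``; an intergenic summit in the window
    of at least one start is ``intergenic_upstream``; an intragenic summit
    in the window of a downstream gene's start is ``intragenic_upstream``;
    anything else is ``intragenic``.
    """
    contexts = []
    for peak in peaks:
        summit = peak.summit
        host_rna = [g for g in ann.genes
                    if g.kind in ("rRNA", "tRNA")
                    and g.start - 1 <= summit < g.end]
        in_window = [(g, summit_to_start_distance(peak, g))
                     for g in ann.genes]
        in_window = [(g, d) for g, d in in_window if _in_window(d, window)]
        intergenic = is_intergenic(ann, summit)

        if host_rna:
            g = host_rna[0]
            ctx = PeakContext(peak, "rna_locus",
                              [(g, summit_to_start_distance(peak, g))])
        elif intergenic:
            minus = [(g, d) for g, d in in_window if g.strand == "-"]
            plus = [(g, d) for g, d in in_window if g.strand == "+"]
            divergent = None
            if minus and plus:
                # facing starts: the - gene left of the summit, + gene right
                left = [(g, d) for g, d in minus if g.end - 1 <= summit]
                right = [(g, d) for g, d in plus if g.start - 1 >= summit]
                if left and right:
                    lg = min(left, key=lambda t: abs(t[1]))
                    rg = min(right, key=lambda t: abs(t[1]))
                    divergent = [lg, rg]
            if divergent:
                ctx = PeakContext(peak, "intergenic_divergent", divergent)
            elif in_window:
                ctx = PeakContext(peak, "intergenic_upstream",
                                  _nearest_per_strand(in_window))
            else:
                ctx = PeakContext(peak, "intragenic", [])
        else:
            # a start codon within the window counts, whether the summit sits
            # in the upstream neighbour or just past this gene's own start
            downstream = in_window
            if downstream:
                ctx = PeakContext(peak, "intragenic_upstream",
                                  _nearest_per_strand(downstream))
            else:
                ctx = PeakContext(peak, "intragenic", [])
        contexts.append(ctx)
    return contexts


def _nearest_per_strand(cands: list[tuple[Gene, int]]
                        ) -> list[tuple[Gene, int]]:
    """Keep the nearest candidate start per strand (ties: keep nearer only)."""
    out = []
    for strand in "+-":
        sub = [t for t in cands if t[0].strand == strand]
        if sub:
            out.append(min(sub, key=lambda t: abs(t[1])))
    return out


def infer_operons(ann: GenomeAnnotation, expression: dict[str, float],
                  max_gap: int = OPERON_MAX_GAP,
                  max_expr_delta: float = OPERON_MAX_EXPR_DELTA
                  ) -> list[list[str]]:
    """Operons from gene spacing and expression similarity.

    Maximal runs of adjacent same-strand genes separated by fewer than
    ``max_gap`` bp whose neighbouring mean expression levels differ by at
    most ``max_expr_delta`` log2 units.  Lists are in transcription order
    (rightmost gene first on the minus strand); singletons are dropped.
    """
    missing = [g.locus_id for g in ann.genes if g.locus_id not in expression]
    if missing:
        raise ValueError(f"expression levels missing for {missing[:5]}...")
    operons: list[list[str]] = []
    run: list[Gene] = []

    def flush() -> None:
        if len(run) > 1:
            loci = [g.locus_id for g in run]
            operons.append(loci if run[0].strand == "+" else loci[::-1])

    def log2_expr(locus: str) -> float:
        return float(np.log2(max(expression[locus], 1e-9)))

    for gene in ann.genes:
        if run:
            prev = run[-1]
            gap = gene.start - prev.end - 1
            same = gene.strand == prev.strand
            co = abs(log2_expr(gene.locus_id)
                     - log2_expr(prev.locus_id)) <= max_expr_delta
            if same and gap < max_gap and co:
                run.append(gene)
                continue
            flush()
        run = [gene]
    flush()
    return operons


def _operon_roles(operons: list[list[str]]) -> dict[str, str]:
    roles = {}
    for op in operons:
        roles[op[0]] = "first_in_operon"
        for locus in op[1:]:
            roles[locus] = "in_operon"
    return roles


def assign_regulation(peaks_ctx: list[PeakContext],
                      degs: list[DEGRecord],
                      operons: list[list[str]],
                      window: tuple[int, int] = PROMOTER_WINDOW,
                      ann: GenomeAnnotation | None = None,
                      motif_hits: dict[str, list[MotifHit]] | None = None
                      ) -> list[RegulonRecord]:
    """Label every DEG as direct, direct-via-operon, or indirect.

    A DEG whose start codon has a consensus summit within the promoter
    window is direct; a DEG inside an operon whose first gene is direct is
    direct-via-operon; every other DEG is indirect.  A divergent peak can
    make both flanking DEGs direct.  ``motif_hits`` (peak_id -> hits inside
    the peak) supplies the best matched site per direct record, preferring
    exact dyad hits over PWM hits, then lowest p.
    """
    deg_by_locus = {r.locus_id: r for r in degs if r.mode != "none"}
    if ann is not None:
        known = {g.locus_id for g in ann.genes}
        offenders = sorted(set(deg_by_locus) - known)
        if offenders:
            raise ValueError(f"DEG loci absent from annotation: {offenders}")

    roles = _operon_roles(operons)
    # locus -> (peak, distance) for summits in the promoter window
    bound: dict[str, tuple[Peak, int]] = {}
    for ctx in peaks_ctx:
        for gene, dist in ctx.candidate_genes:
            if not _in_window(dist, window):
                continue
            cur = bound.get(gene.locus_id)
            if cur is None or abs(dist) < abs(cur[1]):
                bound[gene.locus_id] = (ctx.peak, dist)

    def best_site(peak: Peak) -> str | None:
        hits = (motif_hits or {}).get(peak.peak_id, [])
        if not hits:
            return None
        best = min(hits, key=lambda h: (h.kind != "dyad", h.p, h.position))
        return best.matched

    records = []
    first_gene_direct = {op[0]: op for op in operons
                         if op[0] in bound and op[0] in deg_by_locus}
    via_operon = {}
    for first, op in first_gene_direct.items():
        for follower in op[1:]:
            via_operon[follower] = first

    for locus, deg in sorted(deg_by_locus.items()):
        role = roles.get(locus, "single")
        if locus in bound:
            peak, dist = bound[locus]
            records.append(RegulonRecord(
                locus, peak.peak_id, dist, role, deg.log2fc, deg.mode,
                best_site(peak), "direct"))
        elif locus in via_operon:
            peak, _dist = bound[via_operon[locus]]
            records.append(RegulonRecord(
                locus, peak.peak_id, None, role, deg.log2fc, deg.mode,
                best_site(peak), "direct_via_operon"))
        else:
            records.append(RegulonRecord(
                locus, "", None, role, deg.log2fc, deg.mode, None,
                "indirect"))
    return records


def summarize_regulon(records: list[RegulonRecord],
                      peaks_ctx: list[PeakContext],
                      ann: GenomeAnnotation) -> dict:
    """Counts, intergenic enrichment, and peak-height comparison.

    Intergenic enrichment is an exact binomial test of the observed
    intergenic summit fraction against the genome's intergenic base
    fraction; peak heights between intergenic and intragenic summits are
    compared with a Mann-Whitney U test (normal approximation).
    """
    by_reg = {"direct": 0, "direct_via_operon": 0, "indirect": 0}
    modes = {"activated": 0, "repressed": 0}
    direct_peaks = set()
    for r in records:
        by_reg[r.regulation] += 1
        if r.regulation == "direct":
            modes[r.mode] += 1
            direct_peaks.add(r.peak_id)

    # divergent pairs among direct records: one peak, two strands
    peak_strand: dict[str, set[str]] = {}
    strand_of = {g.locus_id: g.strand for g in ann.genes}
    for r in records:
        if r.regulation == "direct" and r.peak_id:
            peak_strand.setdefault(r.peak_id, set()).add(
                strand_of.get(r.locus_id, "?"))
    divergent_pairs = sum(1 for s in peak_strand.values() if s == {"+", "-"})

    categories = {c: 0 for c in CATEGORIES}
    heights_inter, heights_intra = [], []
    for ctx in peaks_ctx:
        categories[ctx.category] += 1
        if is_intergenic(ann, ctx.peak.summit):
            heights_inter.append(ctx.peak.height)
        else:
            heights_intra.append(ctx.peak.height)

    n_peaks = len(peaks_ctx)
    n_inter = len(heights_inter)
    frac_genome = intergenic_fraction(ann)
    binom_p = float(stats.binomtest(
        n_inter, n_peaks, frac_genome, alternative="greater").pvalue) \
        if n_peaks else 1.0
    if heights_inter and heights_intra:
        u_p = float(stats.mannwhitneyu(
            heights_inter, heights_intra, alternative="two-sided",
            method="asymptotic").pvalue)
    else:
        u_p = 1.0

    return {
        "n_direct": by_reg["direct"],
        "n_direct_via_operon": by_reg["direct_via_operon"],
        "n_indirect": by_reg["indirect"],
        "n_direct_total": by_reg["direct"] + by_reg["direct_via_operon"],
        "n_degs": sum(by_reg.values()),
        "direct_activated": modes["activated"],
        "direct_repressed": modes["repressed"],
        "distinct_direct_peaks": len(direct_peaks),
        "divergent_pairs": divergent_pairs,
        "category_counts": categories,
        "n_peaks": n_peaks,
        "intergenic_peaks": n_inter,
        "intergenic_peak_fraction": n_inter / n_peaks if n_peaks else 0.0,
        "intergenic_genome_fraction": frac_genome,
        "intergenic_enrichment_p": binom_p,
        "height_mannwhitney_p": u_p,
    }


def venn_counts(set_a: set[str], set_b: set[str], set_c: set[str]
                ) -> dict[str, int]:
    """The 7 region cardinalities of a 3-set Venn diagram."""
    return {
        "a_only": len(set_a - set_b - set_c),
        "b_only": len(set_b - set_a - set_c),
        "c_only": len(set_c - set_a - set_b),
        "ab_only": len((set_a & set_b) - set_c),
        "ac_only": len((set_a & set_c) - set_b),
        "bc_only": len((set_b & set_c) - set_a),
        "abc": len(set_a & set_b & set_c),
    }


def regulon_table(records: list[RegulonRecord],
                  ann: GenomeAnnotation | None = None) -> pd.DataFrame:
    name_of = {g.locus_id: (g.name or "") for g in ann.genes} if ann else {}
    strand_of = {g.locus_id: g.strand for g in ann.genes} if ann else {}
    rows = [{
        "peak_id": r.peak_id, "locus_id": r.locus_id,
        "gene_name": name_of.get(r.locus_id, ""),
        "strand": strand_of.get(r.locus_id, ""),
        "distance": r.distance if r.distance is not None else "",
        "operon_role": r.operon_role, "log2fc": r.log2fc, "mode": r.mode,
        "matched_site": r.matched_site or "", "regulation": r.regulation,
    } for r in records]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged reference table (hand-transcribed published regulon table)
# ---------------------------------------------------------------------------

def load_table1(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged CgrA direct-regulon reference table.

    One row per (peak, gene) pair as published: peak id, locus, strand,
    signed summit-to-start distance (blank for non-first operon members),
    operon role, log2 fold change, and the predicted binding sequence.
    """
    if path is None:
        ref = importlib.resources.files("regulonseq").joinpath(
            "data/table1_fixture.tsv")
        with importlib.resources.as_file(ref) as p:
            return _read_table1(p)
    return _read_table1(Path(path))


def _read_table1(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"peak_id": str},
                     keep_default_na=False)
    required = {"peak_id", "locus_id", "strand", "distance", "role",
                "log2fc", "site_seq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    df["log2fc"] = df["log2fc"].astype(float)
    return df
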
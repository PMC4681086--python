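"""Synthetic paired ChIP-seq / RNA-seq data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for a small high-GC bacterial replicon:

* an i.i.d. nucleotide sequence at 70.5 % GC;
* densely packed genes (~90 % of bases intragenic) organised into operonic
  clusters (same strand, gaps under 50 bp) separated by intergenic gaps of
  at least 200 bp;
* palindromic dyad binding sites (TGTGA-N6-TCACA by default) written into
  intergenic promoter regions, with IP coverage enriched over a Poisson
  background at each site;
* negative-binomial read counts for wild-type and TF-deletion samples, with
  fold changes planted on site-adjacent (direct) genes, their operon
  followers, and a set of site-free (indirect) genes.

Everything is deterministic under a fixed seed, and the returned
:class:`SyntheticTruth` is sufficient to score recall and precision of every
downstream stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome_model import Gene, GenomeAnnotation, write_fasta, write_gff

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults are the reference desk-scale conditions: a 200 kb replicon at
    70.5 % GC with 120 genes covering ~90 % of the sequence, 20 planted
    dyad sites at 8-fold IP enrichment, three replicates per condition and
    planted |log2 fold changes| of 2 on direct targets.
    """

    seed: int = 1
    genome_length: int = 200_000
    n_genes: int = 120
    gc_content: float = 0.705
    intragenic_fraction: float = 0.90
    operon_fraction: float = 0.5
    operon_gap: int = 40
    min_intergenic_gap: int = 200
    n_sites: int = 20
    site_left: str = "TGTGA"
    site_right: str = "TCACA"
    site_spacer: int = 6
    intragenic_site_fraction: float = 0.0
    enrichment: float = 8.0
    background_depth: float = 0.25
    fragment_size: int = 150
    n_replicates: int = 3
    direct_fraction: float = 0.8
    lfc_direct: float = 2.0
    repressed_fraction: float = 0.25
    n_indirect: int = 10
    nb_dispersion: float = 0.05
    mean_expression: float = 300.0

    def __post_init__(self) -> None:
        for name in ("gc_content", "intragenic_fraction", "operon_fraction",
                     "direct_fraction", "intragenic_site_fraction",
                     "repressed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.enrichment < 1:
            raise ValueError("enrichment must be at least 1")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if self.operon_gap >= 50:
            raise ValueError("operon_gap must be below 50 bp")

    @property
    def site_width(self) -> int:
        return len(self.site_left) + self.site_spacer + len(self.site_right)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset (the recovery oracle)."""

    planted_sites: list[tuple[int, str, str]] = field(default_factory=list)
    direct_targets: dict[str, float] = field(default_factory=dict)
    indirect_targets: dict[str, float] = field(default_factory=dict)
    operon_targets: dict[str, float] = field(default_factory=dict)
    operons: list[list[str]] = field(default_factory=list)
    expression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.direct_targets) & set(self.indirect_targets):
            raise ValueError("direct and indirect target sets overlap")

    @property
    def all_planted(self) -> dict[str, float]:
        """Every gene with a planted fold change, whatever its route."""
        return {**self.direct_targets, **self.operon_targets,
                **self.indirect_targets}


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.array(list("ACGT")), size=n, p=probs)


def generate_genome(cfg: SimulationConfig
                    ) -> tuple[GenomeAnnotation, SyntheticTruth]:
    """Generate an annotated genome with planted dyad sites.

    Genes are laid out as transcription units (singletons and operons of
    2-4 genes) left to right; units alternate strand randomly.  Unit gaps
    are at least ``min_intergenic_gap`` with the leftover intergenic budget
    spread over them at random; gaps inside operons are below
    ``operon_gap``.  Raises ``ValueError`` when the requested gene content
    cannot be packed into the genome.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.genome_length

    # --- transcription-unit structure -----------------------------------
    n_operon_genes = int(round(cfg.operon_fraction * cfg.n_genes))
    operon_sizes: list[int] = []
    remaining = n_operon_genes
    while remaining >= 2:
        size = int(rng.integers(2, 5))
        size = min(size, remaining)
        operon_sizes.append(size)
        remaining -= size
    n_singles = cfg.n_genes - sum(operon_sizes)
    units: list[int] = [1] * n_singles + operon_sizes
    rng.shuffle(units)

    # --- base budget ------------------------------------------------------
    gene_budget = int(round(cfg.intragenic_fraction * L))
    raw_lengths = rng.lognormal(mean=0.0, sigma=0.35, size=cfg.n_genes)
    lengths = np.maximum(
        150, np.round(raw_lengths / raw_lengths.sum() * gene_budget)
    ).astype(int)
    operon_gaps_total = 0
    operon_gap_draws: list[int] = []
    for size in units:
        for _ in range(size - 1):
            g = int(rng.integers(10, cfg.operon_gap))
            operon_gap_draws.append(g)
            operon_gaps_total += g
    n_unit_gaps = len(units) + 1
    slack = L - int(lengths.sum()) - operon_gaps_total \
        - cfg.min_intergenic_gap * n_unit_gaps
    if slack < 0:
        raise ValueError(
            f"infeasible packing: gene content + minimum gaps exceed the "
            f"{L} bp genome by {-slack} bp")
    extra = rng.multinomial(slack, np.full(n_unit_gaps, 1 / n_unit_gaps))
    unit_gaps = cfg.min_intergenic_gap + extra

    # --- placement --------------------------------------------------------
    genes: list[Gene] = []
    operons: list[list[str]] = []
    gene_idx = 0
    pos = int(unit_gaps[0])
    for ui, size in enumerate(units):
        strand = "+" if rng.random() < 0.5 else "-"
        unit_loci: list[str] = []
        for k in range(size):
            length = int(lengths[gene_idx])
            locus = f"SYN_{gene_idx + 1:04d}"
            genes.append(Gene(locus, pos + 1, pos + length, strand))
            unit_loci.append(locus)
            pos += length
            if k < size - 1:
                pos += operon_gap_draws.pop(0)
            gene_idx += 1
        if size > 1:
            # transcription order: leftmost first on +, rightmost first on -
            operons.append(unit_loci if strand == "+" else unit_loci[::-1])
        pos += int(unit_gaps[ui + 1])

    ann = GenomeAnnotation(L, genes)

    # --- sequence with planted sites -------------------------------------
    seq = _random_sequence(rng, L, cfg.gc_content)
    truth = SyntheticTruth(operons=operons)
    first_of_unit = {op[0] for op in operons}
    in_operon_not_first = {g for op in operons for g in op[1:]}
    eligible = [g for g in genes
                if g.locus_id not in in_operon_not_first]
    rng.shuffle(eligible)
    n_intra = int(round(cfg.intragenic_site_fraction * cfg.n_sites))
    site_genes = eligible[:cfg.n_sites]
    if len(site_genes) < cfg.n_sites:
        raise ValueError("not enough eligible genes for the requested sites")

    half = cfg.site_width // 2
    for i, gene in enumerate(site_genes):
        if i < n_intra:
            # mid-gene site, to exercise context classification
            centre = (gene.start - 1 + gene.end) // 2
        else:
            offset = int(rng.integers(60, cfg.min_intergenic_gap - half - 10))
            if gene.strand == "+":
                centre = gene.start - 1 - offset
            else:
                centre = gene.end - 1 + offset
        spacer = "".join(_random_sequence(rng, cfg.site_spacer, cfg.gc_content))
        motif = cfg.site_left + spacer + cfg.site_right
        strand = gene.strand
        planted = motif if strand == "+" else reverse_complement(motif)
        start = centre - half
        seq[start:start + cfg.site_width] = list(planted)
        truth.planted_sites.append((centre, motif, strand))

    # --- expression levels and planted fold changes -----------------------
    levels = rng.lognormal(np.log(cfg.mean_expression), 1.0, size=len(units))
    unit_of: dict[str, float] = {}
    gi = 0
    for ui, size in enumerate(units):
        for _ in range(size):
            unit_of[genes[gi].locus_id] = float(levels[ui])
            gi += 1
    truth.expression = unit_of

    operon_of_first = {op[0]: op for op in operons}
    # only promoter-proximal sites can make a gene a direct target
    promoter_site_genes = site_genes[n_intra:]
    n_direct = int(round(cfg.direct_fraction * len(promoter_site_genes)))
    direct_genes = promoter_site_genes[:n_direct]
    for gene in direct_genes:
        sign = -1.0 if rng.random() >= cfg.repressed_fraction else 1.0
        lfc = sign * cfg.lfc_direct
        truth.direct_targets[gene.locus_id] = lfc
        for follower in operon_of_first.get(gene.locus_id, [])[1:]:
            truth.operon_targets[follower] = lfc

    # indirect targets must have no site anywhere in their promoter window
    # (not merely "no site of their own": windows span neighbouring gaps)
    def promoter_has_site(g: Gene) -> bool:
        for c, _m, _s in truth.planted_sites:
            d = (c + 1 - g.start) if g.strand == "+" else (g.end - c - 1)
            if -1000 <= d <= 50:
                return True
        return False

    with_site = {g.locus_id for g in site_genes}
    with_site |= set(truth.operon_targets)
    with_site |= {g.locus_id for g in genes if promoter_has_site(g)}
    candidates = [g.locus_id for g in genes if g.locus_id not in with_site]
    rng.shuffle(candidates)
    for locus in candidates[:cfg.n_indirect]:
        sign = -1.0 if rng.random() >= cfg.repressed_fraction else 1.0
        truth.indirect_targets[locus] = sign * cfg.lfc_direct

    ann.sequence = "".join(seq)
    return ann, truth


# ---------------------------------------------------------------------------
# ChIP-seq coverage
# ---------------------------------------------------------------------------

def simulate_coverage(ann: GenomeAnnotation, truth: SyntheticTruth,
                      cfg: SimulationConfig
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate per-base IP and input coverage tracks.

    Fragment starts are Poisson(``background_depth``) per base; coverage is
    the running sum over ``fragment_size`` bases, so the expected background
    coverage is ``background_depth * fragment_size``.  At each planted site
    the IP track receives extra fragments centred on the site so the expected
    summit height is ``enrichment`` times the background.
    """
    rng = np.random.default_rng(cfg.seed + 101)
    L, frag = ann.genome_length, cfg.fragment_size
    kernel = np.ones(frag)

    def coverage_from_starts(starts: np.ndarray) -> np.ndarray:
        return np.convolve(starts, kernel)[:L]

    input_starts = rng.poisson(cfg.background_depth, L).astype(float)
    ip_starts = rng.poisson(cfg.background_depth, L).astype(float)

    n_extra_mean = (cfg.enrichment - 1.0) * cfg.background_depth * frag
    for centre, _motif, _strand in truth.planted_sites:
        n_extra = rng.poisson(n_extra_mean)
        jitter = rng.integers(-frag // 4, frag // 4 + 1, size=n_extra)
        starts = np.clip(centre - frag // 2 + jitter, 0, L - 1)
        np.add.at(ip_starts, starts, 1.0)

    return coverage_from_starts(ip_starts), coverage_from_starts(input_starts)


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def simulate_counts(ann: GenomeAnnotation, truth: SyntheticTruth,
                    cfg: SimulationConfig) -> pd.DataFrame:
    """Simulate a gene-by-sample NB count matrix (wt and mutant replicates).

    Per-gene means are proportional to gene length times the unit expression
    level; mutant means are multiplied by ``2**lfc`` for planted targets;
    library sizes vary by +/-30 %.  Returns a DataFrame indexed by locus_id
    with a ``length_bp`` column followed by count columns ``wt_i`` /
    ``mut_i``.
    """
    rng = np.random.default_rng(cfg.seed + 202)
    n = cfg.n_replicates
    samples = [f"wt_{i + 1}" for i in range(n)] + \
              [f"mut_{i + 1}" for i in range(n)]
    size_factors = rng.uniform(0.7, 1.3, size=2 * n)

    planted = truth.all_planted
    loci, lengths = [], []
    mu = np.zeros((len(ann.genes), 2 * n))
    for gi, gene in enumerate(ann.genes):
        loci.append(gene.locus_id)
        lengths.append(gene.length)
        base = truth.expression.get(gene.locus_id, cfg.mean_expression)
        base *= gene.length / 1000.0
        lfc = planted.get(gene.locus_id, 0.0)
        for j in range(2 * n):
            cond_mean = base * (2.0 ** lfc if j >= n else 1.0)
            mu[gi, j] = cond_mean * size_factors[j]

    alpha = cfg.nb_dispersion
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=np.where(mu > 0, mu * alpha, 0))
    else:
        lam = mu
    counts = rng.poisson(lam)

    df = pd.DataFrame(counts, index=pd.Index(loci, name="locus_id"),
                      columns=samples)
    df.insert(0, "length_bp", lengths)
    return df


# ---------------------------------------------------------------------------
# On-disk dataset
# ---------------------------------------------------------------------------

def write_bedgraph(track: np.ndarray, path: str | Path,
                   seqid: str = "chr1") -> None:
    """Write a dense per-base track as run-length-encoded bedGraph."""
    vals = np.asarray(track)
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(vals)]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{seqid}\t{s}\t{e}\t{vals[s]:g}\n")


def read_bedgraph(path: str | Path, genome_length: int) -> np.ndarray:
    track = np.zeros(genome_length)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            _chrom, s, e, v = line.split("\t")
            track[int(s):int(e)] = float(v)
    return track


def write_dataset(outdir: str | Path, cfg: SimulationConfig) -> SyntheticTruth:
    """Generate a full dataset and write every artefact under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann, truth = generate_genome(cfg)
    ip, inp = simulate_coverage(ann, truth, cfg)
    counts = simulate_counts(ann, truth, cfg)

    write_fasta(ann.sequence, outdir / "genome.fasta", ann.seqid)
    write_gff(ann, outdir / "annotation.gff3")
    write_bedgraph(ip, outdir / "ip.bedgraph", ann.seqid)
    write_bedgraph(inp, outdir / "input.bedgraph", ann.seqid)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    cfg.to_yaml(outdir / "config.yaml")

    sites = pd.DataFrame(truth.planted_sites,
                         columns=["position", "motif", "strand"])
    sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    rows = [(g, lfc, "direct") for g, lfc in truth.direct_targets.items()]
    rows += [(g, lfc, "operon") for g, lfc in truth.operon_targets.items()]
    rows += [(g, lfc, "indirect") for g, lfc in truth.indirect_targets.items()]
    pd.DataFrame(rows, columns=["locus_id", "log2fc", "route"]).to_csv(
        outdir / "truth_targets.tsv", sep="\t", index=False)
    with open(outdir / "truth_operons.tsv", "w") as fh:
        for op in truth.operons:
            fh.write("\t".join(op) + "\n")
    return truth
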
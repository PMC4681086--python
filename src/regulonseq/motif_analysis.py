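"""CRP-family dyad motif analysis: PWM scanning with exact p-values,
flexible-spacer dyad search, and consensus construction.

The binding site modelled here is the classic CRP-type palindrome
TGTGA-N6-TCACA (16 bp), scanned either as an exact spaced dyad
(:func:`scan_dyad`, also with the relaxed GTG-N8-CAC / GTG-N10-CAC cores)
or as a position weight matrix scored in log-odds bits against the genome
background.  PWM per-position p-values are exact: the null score
distribution of a background-random sequence is computed by column-wise
convolution of the integer-discretised score distribution, the same
dynamic programme FIMO uses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ALPHABET = "ACGT"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
DEFAULT_RESOLUTION = 0.001    # bits; score discretisation of the p-value DP

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# IUPAC code for each non-empty subset of bases
_IUPAC = {frozenset(s): c for s, c in [
    ("A", "A"), ("C", "C"), ("G", "G"), ("T", "T"),
    ("AG", "R"), ("CT", "Y"), ("CG", "S"), ("AT", "W"),
    ("GT", "K"), ("AC", "M"), ("CGT", "B"), ("AGT", "D"),
    ("ACT", "H"), ("ACG", "V"), ("ACGT", "N")]}


@dataclass(frozen=True)
class DyadSpec:
    """Two conserved half-sites separated by unconstrained spacers."""

    left: str
    right: str
    spacers: frozenset[int]

    def __post_init__(self) -> None:
        for word in (self.left, self.right):
            if not word or any(c not in ALPHABET for c in word):
                raise ValueError(f"half-site {word!r} must be over ACGT")
        if any(s < 0 for s in self.spacers):
            raise ValueError("spacer lengths must be >= 0")

    def width(self, spacer: int) -> int:
        return len(self.left) + spacer + len(self.right)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.right) == self.left


#: The strict CRP/CgrA palindrome and its relaxed cores.
CRP_DYAD = DyadSpec("TGTGA", "TCACA", frozenset({6}))
GTG_N8_CAC = DyadSpec("GTG", "CAC", frozenset({8}))
GTG_N10_CAC = DyadSpec("GTG", "CAC", frozenset({10}))


@dataclass(frozen=True)
class MotifHit:
    position: int              # 0-based forward-strand leftmost base
    strand: str                # + or -
    matched: str               # site as read on the hit strand
    score: float               # log-odds bits (PWM) or width (dyad)
    p: float = 1.0
    kind: str = "pwm"          # pwm | dyad


@dataclass
class PWM:
    """Per-column base probabilities plus the background model."""

    columns: np.ndarray        # width x 4, rows sum to 1
    background: np.ndarray     # length-4 probabilities
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != 4 \
                or self.columns.shape[0] < 1:
            raise ValueError("PWM needs a width x 4 column matrix")
        if not np.allclose(self.columns.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.columns.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """Width x 4 log2(column / background), in bits."""
        with np.errstate(divide="ignore"):
            return np.log2(self.columns) - np.log2(self.background)


def genome_background(sequence: str) -> np.ndarray:
    """Mononucleotide frequencies of a genome sequence."""
    counts = np.array([sequence.count(c) for c in ALPHABET], dtype=float)
    if counts.sum() == 0:
        raise ValueError("sequence contains no ACGT bases")
    return counts / counts.sum()


def build_pwm(sites: list[str], pseudocount: float = 0.5,
              background: np.ndarray | None = None) -> PWM:
    """Count matrix from pre-aligned equal-length sites, plus pseudocounts."""
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    width = len(sites[0])
    counts = np.zeros((width, 4))
    for s in sites:
        if len(s) != width:
            raise ValueError("sites have unequal lengths")
        for j, c in enumerate(s.upper()):
            if c not in _INDEX:
                raise ValueError(f"non-ACGT base {c!r} in site {s!r}")
            counts[j, _INDEX[c]] += 1
    cols = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    return PWM(cols, bg, pseudocount)


@dataclass
class PValueTable:
    """Exact null distribution of the discretised PWM score.

    ``pvalue[k]`` is P(S >= offset + k) for a background-random word, with
    scores measured in units of ``resolution`` bits.
    """

    resolution: float
    offset: int                       # integer score of index 0
    tail: np.ndarray = field(repr=False)   # survival probabilities

    def p_of(self, score_bits: float) -> float:
        k = int(round(score_bits / self.resolution)) - self.offset
        if k <= 0:
            return 1.0
        if k >= len(self.tail):
            return float(self.tail[-1])
        return float(self.tail[k])


def pwm_pvalue_table(pwm: PWM,
                     resolution: float = DEFAULT_RESOLUTION) -> PValueTable:
    """Exact score distribution by column-wise convolution."""
    lo = pwm.log_odds
    ints = np.round(lo / resolution).astype(np.int64)
    probs = np.array([1.0])
    offset = 0
    for j in range(pwm.width):
        col = ints[j]
        cmin, cmax = int(col.min()), int(col.max())
        new = np.zeros(len(probs) + cmax - cmin)
        for b in range(4):
            new[col[b] - cmin:col[b] - cmin + len(probs)] += \
                probs * pwm.background[b]
        probs = new
        offset += cmin
    # survival function: P(S >= s) for every achievable integer score
    tail = np.cumsum(probs[::-1])[::-1]
    return PValueTable(resolution, offset, tail)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for c, i in _INDEX.items():
        out[arr == ord(c)] = i
    return out


def _strand_scores(enc: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Window scores over one strand; NaN where a window has non-ACGT."""
    width = lo.shape[0]
    n = len(enc) - width + 1
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(width):
        base = enc[j:j + n]
        valid &= base >= 0
        scores += lo[j, np.clip(base, 0, 3)]
    scores[~valid] = np.nan
    return scores


def scan_pwm(pwm: PWM, seq: str, p_threshold: float = 0.01,
             table: PValueTable | None = None) -> list[MotifHit]:
    """Scan both strands; report hits with exact per-position p <= threshold.

    Minus-strand hits are reported at the forward coordinate of their
    leftmost matched base.
    """
    if len(seq) < pwm.width:
        return []
    if table is None:
        table = pwm_pvalue_table(pwm)
    width = pwm.width
    enc_f = _encode(seq)
    enc_r = _encode(reverse_complement(seq))
    hits = []
    for strand, enc in (("+", enc_f), ("-", enc_r)):
        scores = _strand_scores(enc, pwm.log_odds)
        for q in np.flatnonzero(~np.isnan(scores)):
            p = table.p_of(scores[q])
            if p <= p_threshold:
                pos = int(q) if strand == "+" else len(seq) - width - int(q)
                word = seq[pos:pos + width].upper()
                matched = word if strand == "+" else reverse_complement(word)
                hits.append(MotifHit(pos, strand, matched,
                                     float(scores[q]), p, "pwm"))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_dyad(spec: DyadSpec, seq: str) -> list[MotifHit]:
    """Exact-match spaced-dyad search on both strands; overlaps reported."""
    seq = seq.upper()
    hits = []
    for spacer in sorted(spec.spacers):
        width = spec.width(spacer)
        for strand in "+-":
            left, right = (spec.left, spec.right) if strand == "+" else (
                reverse_complement(spec.right), reverse_complement(spec.left))
            pat = re.compile(f"(?=({left}.{{{spacer}}}{right}))")
            for m in pat.finditer(seq):
                word = m.group(1)
                matched = word if strand == "+" else reverse_complement(word)
                hits.append(MotifHit(m.start(), strand, matched,
                                     float(width), 1.0, "dyad"))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def consensus_from_sites(sites: list[str]) -> tuple[str, np.ndarray]:
    """Majority consensus and per-column information content in bits.

    When the two most frequent bases of a column are within 10 % frequency
    of each other the column gets the IUPAC ambiguity code for the tied set.
    """
    if not sites:
        raise ValueError("no sites")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("sites have unequal lengths")
    n = len(sites)
    consensus = []
    ic = np.zeros(width)
    for j in range(width):
        freqs = np.array(
            [sum(s[j].upper() == c for s in sites) for c in ALPHABET]) / n
        order = np.argsort(freqs)[::-1]
        top = {ALPHABET[order[0]]}
        for b in order[1:]:
            if freqs[order[0]] - freqs[b] <= 0.10 and freqs[b] > 0:
                top.add(ALPHABET[b])
        consensus.append(_IUPAC[frozenset(top)])
        nz = freqs[freqs > 0]
        ic[j] = 2.0 + float((nz * np.log2(nz)).sum())
    return "".join(consensus), ic


# ---------------------------------------------------------------------------
# MEME minimal text format
# ---------------------------------------------------------------------------

def write_meme(pwm: PWM, path: str | Path, name: str = "motif_1") -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{c} {pwm.background[i]:.5f}"
                          for i, c in enumerate(ALPHABET)) + "\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                 f"nsites= 20 E= 0\n")
        for row in pwm.columns:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_meme(path: str | Path) -> PWM:
    background = np.full(4, 0.25)
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    for line in lines:
        if line.startswith("Background letter frequencies"):
            parts = next(lines).split()
            background = np.array([float(parts[i * 2 + 1]) for i in range(4)])
        elif line.startswith("letter-probability matrix"):
            m = re.search(r"w=\s*(\d+)", line)
            width = int(m.group(1)) if m else None
            while True:
                row = next(lines, "").split()
                if len(row) != 4:
                    break
                rows.append([float(v) for v in row])
    if not rows or (width is not None and len(rows) != width):
        raise ValueError("malformed MEME motif file")
    return PWM(np.array(rows), background)


def read_sites_fasta(path: str | Path) -> list[str]:
    from Bio import SeqIO
    return [str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")]


def hits_table(hits: list[MotifHit], peak_id: str = "") -> list[dict]:
    return [{"peak_id": peak_id, "position": h.position, "strand": h.strand,
             "matched": h.matched, "score": h.score, "p": h.p,
             "kind": h.kind} for h in hits]
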
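"""TF binding-site peak calling from IP versus input coverage.

Two independent background models are run over the same 300 bp sliding
windows (75 bp step) and only peaks found by both are retained:

* **Poisson caller** — a local-lambda model: the expected window count is
  the maximum of the genome-wide input mean and the input means over 1 kb,
  5 kb and 10 kb windows centred on the test window (input scaled to IP
  depth), and a window is significant when the upper Poisson tail of the
  observed IP count is at or below the cutoff (default 1e-5).
* **GC-aware NB caller** — windows are stratified into GC-content bins; in
  each bin a negative-binomial background is fitted to the input window
  counts by method of moments, with a robust (median-based) per-bin IP/input
  depth ratio so GC-dependent amplification bias in the IP does not
  masquerade as enrichment.

Coverage tracks are per-base fragment pile-ups, so window sums are divided
by the fragment size to recover approximate fragment counts before any
Poisson/NB tail probability is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .genome_model import Interval

logger = logging.getLogger(__name__)

DEFAULT_P_CUTOFF = 1e-5
DEFAULT_WINDOW = 300          # "band width" of the reference caller
DEFAULT_STEP = 75
LOCAL_WINDOWS = (1_000, 5_000, 10_000)
_P_FLOOR = 1e-300             # keep p-values in (0, 1]


@dataclass(frozen=True)
class Peak:
    """An enriched interval with its summit and both background p-values."""

    interval: Interval
    summit: int                # 0-based position of the IP maximum
    height: float              # IP coverage at the summit
    p_poisson: float = 1.0
    p_nb: float = 1.0
    fold_enrichment: float = 1.0
    peak_id: str = ""

    def __post_init__(self) -> None:
        if not self.interval.start <= self.summit < self.interval.end:
            raise ValueError("summit outside peak interval")


def _window_counts(track: np.ndarray, window: int, step: int,
                   fragment_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Window start positions and fragment-count-unit window sums."""
    L = len(track)
    csum = np.concatenate(([0.0], np.cumsum(track)))
    starts = np.arange(0, max(L - window, 0) + 1, step)
    counts = (csum[starts + window] - csum[starts]) / fragment_size
    return starts, counts


def _local_means(track: np.ndarray, starts: np.ndarray, window: int,
                 span: int, fragment_size: int) -> np.ndarray:
    """Mean window-count over ``span``-wide regions centred on each window."""
    L = len(track)
    csum = np.concatenate(([0.0], np.cumsum(track)))
    centres = starts + window // 2
    lo = np.clip(centres - span // 2, 0, L)
    hi = np.clip(centres + span // 2, 0, L)
    per_base = (csum[hi] - csum[lo]) / np.maximum(hi - lo, 1)
    return per_base * window / fragment_size


def _merge_significant(starts: np.ndarray, window: int,
                       flags: np.ndarray) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent significant windows into regions."""
    regions: list[list[int]] = []
    for s in starts[flags]:
        if regions and s <= regions[-1][1]:
            regions[-1][1] = s + window
        else:
            regions.append([int(s), int(s + window)])
    return [(s, e) for s, e in regions]


def _build_peaks(regions: list[tuple[int, int]], ip: np.ndarray,
                 starts: np.ndarray, window: int,
                 pvals: np.ndarray, expected: np.ndarray,
                 fragment_size: int, which: str) -> list[Peak]:
    peaks = []
    for s, e in regions:
        summit = s + int(np.argmax(ip[s:e]))        # leftmost maximum
        overlapping = (starts < e) & (starts + window > s)
        p_best = float(max(pvals[overlapping].min(), _P_FLOOR))
        exp_cov = float(expected[overlapping].mean()) \
            * fragment_size / window
        fe = float(ip[summit] / exp_cov) if exp_cov > 0 else float("inf")
        kw = {"p_poisson": p_best} if which == "poisson" else {"p_nb": p_best}
        peaks.append(Peak(Interval(s, e), summit, float(ip[summit]),
                          fold_enrichment=fe, **kw))
    return peaks


def call_peaks_poisson(ip: np.ndarray, input_: np.ndarray,
                       p_cutoff: float = DEFAULT_P_CUTOFF,
                       window: int = DEFAULT_WINDOW,
                       step: int = DEFAULT_STEP,
                       fragment_size: int = 150) -> list[Peak]:
    """Local-lambda Poisson peak caller (IP vs depth-scaled input)."""
    if len(ip) != len(input_):
        raise ValueError("ip and input tracks differ in length")
    if input_.sum() <= 0:
        raise ValueError("input track has no signal")
    ratio = ip.sum() / input_.sum()
    scaled_input = input_ * ratio

    starts, ip_counts = _window_counts(ip, window, step, fragment_size)
    lam = np.full_like(ip_counts,
                       scaled_input.mean() * window / fragment_size)
    for span in LOCAL_WINDOWS:
        lam = np.maximum(
            lam, _local_means(scaled_input, starts, window, span,
                              fragment_size))
    pvals = stats.poisson.sf(np.ceil(ip_counts) - 1, lam)
    flags = pvals <= p_cutoff
    regions = _merge_significant(starts, window, flags)
    return _build_peaks(regions, ip, starts, window, pvals, lam,
                        fragment_size, "poisson")


def window_gc(sequence: str, starts: np.ndarray, window: int) -> np.ndarray:
    """GC fraction of each window of ``sequence``."""
    is_gc = np.frombuffer(sequence.encode(), dtype=np.uint8)
    is_gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(float)
    csum = np.concatenate(([0.0], np.cumsum(is_gc)))
    return (csum[starts + window] - csum[starts]) / window


def call_peaks_nb_gc(ip: np.ndarray, input_: np.ndarray, sequence: str,
                     p_cutoff: float = DEFAULT_P_CUTOFF,
                     gc_bins: int = 10,
                     window: int = DEFAULT_WINDOW,
                     step: int = DEFAULT_STEP,
                     fragment_size: int = 150,
                     min_bin_windows: int = 20) -> list[Peak]:
    """GC-stratified negative-binomial peak caller.

    Bins with fewer than ``min_bin_windows`` windows are merged into the
    nearest populated bin (logged as a warning).  Within a bin, if the input
    window counts show no overdispersion the NB fit degenerates to Poisson.
    """
    if len(ip) != len(input_) or len(sequence) != len(ip):
        raise ValueError("ip, input and sequence lengths differ")
    starts, ip_counts = _window_counts(ip, window, step, fragment_size)
    _, in_counts = _window_counts(input_, window, step, fragment_size)
    gc = window_gc(sequence, starts, window)

    edges = np.linspace(gc.min(), gc.max() + 1e-9, gc_bins + 1)
    labels = np.clip(np.digitize(gc, edges) - 1, 0, gc_bins - 1)
    # merge sparse bins into the nearest populated neighbour
    counts_per_bin = np.bincount(labels, minlength=gc_bins)
    populated = np.flatnonzero(counts_per_bin >= min_bin_windows)
    if populated.size == 0:
        populated = np.array([int(np.argmax(counts_per_bin))])
    remap = {}
    for b in range(gc_bins):
        if counts_per_bin[b] and b not in populated:
            nearest = populated[np.argmin(np.abs(populated - b))]
            logger.warning(
                "GC bin %d has %d windows (<%d); merged into bin %d",
                b, counts_per_bin[b], min_bin_windows, nearest)
            remap[b] = int(nearest)
    labels = np.array([remap.get(int(b), int(b)) for b in labels])

    pvals = np.ones_like(ip_counts)
    expected = np.ones_like(ip_counts)
    for b in np.unique(labels):
        mask = labels == b
        inp = in_counts[mask]
        ipc = ip_counts[mask]
        med_in = max(np.median(inp), 1e-9)
        c = np.median(ipc) / med_in      # robust per-bin depth ratio
        bg = inp * c
        m = float(bg.mean())
        v = float(bg.var(ddof=1)) if bg.size > 1 else 0.0
        k = np.ceil(ipc) - 1
        if v > m > 0:
            r = m * m / (v - m)
            pvals[mask] = stats.nbinom.sf(k, r, r / (r + m))
        elif m > 0:
            pvals[mask] = stats.poisson.sf(k, m)
        expected[mask] = max(m, 1e-9)

    flags = pvals <= p_cutoff
    regions = _merge_significant(starts, window, flags)
    return _build_peaks(regions, ip, starts, window, pvals, expected,
                        fragment_size, "nb")


def consensus_peaks(a: list[Peak], b: list[Peak]) -> list[Peak]:
    """Peaks from ``a`` overlapping (>= 1 bp) any peak in ``b``.

    The retained peak keeps caller A's interval and summit and carries the
    best NB p-value among overlapping B peaks.
    """
    out = []
    for pa in sorted(a, key=lambda p: p.interval.start):
        hits = [pb for pb in b if pa.interval.overlaps(pb.interval)]
        if hits:
            out.append(replace(pa, p_nb=min(pb.p_nb for pb in hits)))
    return out


def number_peaks(peaks: list[Peak], prefix: str = "peak") -> list[Peak]:
    return [replace(p, peak_id=f"{prefix}_{i}")
            for i, p in enumerate(sorted(peaks, key=lambda p: p.interval.start),
                                  start=1)]


# ---------------------------------------------------------------------------
# narrowPeak / BED output
# ---------------------------------------------------------------------------

def write_narrowpeak(peaks: list[Peak], path: str | Path,
                     seqid: str = "chr1") -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, start=1):
            name = p.peak_id or f"peak_{i}"
            score = int(round(-10 * np.log10(max(p.p_poisson, _P_FLOOR))))
            fh.write("\t".join(map(str, [
                seqid, p.interval.start, p.interval.end, name, score, ".",
                f"{p.fold_enrichment:.4f}", f"{p.p_poisson:.4g}", -1,
                p.summit - p.interval.start])) + "\n")


def read_narrowpeak(path: str | Path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            start, end = int(f[1]), int(f[2])
            summit = start + int(f[9]) if len(f) > 9 and int(f[9]) >= 0 \
                else (start + end) // 2
            peaks.append(Peak(Interval(start, end), summit, 0.0,
                              p_poisson=float(f[7]) if len(f) > 7 else 1.0,
                              fold_enrichment=float(f[6]) if len(f) > 6 else 1.0,
                              peak_id=f[3] if len(f) > 3 else ""))
    return peaks


def write_bed(peaks: list[Peak], path: str | Path, seqid: str = "chr1") -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, start=1):
            name = p.peak_id or f"peak_{i}"
            fh.write(f"{seqid}\t{p.interval.start}\t{p.interval.end}"
                     f"\t{name}\t0\t.\n")
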
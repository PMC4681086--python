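"""Differential expression between wild-type and TF-deletion count samples.

The caller is a deliberately transparent negative-binomial Wald test:
median-of-ratios (geometric) library normalization, per-gene
method-of-moments dispersion with a floor, a log2 fold-change Wald statistic
and Benjamini-Hochberg FDR control.  A gene is declared differentially
expressed when |log2FC| >= 1.32 (fold change >= 2.5) at BH q < 0.05, and
genes whose mean normalized count stays below 10 in both conditions are not
tested at all.

Sign convention: the fold change is mutant over wild type, so a gene the
transcription factor *activates* has a negative log2FC (lower in the
deletion strain) and a *repressed* gene a positive one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

LFC_THRESHOLD = 1.32          # |log2FC| >= 1.32, i.e. fold change >= 2.5
Q_THRESHOLD = 0.05            # BH-adjusted p
MIN_COUNT = 10.0              # mean normalized count filter
DISPERSION_FLOOR = 0.01
DISPERSION_PRIOR_DF = 4       # weight of the across-genes dispersion prior
PSEUDOCOUNT = 0.5             # normalized units, for zero condition means


@dataclass
class CountMatrix:
    """Integer counts for genes x samples with condition labels."""

    counts: pd.DataFrame           # genes x samples, non-negative integers
    lengths: pd.Series             # gene lengths in bp, same index
    conditions: dict[str, str]     # sample -> {"wt", "mutant"}

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise ValueError("counts and lengths indexed differently")
        labels = [self.conditions[s] for s in self.counts.columns]
        for cond in ("wt", "mutant"):
            if labels.count(cond) < 2:
                raise ValueError(f"need >= 2 samples in condition {cond!r}")
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns
                if self.conditions[s] == condition]

    @classmethod
    def from_tsv(cls, path: str | Path,
                 conditions: dict[str, str] | None = None) -> "CountMatrix":
        """Read a counts TSV: locus_id, length_bp, then one column per sample.

        Without an explicit condition map, sample names starting with ``wt``
        map to wild type and everything else to mutant.
        """
        df = pd.read_csv(path, sep="\t", index_col="locus_id")
        lengths = df.pop("length_bp")
        if conditions is None:
            conditions = {s: ("wt" if s.startswith("wt") else "mutant")
                          for s in df.columns}
        return cls(df, lengths, conditions)


@dataclass
class DEGRecord:
    locus_id: str
    log2fc: float
    p: float
    q: float = 1.0
    mode: str = "none"             # activated | repressed | none
    tested: bool = True


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios library size factors, geometric mean 1.

    For each gene with all-positive counts, each sample's count is divided
    by the gene's geometric mean across samples; the per-sample median of
    those ratios is the size factor.
    """
    arr = cm.counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; filter the matrix "
            "or check the input")
    sub = arr[positive]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.log(sub) - log_geo
    factors = np.exp(np.median(ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads."""
    totals = cm.counts.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        bad = cm.counts.columns[totals == 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    lengths = cm.lengths.to_numpy(dtype=float)[:, None]
    return cm.counts / lengths / totals[None, :] * 1e9


def test_differential(cm: CountMatrix) -> list[DEGRecord]:
    """Per-gene NB Wald test of mutant vs wild type.

    Normalized counts are counts over size factors.  The per-gene NB
    dispersion alpha (var = mu + alpha mu^2) is estimated by pooled method
    of moments over the within-condition residuals, shrunk toward the
    median dispersion of the well-expressed genes (prior weight
    ``DISPERSION_PRIOR_DF`` pseudo-df, the usual moderated-statistic
    remedy for 3-vs-3 designs) and floored at 0.01.  The Wald statistic is
    log2FC over its delta-method standard error, with a two-sided t
    p-value at residual-plus-prior degrees of freedom; it converges to the
    normal reference as replication grows.
    """
    sf = size_factors(cm)
    norm = cm.counts / sf
    wt_cols = cm.samples("wt")
    mut_cols = cm.samples("mutant")
    n_wt, n_mut = len(wt_cols), len(mut_cols)

    wt = norm[wt_cols].to_numpy(dtype=float)
    mut = norm[mut_cols].to_numpy(dtype=float)
    m_wt, m_mut = wt.mean(axis=1), mut.mean(axis=1)
    # pooled within-condition variance on normalized counts
    ss = ((wt - m_wt[:, None]) ** 2).sum(axis=1) \
        + ((mut - m_mut[:, None]) ** 2).sum(axis=1)
    pooled_var = ss / (n_wt + n_mut - 2)
    pooled_mean = (n_wt * m_wt + n_mut * m_mut) / (n_wt + n_mut)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = (pooled_var - pooled_mean) / pooled_mean ** 2
    alpha_raw = np.where(np.isfinite(alpha_raw),
                         np.maximum(alpha_raw, 0.0), 0.0)

    low = (m_wt < MIN_COUNT) & (m_mut < MIN_COUNT)
    resid_df = n_wt + n_mut - 2
    prior = float(np.median(alpha_raw[~low])) if (~low).any() else 0.0
    alpha = (resid_df * alpha_raw + DISPERSION_PRIOR_DF * prior) \
        / (resid_df + DISPERSION_PRIOR_DF)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    a_wt = np.where(m_wt > 0, m_wt, PSEUDOCOUNT)
    a_mut = np.where(m_mut > 0, m_mut, PSEUDOCOUNT)
    log2fc = np.log2(a_mut / a_wt)

    var_wt = (a_wt + alpha * a_wt ** 2) / n_wt
    var_mut = (a_mut + alpha * a_mut ** 2) / n_mut
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt((var_wt / a_wt ** 2 + var_mut / a_mut ** 2) / ln2sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(z), df=resid_df + DISPERSION_PRIOR_DF)

    records = []
    for i, locus in enumerate(cm.counts.index):
        if low[i]:
            records.append(DEGRecord(locus, 0.0, 1.0, tested=False))
        else:
            records.append(DEGRecord(locus, float(log2fc[i]),
                                     float(min(p[i], 1.0))))
    return records


def call_degs(records: list[DEGRecord],
              lfc_threshold: float = LFC_THRESHOLD,
              q_threshold: float = Q_THRESHOLD) -> list[DEGRecord]:
    """Fill in BH q-values and the activated/repressed/none call.

    BH runs over the tested genes only; untested (low-count) genes keep
    q = 1.  A gene is a DEG iff |log2FC| >= ``lfc_threshold`` and
    q < ``q_threshold``; negative log2FC means TF-activated.
    """
    tested = [r for r in records if r.tested]
    if tested:
        pvals = np.array([r.p for r in tested])
        if ((pvals < 0) | (pvals > 1)).any():
            raise ValueError("p-values outside [0, 1]")
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for r, q in zip(tested, qvals):
            r.q = float(q)
    for r in records:
        if r.tested and abs(r.log2fc) >= lfc_threshold and r.q < q_threshold:
            r.mode = "activated" if r.log2fc < 0 else "repressed"
        else:
            r.mode = "none"
    return records


def run_deg_analysis(cm: CountMatrix,
                     lfc_threshold: float = LFC_THRESHOLD,
                     q_threshold: float = Q_THRESHOLD) -> list[DEGRecord]:
    return call_degs(test_differential(cm), lfc_threshold, q_threshold)


def deg_table(records: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.locus_id, r.log2fc, r.p, r.q, r.mode) for r in records],
        columns=["locus_id", "log2fc", "p", "q", "mode"],
    ).set_index("locus_id")


def read_conditions_yaml(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ValueError("condition map must be a sample -> condition mapping")
    return {str(k): str(v) for k, v in mapping.items()}
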
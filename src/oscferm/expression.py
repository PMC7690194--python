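"""TPM quantification, TMM normalization, fold changes, DEG filtering and
oscillation-phase pattern calls.

Expression over one oscillation cycle is sampled at five time points,
three on the falling stage and two on the rising stage.  Genes sort into
two opposite phase patterns: type I peaks on the rising stage and bottoms
on the falling stage (tracking growth), type II the mirror image
(tracking the stress/lag phase); everything else is unclassified.

The differential-expression filter applies the conventional thresholds
(BH-adjusted p < 0.001 and |log2 fold change| >= 1) on top of an exact
binomial two-library test of each gene's count split, with TMM-scaled
effective library sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "PatternCall",
    "tpm",
    "tmm_factors",
    "fold_change",
    "deg_filter",
    "classify_pattern",
]

DEG_ALPHA = 0.001
DEG_LFC_MIN = 1.0
PATTERN_MIN_FOLD = 2.0
FC_PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Gene x sample read counts with gene lengths and stage labels."""

    genes: list[str]
    lengths: np.ndarray  # bp
    counts: np.ndarray  # genes x samples, non-negative ints
    times: list  # time point labels (h)
    stages: list[str]  # "rising" | "falling" per sample
    truth_patterns: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(self.lengths <= 0):
            raise ValueError("gene lengths must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.genes), len(self.times)):
            raise ValueError("counts must be genes x samples")
        if len(self.stages) != len(self.times):
            raise ValueError("one stage label per sample required")
        for s in self.stages:
            if s not in ("rising", "falling"):
                raise ValueError(f"stage label {s!r} not 'rising'/'falling'")

    @property
    def sample_names(self) -> list[str]:
        return [f"{t}h" for t in self.times]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.genes, columns=self.sample_names)
        df.insert(0, "length_bp", self.lengths.astype(int))
        return df


@dataclass(frozen=True)
class PatternCall:
    gene: str
    label: str  # "typeI" | "typeII" | "unclassified"
    max_sample: str
    min_sample: str
    fold: float


def tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalized counts scaled to 1e6.

    Per sample, rate_g = count_g / length_g and
    TPM_g = rate_g / sum(rate) * 1e6, so every column sums to one million.
    """
    rate = cm.counts / cm.lengths[:, None]
    colsum = rate.sum(axis=0)
    if np.any(colsum == 0):
        bad = [cm.sample_names[i] for i in np.flatnonzero(colsum == 0)]
        raise ValueError(f"all-zero sample(s): {bad}")
    vals = rate / colsum[None, :] * 1e6
    return pd.DataFrame(vals, index=cm.genes, columns=cm.sample_names)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float) -> float:
    """Weighted trimmed log2 ratio of one sample against the reference.

    Follows the published TMM recipe: genes expressed in both libraries,
    30% two-sided trim on M (log ratio), 5% on A (log abundance),
    inverse-asymptotic-variance weights.
    """
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(M) & np.isfinite(A) & np.isfinite(w)
    M, A, w = M[finite], A[finite], w[finite]
    if M.size == 0:
        return 1.0
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_m, hi_m = np.floor(n * 0.3) + 1, n + 1 - (np.floor(n * 0.3) + 1)
    lo_a, hi_a = np.floor(n * 0.05) + 1, n + 1 - (np.floor(n * 0.05) + 1)
    rank_m = stats.rankdata(M)
    rank_a = stats.rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        return 1.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0**f)


def tmm_factors(counts: np.ndarray, ref_sample: int | None = None) -> np.ndarray:
    """Trimmed-mean-of-M-values scale factors, geometric mean 1.

    ``ref_sample`` defaults to the library whose upper quartile of scaled
    counts is closest to the mean upper quartile.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a genes x samples matrix with >= 2 samples")
    n_samples = counts.shape[1]
    lib = counts.sum(axis=0).astype(float)
    if np.any(lib == 0):
        raise ValueError("library with zero total counts")
    expressed = (counts > 0).sum(axis=0)
    if np.any(expressed <= 1):
        warnings.warn("degenerate library (<=1 expressed gene); factors set to 1")
        return np.ones(n_samples)
    if ref_sample is None:
        uq = np.array(
            [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(n_samples)]
        )
        ref_sample = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [
            _tmm_pair(counts[:, j], counts[:, ref_sample], lib[j], lib[ref_sample])
            for j in range(n_samples)
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def fold_change(
    tpm_df: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    pseudocount: float = FC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene ratio (TPM_a + c)/(TPM_b + c) and its log2."""
    for s in (sample_a, sample_b):
        if s not in tpm_df.columns:
            raise KeyError(f"sample {s!r} not in TPM matrix")
    ratio = (tpm_df[sample_a] + pseudocount) / (tpm_df[sample_b] + pseudocount)
    return pd.DataFrame(
        {"ratio": ratio, "log2_fc": np.log2(ratio)}, index=tpm_df.index
    )


def deg_filter(
    cm: CountMatrix,
    sample_a: str,
    sample_b: str,
    factors: np.ndarray | None = None,
    alpha: float = DEG_ALPHA,
    lfc_min: float = DEG_LFC_MIN,
) -> pd.DataFrame:
    """Two-library differential-expression calls at fixed thresholds.

    Each gene's count is split between the two libraries; an exact
    binomial test against the null proportion implied by the TMM-scaled
    effective library sizes yields a p-value, BH-adjusted across genes.
    A gene is significant iff p_adj < ``alpha`` and |log2FC| >=
    ``lfc_min``.
    """
    names = cm.sample_names
    ia, ib = names.index(sample_a), names.index(sample_b)
    if factors is None:
        factors = tmm_factors(cm.counts)
    lib = cm.counts.sum(axis=0).astype(float) * np.asarray(factors, dtype=float)
    na, nb = lib[ia], lib[ib]
    p0 = na / (na + nb)
    ca = cm.counts[:, ia].astype(int)
    cb = cm.counts[:, ib].astype(int)
    total = ca + cb
    pvals = np.ones(len(cm.genes))
    for g in np.flatnonzero(total > 0):
        pvals[g] = stats.binomtest(int(ca[g]), int(total[g]), p0).pvalue
    padj = multipletests(pvals, method="fdr_bh")[1]
    log2fc = np.log2(((ca + 0.5) / na) / ((cb + 0.5) / nb))
    sig = (padj < alpha) & (np.abs(log2fc) >= lfc_min)
    return pd.DataFrame(
        {
            "count_a": ca,
            "count_b": cb,
            "log2_fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "significant": sig,
        },
        index=cm.genes,
    )


def classify_pattern(
    tpm_df: pd.DataFrame,
    stages: list[str],
    min_fold: float = PATTERN_MIN_FOLD,
    pseudocount: float = FC_PSEUDOCOUNT,
) -> list[PatternCall]:
    """Call each gene's oscillation-phase expression pattern.

    type I: TPM maximum at a rising-stage sample and minimum at a
    falling-stage sample with max/min fold >= ``min_fold``; type II the
    mirror; otherwise unclassified.  The call depends only on the ranking
    of a within-sample-normalized quantity, so it is invariant to
    per-sample rescaling.
    """
    if len(stages) != tpm_df.shape[1]:
        raise ValueError("one stage label per sample required")
    for s in stages:
        if s not in ("rising", "falling"):
            raise ValueError(f"stage label {s!r} not 'rising'/'falling'")
    stages = list(stages)
    calls: list[PatternCall] = []
    vals = tpm_df.to_numpy(dtype=float)
    cols = list(tpm_df.columns)
    imax = np.argmax(vals, axis=1)
    imin = np.argmin(vals, axis=1)
    fold = (vals.max(axis=1) + pseudocount) / (vals.min(axis=1) + pseudocount)
    for g, gene in enumerate(tpm_df.index):
        label = "unclassified"
        if fold[g] >= min_fold:
            smax, smin = stages[imax[g]], stages[imin[g]]
            if smax == "rising" and smin == "falling":
                label = "typeI"
            elif smax == "falling" and smin == "rising":
                label = "typeII"
        calls.append(
            PatternCall(
                gene=str(gene),
                label=label,
                max_sample=cols[imax[g]],
                min_sample=cols[imin[g]],
                fold=float(fold[g]),
            )
        )
    return calls
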
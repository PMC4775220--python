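"""Negative-binomial differential enrichment of RIP over IgG control.

For each detected peak, fragment counts per sample are compared between the
two conditions with a conditional exact test under a negative-binomial
model, after median-of-ratios size-factor correction for sequencing depth.
Peaks with Benjamini-Hochberg FDR below the threshold *and* more
(normalized) reads in the RIP condition are reported as binding sites.

Dispersion is estimated per peak by the method of moments on normalized
counts and stabilised across peaks with a mean-dispersion trend
a0 + a1/mu; the final per-peak value is the maximum of the individual
estimate and the trend, a deliberately conservative choice for the 2 + 2
replicate design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeModel
from .peaks import Peak
from .simulate import CONTROL, RIP, FragmentSet

RIP_UP = "RIP_up"
CONTROL_UP = "control_up"


@dataclass
class PeakCountMatrix:
    """Integer fragment counts per peak (rows) per sample (columns)."""

    peak_ids: list[str]
    sample_ids: list[str]
    conditions: list[str]
    counts: np.ndarray
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.peak_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match peak/sample lists")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def condition_columns(self, condition: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.conditions) if c == condition])


def count_in_peaks(
    peaks: list[Peak], fragment_sets: list[FragmentSet]
) -> PeakCountMatrix:
    """Count fragments whose midpoint falls in each peak.

    Midpoint assignment guarantees every fragment is counted in at most one
    peak; peaks must therefore be disjoint (the caller's detector merges
    overlapping runs, so overlap here indicates a contract violation).
    """
    by_chrom: dict[str, list[tuple[int, Peak]]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append((i, p))
    for chrom, items in by_chrom.items():
        items.sort(key=lambda t: t[1].start)
        for (_, a), (_, b) in zip(items, items[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping peaks on {chrom}: [{a.start},{a.end}) and "
                    f"[{b.start},{b.end})"
                )

    counts = np.zeros((len(peaks), len(fragment_sets)), dtype=np.int64)
    for j, fs in enumerate(fragment_sets):
        for chrom, items in by_chrom.items():
            mids = fs.midpoints(chrom)
            if mids.size == 0:
                continue
            starts = np.array([p.start for _, p in items])
            ends = np.array([p.end for _, p in items])
            idx = np.searchsorted(starts, mids, side="right") - 1
            ok = (idx >= 0) & (mids < ends[np.clip(idx, 0, None)])
            for local_i, n in zip(*np.unique(idx[ok], return_counts=True)):
                counts[items[int(local_i)][0], j] += int(n)
    return PeakCountMatrix(
        peak_ids=[f"peak_{i + 1}" for i in range(len(peaks))],
        sample_ids=[fs.sample_id for fs in fragment_sets],
        conditions=[fs.condition for fs in fragment_sets],
        counts=counts,
    )


def bin_count_matrix(
    fragment_sets: list[FragmentSet], model: GenomeModel, bin_size: int = 2000
) -> np.ndarray:
    """Fragment-midpoint counts in genome-wide bins (for size-factor fitting).

    Size factors estimated from a handful of detected peaks are biased when
    most peaks are genuinely enriched — the median ratio then absorbs the
    enrichment itself. Genome-wide bins are overwhelmingly background, so
    the median ratio estimates relative sequencing depth.
    """
    rows = []
    for chrom, length in model.chromosomes.items():
        edges = np.arange(0, length + bin_size, bin_size)
        mat = np.zeros((len(edges) - 1, len(fragment_sets)), dtype=np.int64)
        for j, fs in enumerate(fragment_sets):
            mids = fs.midpoints(chrom)
            if mids.size:
                mat[:, j] = np.histogram(mids, bins=edges)[0]
        rows.append(mat)
    return np.vstack(rows)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (the library-size correction).

    s_j = median over rows i of counts[i, j] / geometric_mean(counts[i, :]),
    taken over rows whose geometric mean is positive.
    """
    counts = np.asarray(counts, dtype=np.float64)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no row with all-positive counts; cannot estimate size factors")
    log_gm = np.log(counts[positive]).mean(axis=1, keepdims=True)
    ratios = counts[positive] / np.exp(log_gm)
    return np.median(ratios, axis=0)


def estimate_dispersion(
    counts: np.ndarray, s: np.ndarray, conditions: list[str]
) -> np.ndarray:
    """Per-peak NB dispersion: max(method-of-moments estimate, fitted trend).

    The raw moment estimate (v - mu) / mu^2 from normalized counts (pooled
    within-condition variance) is unbiased but extremely noisy with two
    replicates per condition, so a trend a0 + a1/mu is fitted across peaks
    by least squares on the *raw* (possibly negative) estimates — fitting
    only positive estimates would bias the trend upward — and each peak
    receives the maximum of its own truncated estimate and the trend.
    """
    counts = np.asarray(counts, dtype=np.float64)
    conds = np.asarray(conditions)
    q = counts / np.asarray(s)[None, :]
    groups = [np.flatnonzero(conds == c) for c in dict.fromkeys(conditions)]
    for g in groups:
        if g.size < 2:
            raise ValueError("need >= 2 replicates per condition for dispersion")
    mu = q.mean(axis=1)
    num = np.zeros(len(q))
    dof = 0
    for g in groups:
        num += q[:, g].var(axis=1, ddof=1) * (g.size - 1)
        dof += g.size - 1
    v = num / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (v - mu) / mu**2, 0.0)
    alpha_i = np.maximum(raw, 0.0)

    valid = mu > 0
    trend = np.zeros(len(q))
    if valid.sum() >= 2:
        X = np.column_stack([np.ones(valid.sum()), 1.0 / mu[valid]])
        coef, *_ = np.linalg.lstsq(X, raw[valid], rcond=None)
        trend[valid] = np.maximum(0.0, coef[0] + coef[1] / mu[valid])
    return np.maximum(alpha_i, trend)


def _sum_pmf(total_mean: float, total_var: float, k: np.ndarray) -> np.ndarray:
    """pmf of a condition's count sum, NB-matched to (mean, var); Poisson if var<=mean."""
    if total_var <= total_mean * (1 + 1e-12):
        return stats.poisson.pmf(k, total_mean)
    r = total_mean**2 / (total_var - total_mean)
    p = r / (r + total_mean)
    return stats.nbinom.pmf(k, r, p)


def nb_exact_test(
    k_rip: np.ndarray,
    k_control: np.ndarray,
    s_rip: np.ndarray,
    s_control: np.ndarray,
    alpha: float,
) -> float:
    """Two-sided conditional exact test on the split of the total count.

    Conditional on the total K, every split (a, K - a) of the summed counts
    between conditions is assigned the product of the NB likelihoods of the
    two condition sums at the common concentration implied by the size
    factors; the p-value is the total probability of splits no more likely
    than the observed one, normalized by the probability of the total.
    """
    k_rip = np.asarray(k_rip, dtype=np.int64)
    k_control = np.asarray(k_control, dtype=np.int64)
    obs_a = int(k_rip.sum())
    K = obs_a + int(k_control.sum())
    if K == 0:
        return 1.0
    s_a = np.asarray(s_rip, dtype=float)
    s_b = np.asarray(s_control, dtype=float)
    q0 = K / (s_a.sum() + s_b.sum())
    mu_a = q0 * s_a.sum()
    mu_b = q0 * s_b.sum()
    var_a = mu_a + alpha * q0**2 * (s_a**2).sum()
    var_b = mu_b + alpha * q0**2 * (s_b**2).sum()
    a = np.arange(K + 1)
    p_split = _sum_pmf(mu_a, var_a, a) * _sum_pmf(mu_b, var_b, K - a)
    total = p_split.sum()
    if total <= 0:
        return 1.0
    p_obs = p_split[obs_a]
    p = p_split[p_split <= p_obs * (1 + 1e-9)].sum() / total
    return float(min(1.0, max(p, np.finfo(float).tiny)))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values
    return multipletests(p_values, method="fdr_bh")[1]


def run_enrichment(
    matrix: PeakCountMatrix,
    fdr_threshold: float = 0.05,
    size_factor_counts: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full per-peak differential test; returns a tidy results table.

    ``size_factor_counts`` optionally supplies a separate (e.g. genome-bin)
    count matrix for size-factor estimation; by default the peak matrix
    itself is used.
    """
    sf_source = matrix.counts if size_factor_counts is None else size_factor_counts
    s = size_factors(sf_source)
    matrix.size_factors = s
    rip_cols = matrix.condition_columns(RIP)
    ctrl_cols = matrix.condition_columns(CONTROL)
    if rip_cols.size == 0 or ctrl_cols.size == 0:
        raise ValueError("need samples in both conditions")
    alpha = estimate_dispersion(matrix.counts, s, matrix.conditions)
    q = matrix.counts / s[None, :]
    mean_rip = q[:, rip_cols].mean(axis=1)
    mean_ctrl = q[:, ctrl_cols].mean(axis=1)
    log2fc = np.log2((mean_rip + 0.5) / (mean_ctrl + 0.5))

    pvals = np.array(
        [
            nb_exact_test(
                matrix.counts[i, rip_cols],
                matrix.counts[i, ctrl_cols],
                s[rip_cols],
                s[ctrl_cols],
                float(alpha[i]),
            )
            for i in range(len(matrix.peak_ids))
        ]
    )
    fdr = bh_adjust(pvals)
    direction = np.where(mean_rip > mean_ctrl, RIP_UP, CONTROL_UP)
    significant = (fdr < fdr_threshold) & (direction == RIP_UP)
    return pd.DataFrame(
        {
            "peak_id": matrix.peak_ids,
            "base_mean_rip": mean_rip,
            "base_mean_control": mean_ctrl,
            "log2_fold_change": log2fc,
            "dispersion": alpha,
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
            "significant": significant,
        }
    )


def significant_peaks(
    results: pd.DataFrame, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Peaks with FDR strictly below threshold and RIP-direction enrichment."""
    if results.empty:
        return results
    keep = (results["fdr"] < fdr_threshold) & (results["direction"] == RIP_UP)
    return results[keep].reset_index(drop=True)
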
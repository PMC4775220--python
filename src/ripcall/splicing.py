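"""Splicing quantitation: Beta-binomial percent-spliced-in and qPCR ratios.

Percent spliced in (psi) is the fraction of transcripts including an
alternative exon, estimated from inclusion- vs exclusion-junction read
counts. Counts are first normalized by the number of junctions informative
for each isoform (a skipped exon has two inclusion junctions but one
exclusion junction), so isoform length does not bias the estimate; the
normalized counts then update a Beta prior.

The Bayes factor compares two conditions: the marginal likelihood of the
two binomial data sets under independent uniform-prior psi values versus a
single shared psi, both available in closed form through Beta functions.
This is a deliberately simple conjugate model, not a re-implementation of
the full MISO generative model; its role is the same gating decision
(report events with BF above a threshold, conventionally 2).

The qPCR side implements the delta-delta-Ct relative expression method and
isoform ratios summarised over replicate experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import betaln

#: alternative-splicing event categories (labels; the psi model covers SE/RI)
EVENT_TYPES = ("SE", "RI", "MXE", "A5SS", "A3SS", "AFE", "ALE", "T3UTR")

#: (inclusion, exclusion) junction counts per event type, where modelled
JUNCTIONS = {"SE": (2, 1), "RI": (2, 1)}


@dataclass(frozen=True)
class PsiPosterior:
    alpha: float
    beta: float
    mean: float
    ci_low: float
    ci_high: float


@dataclass
class SpliceEvent:
    """Junction counts for one event in two conditions."""

    event_id: str
    event_type: str
    inclusion: tuple[int, int]   # reads supporting inclusion, per condition
    exclusion: tuple[int, int]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        for v in (*self.inclusion, *self.exclusion):
            if v < 0 or int(v) != v:
                raise ValueError("junction counts must be non-negative integers")

    @property
    def has_psi_model(self) -> bool:
        return self.event_type in JUNCTIONS


def psi_posterior(
    inclusion_reads: float,
    exclusion_reads: float,
    n_inclusion_junctions: int = 2,
    n_exclusion_junctions: int = 1,
    prior: tuple[float, float] = (1.0, 1.0),
) -> PsiPosterior:
    """Beta posterior of psi from junction-normalized read counts."""
    if inclusion_reads < 0 or exclusion_reads < 0:
        raise ValueError("read counts must be non-negative")
    i_eff = inclusion_reads / n_inclusion_junctions
    e_eff = exclusion_reads / n_exclusion_junctions
    a = prior[0] + i_eff
    b = prior[1] + e_eff
    lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
    return PsiPosterior(a, b, a / (a + b), float(lo), float(hi))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def bayes_factor(
    inclusion_1: float,
    exclusion_1: float,
    inclusion_2: float,
    exclusion_2: float,
) -> float:
    """Closed-form Bayes factor for 'psi differs between conditions'.

    With effective counts (i, e) per condition (rounded half-up to
    integers), the marginal likelihood of condition c under psi ~ U(0,1)
    is the Beta function B(i_c + 1, e_c + 1); under a shared psi it is
    B(i_1 + i_2 + 1, e_1 + e_2 + 1). BF = product of independent marginals
    over the shared marginal.
    """
    i1 = _round_half_up(inclusion_1)
    e1 = _round_half_up(exclusion_1)
    i2 = _round_half_up(inclusion_2)
    e2 = _round_half_up(exclusion_2)
    if min(i1, e1, i2, e2) < 0:
        raise ValueError("effective counts must be non-negative")
    log_m1 = betaln(i1 + 1, e1 + 1) + betaln(i2 + 1, e2 + 1)
    log_m0 = betaln(i1 + i2 + 1, e1 + e2 + 1)
    return float(np.exp(log_m1 - log_m0))


def event_bayes_factor(event: SpliceEvent) -> float | None:
    """BF on junction-normalized counts; None for unmodelled event types."""
    if not event.has_psi_model:
        return None
    n_inc, n_exc = JUNCTIONS[event.event_type]
    return bayes_factor(
        event.inclusion[0] / n_inc,
        event.exclusion[0] / n_exc,
        event.inclusion[1] / n_inc,
        event.exclusion[1] / n_exc,
    )


def psi_table(events: list[SpliceEvent]):
    """Tidy per-event table: psi posterior mean per condition and BF."""
    import pandas as pd

    rows = []
    for ev in events:
        row = {
            "event_id": ev.event_id,
            "type": ev.event_type,
            "inclusion_1": ev.inclusion[0],
            "exclusion_1": ev.exclusion[0],
            "inclusion_2": ev.inclusion[1],
            "exclusion_2": ev.exclusion[1],
        }
        if ev.has_psi_model:
            n_inc, n_exc = JUNCTIONS[ev.event_type]
            for c in (0, 1):
                post = psi_posterior(
                    ev.inclusion[c], ev.exclusion[c], n_inc, n_exc
                )
                row[f"psi_{c + 1}"] = post.mean
            row["bayes_factor"] = event_bayes_factor(ev)
        else:
            row["psi_1"] = row["psi_2"] = row["bayes_factor"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR: delta-delta-Ct and isoform ratios

def delta_delta_ct(
    ct_target_s1: float,
    ct_ref_s1: float,
    ct_target_s2: float,
    ct_ref_s2: float,
) -> float:
    """Relative expression of sample 1 vs sample 2: 2 ** (-ddCt).

    ddCt = (Ct_target - Ct_reference) in sample 1 minus the same difference
    in sample 2; the reference gene (e.g. GAPDH) absorbs input differences.
    """
    for v in (ct_target_s1, ct_ref_s1, ct_target_s2, ct_ref_s2):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_s1 - ct_ref_s1) - (ct_target_s2 - ct_ref_s2)
    return float(2.0 ** (-ddct))


def isoform_ratio(
    rel_expr_isoform_a: np.ndarray,
    rel_expr_isoform_b: np.ndarray,
) -> tuple[float, float]:
    """Mean and sample sd of the per-replicate isoform expression ratio a/b.

    Requires at least three replicate experiments.
    """
    a = np.asarray(rel_expr_isoform_a, dtype=float)
    b = np.asarray(rel_expr_isoform_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate vectors must have equal length")
    if a.size < 3:
        raise ValueError("need >= 3 replicate experiments")
    if (b == 0).any():
        raise ValueError("zero denominator expression in a replicate")
    ratios = a / b
    return float(ratios.mean()), float(ratios.std(ddof=1))
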
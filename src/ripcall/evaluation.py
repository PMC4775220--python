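"""Recovery metrics of detected peaks against planted ground truth."""

from __future__ import annotations

from dataclasses import dataclass

from .peaks import Peak
from .simulate import PlantedSite


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """min(overlap/len_a, overlap/len_b); 0 when disjoint."""
    overlap = min(a_end, b_end) - max(a_start, b_start)
    if overlap <= 0:
        return 0.0
    return min(overlap / (a_end - a_start), overlap / (b_end - b_start))


@dataclass
class MatchResult:
    recall: float
    precision: float
    pairs: list[tuple[int, int]]          # (site index, peak index)
    matched_peaks: set[int]
    matched_sites: set[int]


def match_peaks_to_sites(
    peaks: list[Peak],
    sites: list[PlantedSite],
    min_reciprocal: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching by decreasing reciprocal overlap.

    recall = matched sites / all sites; precision = matched peaks / all
    peaks. Both are 1.0 on empty inputs of the respective denominator.
    """
    scored = []
    for si, site in enumerate(sites):
        for pi, peak in enumerate(peaks):
            if peak.chrom != site.chrom:
                continue
            ro = reciprocal_overlap(site.start, site.end, peak.start, peak.end)
            if ro >= min_reciprocal:
                scored.append((ro, si, pi))
    scored.sort(reverse=True)
    matched_sites: set[int] = set()
    matched_peaks: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, si, pi in scored:
        if si in matched_sites or pi in matched_peaks:
            continue
        matched_sites.add(si)
        matched_peaks.add(pi)
        pairs.append((si, pi))
    recall = len(matched_sites) / len(sites) if sites else 1.0
    precision = len(matched_peaks) / len(peaks) if peaks else 1.0
    return MatchResult(recall, precision, pairs, matched_peaks, matched_sites)
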
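"""Peak detection by Laplacian-of-Gaussian filtering of coverage.

The detector convolves the per-base coverage signal with the second
derivative of a Gaussian of bandwidth sigma (default 300 nt). A coverage
bump of width comparable to sigma produces a strongly negative filter
response; candidate peaks are maximal negative-response runs, bounded by
the flanking zero crossings, that contain a summit whose score (-response)
clears a threshold and whose mean coverage is high enough.

Because the kernel is mean-centred to sum exactly to zero, the response —
and hence the peak calls — are invariant to adding a constant to the
coverage, and scale linearly with the coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import oaconvolve

from .coverage import CoverageTrack

#: numerical guard for "response < 0": keeps zero-crossing boundaries stable
#: against float round-off from the FFT convolution
_NEG_EPS = 1e-12


@dataclass(frozen=True)
class LoGKernel:
    """Truncated, mean-centred second-derivative-of-Gaussian filter."""

    sigma: float
    radius: int
    weights: np.ndarray       # centred: sums to 0 exactly
    raw_weights: np.ndarray   # g''(x) before centring

    def __len__(self) -> int:
        return 2 * self.radius + 1


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    score: float
    mean_coverage: float

    def __post_init__(self) -> None:
        if not self.start <= self.summit < self.end:
            raise ValueError("summit outside peak interval")
        if self.score <= 0:
            raise ValueError("peak score must be positive")

    @property
    def width(self) -> int:
        return self.end - self.start


def log_kernel(sigma: float, radius_multiplier: float = 4.0) -> LoGKernel:
    """Second derivative of a Gaussian density with sd ``sigma``.

    w[x] = g(x) * (x^2 - sigma^2) / sigma^4 at integer offsets in
    [-radius, radius], radius = ceil(radius_multiplier * sigma); the
    truncated weights are then mean-centred so they sum to zero exactly.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if radius_multiplier < 4:
        raise ValueError("radius_multiplier must be >= 4 (truncation bias)")
    radius = int(np.ceil(radius_multiplier * sigma))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    raw = g * (x**2 - sigma**2) / sigma**4
    centered = raw - raw.mean()
    return LoGKernel(float(sigma), radius, centered, raw)


def convolve(track: CoverageTrack | np.ndarray, kernel: LoGKernel) -> np.ndarray:
    """Filter response: response[p] = sum_x w[x] * values[p + x].

    Edges are zero-padded; the kernel is symmetric, so this correlation
    equals the convolution computed by the overlap-add FFT routine. The
    first and last ``radius`` positions are then set to zero: there the
    response reflects the finite extent of the track rather than the
    signal (a constant track would otherwise look like a box edge), and
    zeroing them keeps the response of a constant track identically zero.
    """
    values = track.values if isinstance(track, CoverageTrack) else np.asarray(track)
    if len(values) <= 2 * kernel.radius:
        raise ValueError(
            f"track length {len(values)} must exceed kernel width {len(kernel)}"
        )
    response = oaconvolve(values, kernel.weights, mode="same")
    response[: kernel.radius] = 0.0
    response[-kernel.radius :] = 0.0
    return response


def adaptive_min_score(response: np.ndarray, mad_k: float = 6.0) -> float:
    """Score threshold k * MAD of the response over non-zero positions.

    Positions where the response is exactly zero (regions farther than the
    kernel radius from any covered base) carry no information about the
    background response scale and are excluded.
    """
    nz = response[np.abs(response) > _NEG_EPS]
    if nz.size == 0:
        return np.inf
    mad = float(np.median(np.abs(nz - np.median(nz))))
    return mad_k * mad


def _negative_runs(response: np.ndarray) -> list[tuple[int, int]]:
    neg = response < -_NEG_EPS
    if not neg.any():
        return []
    d = np.diff(neg.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if neg[0]:
        starts.insert(0, 0)
    if neg[-1]:
        ends.append(len(neg))
    return list(zip(starts, ends))


def call_peaks(
    response: np.ndarray,
    coverage: np.ndarray,
    min_score: float | None = None,
    min_coverage: float = 5.0,
    min_width: int = 50,
    merge_gap: int = 50,
    chrom: str = "chr1",
    mad_k: float = 6.0,
) -> list[Peak]:
    """Extract peaks from the filter response.

    A peak is a maximal negative-response run (runs separated by less than
    ``merge_gap`` are merged) that is at least ``min_width`` wide, has mean
    coverage >= ``min_coverage``, and contains a position with
    -response >= ``min_score``. When ``min_score`` is None it is set
    adaptively to ``mad_k`` times the MAD of the response. The summit is the
    most negative response position (leftmost on ties).
    """
    response = np.asarray(response, dtype=np.float64)
    coverage = np.asarray(coverage, dtype=np.float64)
    if response.shape != coverage.shape:
        raise ValueError("response and coverage must have the same length")
    if min_score is None:
        min_score = adaptive_min_score(response, mad_k)

    runs = _negative_runs(response)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    peaks: list[Peak] = []
    for s, e in merged:
        if e - s < min_width:
            continue
        window = response[s:e]
        summit_off = int(np.argmin(window))  # leftmost minimum
        score = -float(window[summit_off])
        if score < min_score:
            continue
        mean_cov = float(coverage[s:e].mean())
        if mean_cov < min_coverage:
            continue
        peaks.append(Peak(chrom, int(s), int(e), int(s + summit_off), score, mean_cov))
    return sorted(peaks, key=lambda p: (p.chrom, p.start))


def write_peaks_bed(peaks: list[Peak], path: str) -> None:
    """BED6; scores rescaled to [0, 1000] relative to the top peak."""
    top = max((p.score for p in peaks), default=1.0)
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i + 1}\t"
                f"{int(round(1000 * p.score / top))}\t.\n"
            )


def write_peaks_tsv(peaks: list[Peak], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tchrom\tstart\tend\tsummit\tscore\tmean_coverage\n")
        for i, p in enumerate(peaks):
            fh.write(
                f"peak_{i + 1}\t{p.chrom}\t{p.start}\t{p.end}\t{p.summit}\t"
                f"{p.score:.6g}\t{p.mean_coverage:.4f}\n"
            )


def read_peaks_tsv(path: str) -> list[Peak]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        Peak(r.chrom, int(r.start), int(r.end), int(r.summit),
             float(r.score), float(r.mean_coverage))
        for r in df.itertuples()
    ]
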
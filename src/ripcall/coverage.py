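"""Per-base fragment coverage tracks with optional reads-per-million scaling."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genome import GenomeModel
from .simulate import FragmentSet

RAW = "raw"
RPM = "RPM"


@dataclass
class CoverageTrack:
    """Dense per-base fragment depth for one chromosome."""

    chrom: str
    values: np.ndarray
    scale: str
    library_size: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


def build_coverage(
    fragments: FragmentSet, model: GenomeModel
) -> dict[str, CoverageTrack]:
    """Per-chromosome depth: values[p] = number of fragments covering p.

    Uses a difference array (+1 at start, -1 at end, cumulative sum), so the
    cost is O(fragments + genome length).
    """
    tracks: dict[str, CoverageTrack] = {}
    df = fragments.fragments
    for chrom, length in model.chromosomes.items():
        sub = df[df["chrom"] == chrom]
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        bad = (starts < 0) | (ends > length) | (ends <= starts)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"fragment [{starts[i]},{ends[i]}) of sample "
                f"{fragments.sample_id} outside {chrom} [0,{length})"
            )
        diff = np.zeros(length + 1, dtype=np.float64)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        values = np.cumsum(diff[:-1])
        tracks[chrom] = CoverageTrack(chrom, values, RAW, fragments.library_size)
    unknown = set(df["chrom"]) - set(model.chromosomes)
    if unknown:
        raise ValueError(f"fragments on unknown chromosome(s): {sorted(unknown)}")
    return tracks


def pooled_coverage(
    fragment_sets: list[FragmentSet], model: GenomeModel
) -> dict[str, CoverageTrack]:
    """Sum of raw coverage over samples (library sizes add)."""
    pooled: dict[str, CoverageTrack] = {}
    for fs in fragment_sets:
        for chrom, track in build_coverage(fs, model).items():
            if chrom in pooled:
                pooled[chrom].values += track.values
                pooled[chrom].library_size += track.library_size
            else:
                pooled[chrom] = track
    return pooled


def rpm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Scale raw depth to reads per million mapped fragments."""
    if track.scale != RAW:
        raise ValueError(f"track is already {track.scale}-scaled")
    if track.library_size <= 0:
        raise ValueError("library_size must be > 0 for RPM scaling")
    return replace(
        track, values=track.values * (1e6 / track.library_size), scale=RPM
    )


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """Run-length encoded 4-column bedGraph (0-based half-open)."""
    v = track.values
    change = np.flatnonzero(np.diff(v)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(v)]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            val = v[s]
            if val != 0:
                fh.write(f"{track.chrom}\t{s}\t{e}\t{val:g}\n")
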
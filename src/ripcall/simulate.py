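"""Synthetic RIP-seq data with planted binding sites.

The generator emulates the experimental design the pipeline targets: two
immunoprecipitation (RIP) replicates and two IgG control replicates of
paired-end fragments with mean length 200 nt, sharing a common background
over transcribed regions, with a set of planted windows whose fragment
density in the RIP samples is multiplied by a known enrichment factor.
Per-window fragment counts are negative-binomially dispersed (gamma-Poisson
mixture) around their expected value, so the differential count test
downstream sees realistic replicate-to-replicate overdispersion.

Everything is deterministic given the seed; per-sample randomness is drawn
from spawned substreams so the fragment sets of one sample do not depend on
how many other samples are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import CDS, INTRON, UTR3, UTR5, Gene, GenomeModel, Transcript

#: default region mix for planted sites, echoing the intron-heavy binding
#: profile of nuclear RNA-binding proteins (55% intron, 41% 3'UTR)
DEFAULT_REGION_MIX = {INTRON: 0.55, UTR3: 0.41, UTR5: 0.02, CDS: 0.02}

RIP = "RIP"
CONTROL = "control"


class CapacityError(ValueError):
    """Genes or sites cannot be placed under the requested geometry."""


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth enriched window: the simulator's record of one binding site."""

    chrom: str
    start: int
    end: int
    enrichment_factor: float
    host_region_class: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty site interval")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")


@dataclass
class FragmentSet:
    """All aligned fragments of one sample.

    ``fragments`` is a DataFrame with columns chrom/start/end (0-based,
    half-open), sorted by (chrom, start).
    """

    sample_id: str
    condition: str
    replicate: int
    fragments: pd.DataFrame

    @property
    def library_size(self) -> int:
        return len(self.fragments)

    def midpoints(self, chrom: str) -> np.ndarray:
        sub = self.fragments[self.fragments["chrom"] == chrom]
        return ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)


# ---------------------------------------------------------------------------
# gene-model generation

# genomic layout of a generated gene, left to right (lengths in nt);
# ranges are chosen so that every region class offers a contiguous run of
# >= 600 nt somewhere in the gene and a single gene always fits in 10 kb
_LEFT_UTR = (650, 900)
_CDS_FLANK = (200, 350)     # CDS portion of the first and last exon
_INTRON = (1400, 2500)
_MID_EXON = (650, 1000)     # internal exon, fully coding
_RIGHT_UTR = (1000, 1500)
_INTERGENIC_GAP = (500, 2000)


def _rand_len(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def make_genome_model(
    n_genes: int,
    chrom_length: int = 2_000_000,
    seed: int = 0,
    chrom_name: str = "chr1",
) -> GenomeModel:
    """Generate a single-chromosome model of disjoint three-exon genes.

    Each gene has two introns, a CDS spanning parts of the first and last
    exon plus the whole middle exon, and non-empty UTRs on both sides, so
    all four region classes exist and can host planted sites.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genes: list[Gene] = []
    cursor = _rand_len(rng, (100, 300))
    for i in range(n_genes):
        left_utr = _rand_len(rng, _LEFT_UTR)
        cds_a = _rand_len(rng, _CDS_FLANK)
        intron_a = _rand_len(rng, _INTRON)
        mid = _rand_len(rng, _MID_EXON)
        intron_b = _rand_len(rng, _INTRON)
        cds_b = _rand_len(rng, _CDS_FLANK)
        right_utr = _rand_len(rng, _RIGHT_UTR)

        g = cursor
        exon1 = (g, g + left_utr + cds_a)
        e2s = exon1[1] + intron_a
        exon2 = (e2s, e2s + mid)
        e3s = exon2[1] + intron_b
        exon3 = (e3s, e3s + cds_b + right_utr)
        if exon3[1] > chrom_length:
            raise CapacityError(
                f"cannot place gene {i + 1}/{n_genes} on {chrom_name} "
                f"(length {chrom_length}); placed {len(genes)}"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene_{i + 1:04d}"
        tx = Transcript(
            transcript_id=f"{gene_id}.t1",
            exons=(exon1, exon2, exon3),
            cds=(g + left_utr, e3s + cds_b),
            strand=strand,
        )
        genes.append(Gene(gene_id, chrom_name, strand, [tx]))
        cursor = exon3[1] + _rand_len(rng, _INTERGENIC_GAP)
    return GenomeModel(chromosomes={chrom_name: int(chrom_length)}, genes=genes)


# ---------------------------------------------------------------------------
# planted binding sites

def plant_sites(
    model: GenomeModel,
    n_sites: int,
    region_mix: dict[str, float] | None = None,
    width: int = 600,
    enrichment: float = 8.0,
    seed: int = 0,
    max_tries: int = 2000,
) -> list[PlantedSite]:
    """Place enriched windows wholly inside regions of classes drawn from a mix.

    Sites are pairwise separated by at least 4x ``width`` so neighbouring
    sites can never blur into one detected peak. Placement retries are
    bounded; dense requests raise :class:`CapacityError`.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    mix = dict(DEFAULT_REGION_MIX if region_mix is None else region_mix)
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"region_mix probabilities sum to {total}, expected 1")
    if n_sites == 0:
        return []

    # contiguous candidate runs per class, wide enough for a site
    candidates: dict[str, list[tuple[str, int, int]]] = {c: [] for c in mix}
    for gene in model.genes:
        tx = gene.transcripts[0]
        for s, e, cls in tx.region_runs():
            if cls in candidates and e - s >= width:
                candidates[cls].append((gene.chrom, s, e))
    for cls, prob in mix.items():
        if prob > 0 and not candidates[cls]:
            raise CapacityError(f"no region of class {cls} can host a site")

    rng = np.random.default_rng(seed)
    classes = sorted(mix)
    probs = np.array([mix[c] for c in classes])
    drawn = rng.choice(len(classes), size=n_sites, p=probs)
    min_gap = 4 * width

    placed: list[PlantedSite] = []
    starts_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for cls_idx in drawn:
        cls = classes[cls_idx]
        pool = candidates[cls]
        for _ in range(max_tries):
            chrom, rs, re_ = pool[int(rng.integers(len(pool)))]
            start = int(rng.integers(rs, re_ - width + 1))
            end = start + width
            taken = starts_by_chrom.get(chrom, [])
            if all(start - min_gap >= te or end + min_gap <= ts for ts, te in taken):
                placed.append(PlantedSite(chrom, start, end, float(enrichment), cls))
                starts_by_chrom.setdefault(chrom, []).append((start, end))
                break
        else:
            raise CapacityError(
                f"could not place site {len(placed) + 1}/{n_sites} of class "
                f"{cls} after {max_tries} tries"
            )
    return sorted(placed, key=lambda s: (s.chrom, s.start))


# ---------------------------------------------------------------------------
# fragment simulation

def _nb_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draws: mean m, variance m + dispersion * m**2."""
    means = np.asarray(means, dtype=float)
    if dispersion == 0:
        return rng.poisson(means)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * means)
    return rng.poisson(lam)


def _segments_for_interval(
    start: int, end: int, window: int, edges: list[int]
) -> list[tuple[int, int]]:
    cuts = set(range(start, end, window))
    cuts.add(end)
    cuts.update(e for e in edges if start < e < end)
    cuts.add(start)
    srt = sorted(cuts)
    return list(zip(srt, srt[1:]))


def simulate_fragments(
    model: GenomeModel,
    sites: list[PlantedSite],
    background_rate: float = 0.05,
    fragment_len_mean: float = 200.0,
    nb_dispersion: float = 0.05,
    n_rip: int = 2,
    n_control: int = 2,
    seed: int = 0,
    window: int = 200,
    background_shape: str = "transcript",
    depth_factors: dict[str, float] | None = None,
    min_fragment_len: int = 50,
) -> list[FragmentSet]:
    """Simulate per-sample fragment sets over a shared background.

    The genome (gene spans when ``background_shape='transcript'``, whole
    chromosomes when ``'flat'``) is tiled into windows split at planted-site
    edges; each window's expected fragment count is
    ``background_rate * window_length``, multiplied by the site's enrichment
    factor inside planted sites for RIP samples only, and drawn from a
    negative binomial with the given dispersion. Fragment midpoints are
    uniform within their window; lengths are shifted-Poisson around
    ``fragment_len_mean`` with floor ``min_fragment_len``.
    """
    if background_rate <= 0:
        raise ValueError("background_rate must be > 0")
    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    if fragment_len_mean <= min_fragment_len:
        raise ValueError("fragment_len_mean must exceed min_fragment_len")
    if background_shape not in ("transcript", "flat"):
        raise ValueError("background_shape must be 'transcript' or 'flat'")

    # segment table: (chrom, start, end, enrichment multiplier applies if RIP)
    sites_by_chrom: dict[str, list[PlantedSite]] = {}
    for site in sites:
        sites_by_chrom.setdefault(site.chrom, []).append(site)

    seg_chrom: list[str] = []
    seg_start: list[int] = []
    seg_end: list[int] = []
    seg_factor: list[float] = []
    for chrom, length in model.chromosomes.items():
        if background_shape == "flat":
            intervals = [(0, length)]
        else:
            intervals = [g.span for g in model.genes if g.chrom == chrom]
        chrom_sites = sorted(sites_by_chrom.get(chrom, []), key=lambda s: s.start)
        edges = [e for s in chrom_sites for e in (s.start, s.end)]
        for iv_start, iv_end in intervals:
            for a, b in _segments_for_interval(iv_start, iv_end, window, edges):
                factor = 1.0
                for site in chrom_sites:
                    if site.start <= a and b <= site.end:
                        factor = site.enrichment_factor
                        break
                seg_chrom.append(chrom)
                seg_start.append(a)
                seg_end.append(b)
                seg_factor.append(factor)
    seg_start_arr = np.array(seg_start, dtype=np.int64)
    seg_end_arr = np.array(seg_end, dtype=np.int64)
    seg_len = (seg_end_arr - seg_start_arr).astype(float)
    seg_factor_arr = np.array(seg_factor)
    chrom_len = np.array([model.chromosomes[c] for c in seg_chrom], dtype=np.int64)

    sample_plan = [(RIP, r + 1) for r in range(n_rip)] + [
        (CONTROL, r + 1) for r in range(n_control)
    ]
    streams = np.random.SeedSequence(seed).spawn(len(sample_plan))
    out: list[FragmentSet] = []
    for (condition, rep), stream in zip(sample_plan, streams):
        sample_id = f"{'RIP' if condition == RIP else 'IgG'}_{rep}"
        depth = 1.0 if depth_factors is None else depth_factors.get(sample_id, 1.0)
        rng = np.random.default_rng(stream)
        means = background_rate * seg_len * depth
        if condition == RIP:
            means = means * seg_factor_arr
        counts = _nb_counts(rng, means, nb_dispersion)
        total = int(counts.sum())
        rep_idx = np.repeat(np.arange(len(counts)), counts)
        centers = seg_start_arr[rep_idx] + rng.random(total) * seg_len[rep_idx]
        lens = min_fragment_len + rng.poisson(
            fragment_len_mean - min_fragment_len, size=total
        )
        starts = np.maximum(0, np.rint(centers - lens / 2).astype(np.int64))
        ends = np.minimum(chrom_len[rep_idx], starts + lens)
        starts = np.maximum(0, np.minimum(starts, ends - 1))
        frags = pd.DataFrame(
            {
                "chrom": np.array(seg_chrom, dtype=object)[rep_idx],
                "start": starts,
                "end": ends,
            }
        ).sort_values(["chrom", "start"], kind="stable", ignore_index=True)
        out.append(FragmentSet(sample_id, condition, rep, frags))
    return out


def simulate_count_matrix(
    n_peaks: int,
    n_rip: int = 2,
    n_control: int = 2,
    mean_range: tuple[float, float] = (20.0, 200.0),
    nb_dispersion: float = 0.05,
    enrichment: np.ndarray | float = 1.0,
    depth_factors: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Direct NB count matrix (peaks x samples) for calibration studies.

    Per-peak base means are log-uniform over ``mean_range``; RIP columns are
    multiplied by ``enrichment`` (scalar or per-peak vector). Returns the
    counts and the condition label of each column.
    """
    rng = np.random.default_rng(seed)
    n_samples = n_rip + n_control
    conditions = [RIP] * n_rip + [CONTROL] * n_control
    if depth_factors is None:
        depth_factors = np.ones(n_samples)
    lo, hi = mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_peaks))
    enr = np.broadcast_to(np.asarray(enrichment, dtype=float), (n_peaks,))
    counts = np.empty((n_peaks, n_samples), dtype=np.int64)
    for j, cond in enumerate(conditions):
        mu = base * depth_factors[j] * (enr if cond == RIP else 1.0)
        counts[:, j] = _nb_counts(rng, mu, nb_dispersion)
    return counts, conditions


# ---------------------------------------------------------------------------
# BED output

def write_fragments_bed(fragset: FragmentSet, path: str) -> None:
    df = fragset.fragments
    bed = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": [f"{fragset.sample_id}_f{i + 1}" for i in range(len(df))],
            "score": 0,
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(
    path: str, sample_id: str, condition: str, replicate: int = 1
) -> FragmentSet:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    df = df.sort_values(["chrom", "start"], kind="stable", ignore_index=True)
    return FragmentSet(sample_id, condition, replicate, df)


def write_sites_bed(sites: list[PlantedSite], path: str) -> None:
    """Planted truth as BED with the enrichment factor in the score column."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\tsite_{i + 1}\t"
                f"{s.enrichment_factor:g}\t.\t{s.host_region_class}\n"
            )


def read_sites_bed(path: str) -> list[PlantedSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            cls = f[6] if len(f) > 6 else INTRON
            sites.append(PlantedSite(f[0], int(f[1]), int(f[2]), float(f[4]), cls))
    return sites
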
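"""Peak-to-gene annotation: region class of the summit and summaries."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .genome import (
    CODING_CLASSES,
    EXON_NONCODING,
    INTERGENIC,
    GenomeModel,
    Transcript,
)
from .peaks import Peak

#: class precedence when transcripts covering the same summit disagree;
#: UTRs win over intron so isoform-specific UTR annotations are not masked
DEFAULT_PRECEDENCE = ("3'UTR", "5'UTR", "CDS", "intron", EXON_NONCODING)


@dataclass(frozen=True)
class AnnotatedPeak:
    peak: Peak
    gene_id: str
    transcript_id: str | None
    region_class: str

    def __post_init__(self) -> None:
        if (self.region_class == INTERGENIC) != (self.gene_id == INTERGENIC):
            raise ValueError("intergenic class and gene_id must agree")


def classify_position(position: int, transcript: Transcript) -> str:
    """Region class of a genomic position inside the transcript span."""
    return transcript.classify(position)


def annotate_peak(
    peak: Peak,
    model: GenomeModel,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> AnnotatedPeak:
    """Annotate by the summit: best covering transcript by class precedence.

    Ties are broken by class precedence, then the longer transcript span,
    then lexicographic transcript id; a summit covered by no transcript is
    intergenic.
    """
    rank = {cls: i for i, cls in enumerate(precedence)}
    best = None
    for gene, tx in model.transcripts_at(peak.chrom, peak.summit):
        cls = tx.classify(peak.summit)
        lo, hi = tx.span
        key = (rank.get(cls, len(rank)), -(hi - lo), tx.transcript_id)
        if best is None or key < best[0]:
            best = (key, gene, tx, cls)
    if best is None:
        return AnnotatedPeak(peak, INTERGENIC, None, INTERGENIC)
    _, gene, tx, cls = best
    return AnnotatedPeak(peak, gene.gene_id, tx.transcript_id, cls)


def annotate_peaks(
    peaks: list[Peak],
    model: GenomeModel,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> list[AnnotatedPeak]:
    return [annotate_peak(p, model, precedence) for p in peaks]


def region_distribution(annotated: list[AnnotatedPeak]) -> dict[str, float]:
    """Fraction of peaks per region class over the four coding classes.

    Intergenic peaks and peaks on noncoding transcripts are excluded from
    the denominator (they are reported separately by the pipeline).
    """
    counts = Counter(
        a.region_class for a in annotated if a.region_class in CODING_CLASSES
    )
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no peaks in coding-transcript region classes")
    return {cls: counts.get(cls, 0) / total for cls in CODING_CLASSES}


def gene_list(annotated: list[AnnotatedPeak]) -> list[str]:
    """Sorted, deduplicated ids of genes with at least one peak."""
    return sorted({a.gene_id for a in annotated if a.gene_id != INTERGENIC})


def write_annotated_tsv(annotated: list[AnnotatedPeak], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "peak_id\tchrom\tstart\tend\tsummit\tscore\tgene_id\t"
            "transcript_id\tregion_class\n"
        )
        for i, a in enumerate(annotated):
            p = a.peak
            fh.write(
                f"peak_{i + 1}\t{p.chrom}\t{p.start}\t{p.end}\t{p.summit}\t"
                f"{p.score:.6g}\t{a.gene_id}\t{a.transcript_id or '.'}\t"
                f"{a.region_class}\n"
            )


def write_annotated_bed(annotated: list[AnnotatedPeak], path: str) -> None:
    """BED with ``gene|class`` in the name field."""
    with open(path, "w") as fh:
        for a in annotated:
            p = a.peak
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t"
                f"{a.gene_id}|{a.region_class}\t0\t.\n"
            )
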
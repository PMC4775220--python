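"""Gene models: transcripts with exon/CDS structure and derived region classes.

Coordinates are 0-based, half-open genomic intervals throughout the package;
conversion to 1-based inclusive happens only at the GTF boundary.

Region classes are derived from the exon/CDS structure of a transcript:
exonic positions upstream of the CDS (in transcript orientation) are 5'UTR,
positions inside the CDS genomic span are CDS, downstream exonic positions
are 3'UTR, and non-exonic positions inside the transcript span are intron.
On the minus strand the 5'UTR sits at the higher genomic coordinates.
Transcripts without a CDS label their exonic positions ``exon_noncoding``.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from intervaltree import IntervalTree

UTR5 = "5'UTR"
UTR3 = "3'UTR"
CDS = "CDS"
INTRON = "intron"
INTERGENIC = "intergenic"
EXON_NONCODING = "exon_noncoding"

#: the four coding-transcript region classes used for summaries
CODING_CLASSES = (UTR5, CDS, INTRON, UTR3)


class GenomeModelError(ValueError):
    """Raised when a gene model violates its structural invariants."""


@dataclass
class Transcript:
    """A transcript: sorted disjoint exons and an optional CDS genomic span."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None
    strand: str

    _runs: tuple[tuple[int, int, str], ...] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeModelError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise GenomeModelError(f"{self.transcript_id}: no exons")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        for s, e in exons:
            if e <= s:
                raise GenomeModelError(f"{self.transcript_id}: empty exon [{s},{e})")
        for (_, e_prev), (s_next, _) in zip(exons, exons[1:]):
            if s_next < e_prev:
                raise GenomeModelError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
        self.exons = exons
        if self.cds is not None:
            cs, ce = int(self.cds[0]), int(self.cds[1])
            if ce <= cs:
                raise GenomeModelError(f"{self.transcript_id}: empty CDS")
            if cs < exons[0][0] or ce > exons[-1][1]:
                raise GenomeModelError(
                    f"{self.transcript_id}: CDS outside exonic span"
                )
            self.cds = (cs, ce)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def region_runs(self) -> tuple[tuple[int, int, str], ...]:
        """Maximal runs (start, end, class) partitioning the genomic span."""
        if self._runs is not None:
            return self._runs
        runs: list[tuple[int, int, str]] = []

        def exon_label(pos_start: int) -> str:
            if self.cds is None:
                return EXON_NONCODING
            cs, ce = self.cds
            if pos_start < cs:
                return UTR5 if self.strand == "+" else UTR3
            if pos_start < ce:
                return CDS
            return UTR3 if self.strand == "+" else UTR5

        prev_end: int | None = None
        for es, ee in self.exons:
            if prev_end is not None and es > prev_end:
                runs.append((prev_end, es, INTRON))
            # split the exon at CDS boundaries that fall inside it
            cuts = [es, ee]
            if self.cds is not None:
                for c in self.cds:
                    if es < c < ee:
                        cuts.append(c)
            cuts = sorted(set(cuts))
            for a, b in zip(cuts, cuts[1:]):
                runs.append((a, b, exon_label(a)))
            prev_end = ee
        self._runs = tuple(runs)
        return self._runs

    def classify(self, position: int) -> str:
        """Region class at a genomic position inside the transcript span."""
        lo, hi = self.span
        if not lo <= position < hi:
            raise ValueError(
                f"position {position} outside span [{lo},{hi}) of "
                f"{self.transcript_id}"
            )
        runs = self.region_runs()
        i = bisect_right([r[0] for r in runs], position) - 1
        return runs[i][2]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise GenomeModelError(f"{self.gene_id}: no transcripts")
        for tx in self.transcripts:
            if tx.strand != self.strand:
                raise GenomeModelError(
                    f"{self.gene_id}: transcript {tx.transcript_id} strand mismatch"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(tx.span[0] for tx in self.transcripts),
            max(tx.span[1] for tx in self.transcripts),
        )


@dataclass
class GenomeModel:
    """Chromosome lengths plus genes; indexable for summit annotation."""

    chromosomes: dict[str, int]
    genes: list[Gene]

    _index: dict[str, IntervalTree] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for gene in self.genes:
            if gene.chrom not in self.chromosomes:
                raise GenomeModelError(f"{gene.gene_id}: unknown chrom {gene.chrom}")
            length = self.chromosomes[gene.chrom]
            lo, hi = gene.span
            if lo < 0 or hi > length:
                raise GenomeModelError(
                    f"{gene.gene_id}: span [{lo},{hi}) exceeds {gene.chrom} "
                    f"length {length}"
                )

    def transcripts_at(self, chrom: str, position: int) -> list[tuple[Gene, Transcript]]:
        """All (gene, transcript) pairs whose span covers a position."""
        if self._index is None:
            index: dict[str, IntervalTree] = {}
            for gene in self.genes:
                tree = index.setdefault(gene.chrom, IntervalTree())
                for tx in gene.transcripts:
                    lo, hi = tx.span
                    tree.addi(lo, hi, (gene, tx))
            self._index = index
        tree = self._index.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in sorted(tree[position])]


# ---------------------------------------------------------------------------
# GTF I/O (features: exon, CDS; attributes gene_id, transcript_id)

def write_gtf(model: GenomeModel, path: str) -> None:
    with open(path, "w") as fh:
        for gene in model.genes:
            for tx in gene.transcripts:
                attrs = (
                    f'gene_id "{gene.gene_id}"; '
                    f'transcript_id "{tx.transcript_id}";'
                )
                for es, ee in tx.exons:
                    fh.write(
                        f"{gene.chrom}\tripcall\texon\t{es + 1}\t{ee}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )
                if tx.cds is not None:
                    cs, ce = tx.cds
                    for es, ee in tx.exons:
                        a, b = max(es, cs), min(ee, ce)
                        if a < b:
                            fh.write(
                                f"{gene.chrom}\tripcall\tCDS\t{a + 1}\t{b}\t.\t"
                                f"{gene.strand}\t.\t{attrs}\n"
                            )


def write_chrom_sizes(model: GenomeModel, path: str) -> None:
    with open(path, "w") as fh:
        for name, length in model.chromosomes.items():
            fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, length = line.split("\t")[:2]
                sizes[name] = int(length)
    return sizes


def read_gtf(path: str, chromosomes: dict[str, int]) -> GenomeModel:
    """Load a gene model from GTF given chromosome lengths."""
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    # group exon/CDS features by transcript
    by_tx: dict[str, dict] = {}
    for feat in db.all_features():
        tx_id = feat.attributes["transcript_id"][0]
        gene_id = feat.attributes["gene_id"][0]
        rec = by_tx.setdefault(
            tx_id,
            {"gene_id": gene_id, "chrom": feat.seqid, "strand": feat.strand,
             "exons": [], "cds": []},
        )
        interval = (feat.start - 1, feat.end)  # back to half-open
        if feat.featuretype == "exon":
            rec["exons"].append(interval)
        elif feat.featuretype == "CDS":
            rec["cds"].append(interval)

    by_gene: dict[str, Gene] = {}
    for tx_id in sorted(by_tx):
        rec = by_tx[tx_id]
        exons = tuple(sorted(rec["exons"]))
        cds = None
        if rec["cds"]:
            cds = (min(s for s, _ in rec["cds"]), max(e for _, e in rec["cds"]))
        tx = Transcript(tx_id, exons, cds, rec["strand"])
        gene = by_gene.get(rec["gene_id"])
        if gene is None:
            by_gene[rec["gene_id"]] = Gene(
                rec["gene_id"], rec["chrom"], rec["strand"], [tx]
            )
        else:
            gene.transcripts.append(tx)
    genes = sorted(by_gene.values(), key=lambda g: (g.chrom, g.span[0]))
    return GenomeModel(chromosomes=dict(chromosomes), genes=genes)
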
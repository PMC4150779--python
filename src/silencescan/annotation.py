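"""Gene annotation I/O and strand-aware coordinate primitives.

All coordinates are 0-based half-open internally; conversion to/from the
1-based closed convention of GFF3/GTF happens only at the file boundary.
The transcription start site (TSS) of a gene is the 5'-most base of its
span on the gene strand: ``start`` for ``+`` genes, ``end - 1`` for ``-``
genes.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils

__all__ = [
    "GeneModel",
    "GenomicWindow",
    "AnnotationError",
    "read_gene_models",
    "write_bed6",
    "write_bed12",
    "promoter_window",
    "overlap_bp",
]

_BIOTYPES = ("protein_coding", "microRNA", "rRNA", "other")


class AnnotationError(ValueError):
    """Raised for malformed annotation files or invalid gene models."""


@dataclass
class GeneModel:
    """A strand-aware gene: the coordinate anchor for every pipeline stage.

    ``span`` is the half-open interval [start, end) of the full
    transcription unit; ``exons`` is a sorted tuple of non-overlapping
    half-open intervals contained in the span.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple = ()
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if self.biotype not in _BIOTYPES:
            self.biotype = "other"
        if not self.exons:
            self.exons = ((self.start, self.end),)
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise AnnotationError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside span "
                    f"[{self.start},{self.end})"
                )
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted at [{s},{e})"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        """Genomic coordinate (0-based) of the transcription start site."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def span(self) -> tuple:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GenomicWindow:
    """A strand-aware window anchored on a TSS.

    ``upstream_bp`` extends 5' of the TSS on the gene strand (toward larger
    coordinates for ``-`` strand genes); ``downstream_bp`` extends 3'.
    Materializes to a half-open genomic interval of length
    upstream_bp + downstream_bp (unless clipped at coordinate 0).
    """

    chrom: str
    tss: int
    strand: str
    upstream_bp: int
    downstream_bp: int

    def __post_init__(self):
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window sizes must be non-negative")

    @property
    def start(self) -> int:
        if self.strand == "+":
            return max(0, self.tss - self.upstream_bp)
        return max(0, self.tss - self.downstream_bp + 1)

    @property
    def end(self) -> int:
        if self.strand == "+":
            return self.tss + self.downstream_bp
        return self.tss + self.upstream_bp + 1

    @property
    def interval(self) -> tuple:
        return (self.start, self.end)

    def signed_offset(self, pos: int) -> int:
        """Signed bp offset of a genomic position from the TSS.

        Negative = upstream, positive = downstream, on the gene strand.
        """
        return pos - self.tss if self.strand == "+" else self.tss - pos


def promoter_window(gene: GeneModel, upstream_bp: int, downstream_bp: int) -> tuple:
    """Half-open genomic interval covering [-upstream, +downstream) of the TSS.

    Strand-aware: for a ``-`` strand gene, upstream lies at larger genomic
    coordinates. The interval is clipped at coordinate 0.
    """
    w = GenomicWindow(gene.chrom, gene.tss, gene.strand, upstream_bp, downstream_bp)
    return w.interval


def overlap_bp(a: Sequence, b: Sequence) -> int:
    """Number of bases shared by two half-open intervals.

    Accepts ``(start, end)`` pairs or ``(chrom, start, end)`` triples;
    intervals on different chromosomes overlap by 0 (not an error).
    """
    if len(a) == 3 or len(b) == 3:
        if len(a) == 3 and len(b) == 3 and a[0] != b[0]:
            return 0
        a = a[-2:]
        b = b[-2:]
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


# ---------------------------------------------------------------------------
# File I/O


def _infer_dialect(path: str) -> str:
    low = str(path).lower()
    if low.endswith(".gff") or low.endswith(".gff3"):
        return "gff3"
    if low.endswith(".gtf"):
        return "gtf"
    if low.endswith(".bed") or low.endswith(".bed12"):
        return "bed12"
    raise AnnotationError(f"cannot infer annotation dialect from {path!r}")


def read_gene_models(path: str, dialect: str | None = None) -> list:
    """Read gene models from GFF3, GTF, BED6 or BED12.

    Multi-transcript genes collapse to one :class:`GeneModel` with the
    union of exons and the 5'-most start; duplicate gene ids raise.
    """
    dialect = dialect or _infer_dialect(path)
    if dialect in ("gff3", "gtf"):
        return _read_gff(path, dialect)
    if dialect == "bed12":
        return _read_bed(path, twelve=True)
    if dialect == "bed6":
        return _read_bed(path, twelve=False)
    raise AnnotationError(f"unknown dialect {dialect!r}")


def _check_gff_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise AnnotationError(
                    f"{path}: malformed line {lineno}: expected >=8 tab fields"
                )
            try:
                s, e = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"{path}: malformed line {lineno}: non-integer coordinates"
                ) from None
            if s < 1 or e < s:
                raise AnnotationError(
                    f"{path}: malformed line {lineno}: bad coordinate range {s}..{e}"
                )


def _attr_first(attrs, *keys):
    for k in keys:
        if k in attrs:
            v = attrs[k]
            return v[0] if isinstance(v, (list, tuple)) else v
    return None


def _norm_biotype(raw: str | None) -> str:
    if raw is None:
        return "protein_coding"
    low = raw.lower()
    if "protein" in low:
        return "protein_coding"
    if "mirna" in low or "microrna" in low:
        return "microRNA"
    if "rrna" in low:
        return "rRNA"
    return "other"


def _read_gff(path: str, dialect: str) -> list:
    _check_gff_lines(path)
    genes = {}  # gene_id -> dict
    tx2gene = {}
    order = []
    exon_feats = []
    for f in gffutils.iterators.DataIterator(str(path)):
        ftype = f.featuretype
        if ftype == "gene":
            gid = _attr_first(f.attributes, "ID", "gene_id", "Name")
            if gid is None:
                raise AnnotationError(f"{path}: gene feature without an id")
            if gid in genes:
                raise AnnotationError(f"{path}: duplicate gene id {gid!r}")
            genes[gid] = {
                "chrom": f.seqid,
                "strand": f.strand,
                "start": f.start - 1,
                "end": f.end,
                "exons": [],
                "biotype": _norm_biotype(
                    _attr_first(f.attributes, "gene_biotype", "biotype", "gene_type")
                ),
            }
            order.append(gid)
        elif ftype in ("mRNA", "transcript"):
            tid = _attr_first(f.attributes, "ID", "transcript_id")
            gid = _attr_first(f.attributes, "Parent", "gene_id")
            if tid is not None and gid is not None:
                tx2gene[tid] = gid
        elif ftype == "exon":
            exon_feats.append(f)
    for f in exon_feats:
        parent = _attr_first(f.attributes, "Parent", "gene_id")
        gid = tx2gene.get(parent, parent)
        if gid not in genes:
            # exon for an unknown gene: create from the exon's extent
            genes[gid] = {
                "chrom": f.seqid,
                "strand": f.strand,
                "start": f.start - 1,
                "end": f.end,
                "exons": [],
                "biotype": _norm_biotype(
                    _attr_first(f.attributes, "gene_biotype", "biotype", "gene_type")
                ),
            }
            order.append(gid)
        g = genes[gid]
        g["start"] = min(g["start"], f.start - 1)
        g["end"] = max(g["end"], f.end)
        g["exons"].append((f.start - 1, f.end))
    out = []
    for gid in order:
        g = genes[gid]
        exons = _merge_intervals(g["exons"]) if g["exons"] else ()
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=g["chrom"],
                strand=g["strand"],
                start=g["start"],
                end=g["end"],
                exons=exons,
                biotype=g["biotype"],
            )
        )
    return out


def _merge_intervals(ivs: Iterable[tuple]) -> tuple:
    ivs = sorted(ivs)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def _read_bed(path: str, twelve: bool) -> list:
    out = []
    seen = set()
    min_cols = 12 if twelve else 6
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < min_cols:
                raise AnnotationError(
                    f"{path}: malformed line {lineno}: expected >={min_cols} fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise AnnotationError(
                    f"{path}: malformed line {lineno}: non-integer coordinates"
                ) from None
            gid, strand = fields[3], fields[5]
            if gid in seen:
                raise AnnotationError(f"{path}: duplicate gene id {gid!r}")
            seen.add(gid)
            if twelve:
                n = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
                if len(sizes) != n or len(starts) != n:
                    raise AnnotationError(
                        f"{path}: malformed line {lineno}: block count mismatch"
                    )
                exons = tuple(
                    (start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)
                )
            else:
                exons = ((start, end),)
            out.append(
                GeneModel(
                    gene_id=gid,
                    chrom=fields[0],
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                )
            )
    return out


def write_bed6(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_bed12(genes: Iterable[GeneModel], path: str) -> None:
    """Write genes in BED12; exon structure goes to the block columns."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def write_gff3(genes: Iterable[GeneModel], path: str) -> None:
    """Write a flat one-level GFF3 (gene features with exon children)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsilencescan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};gene_biotype={g.biotype}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsilencescan\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
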
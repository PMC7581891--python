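"""Gene-model parsing and transcript anatomy.

Reads gene models (gene / mRNA / exon / CDS) from GFF3 plus a genome FASTA
into strand-normalized transcript models: spliced sequence with transcript
coordinate 1 at the 5' end, the transcript-coordinate position of the last
stop-codon base, and the 3'-UTR length. These anchor all downstream probe
geometry. Also selects a representative isoform per locus and detects
unique exons (UEs) among alternatively spliced siblings.

Conventions: GFF3 intervals are 1-based closed; transcript coordinates are
1-based with position 1 on the 5' side. On the minus strand the spliced
sequence is reverse-complemented so transcript coordinates always run
5' -> 3'.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Fatal annotation defect (e.g. a referenced chromosome is missing)."""


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform with strand-normalized spliced sequence.

    ``stop_end_tx`` is the transcript coordinate (1-based) of the final base
    of the stop codon; ``utr3_length_tx`` counts the bases downstream of it,
    so ``stop_end_tx + utr3_length_tx == len(spliced_sequence)``.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[Interval, ...]          # genomic, sorted by start
    cds_intervals: tuple[Interval, ...]  # genomic, sorted by start
    spliced_sequence: str
    stop_end_tx: int
    utr3_length_tx: int

    def __len__(self) -> int:
        return len(self.spliced_sequence)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def exon_tx_intervals(self) -> list[Interval]:
        """Exon intervals in transcript coordinates, 5'->3' order."""
        order = self.exons if self.strand == "+" else self.exons[::-1]
        out, offset = [], 0
        for s, e in order:
            n = e - s + 1
            out.append((offset + 1, offset + n))
            offset += n
        return out

    def tx_to_genomic(self, pos: int) -> int:
        """Map a 1-based transcript coordinate to its genomic position."""
        if not 1 <= pos <= len(self):
            raise IndexError(f"transcript position {pos} outside 1..{len(self)}")
        offset = 0
        order = self.exons if self.strand == "+" else self.exons[::-1]
        for s, e in order:
            n = e - s + 1
            if pos <= offset + n:
                within = pos - offset
                return s + within - 1 if self.strand == "+" else e - within + 1
            offset += n
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    @property
    def alternatively_spliced(self) -> bool:
        return len(self.transcripts) >= 2


@dataclass(frozen=True)
class UniqueExon:
    """An exon of the representative isoform absent from every sibling."""

    transcript_id: str
    exon_interval_tx: Interval
    length: int


@dataclass
class ParseIssue:
    gene_id: str
    reason: str


def _read_fasta(source) -> dict[str, str]:
    if isinstance(source, Mapping):
        return {k: str(v).upper() for k, v in source.items()}
    if isinstance(source, (str, os.PathLike)) and not (
        isinstance(source, str) and "\n" in source
    ):
        handle = open(source)
    elif isinstance(source, str):
        handle = io.StringIO(source)
    else:
        handle = source
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if handle is not source:
            handle.close()


def _gff3_lines(source) -> Iterable[str]:
    if isinstance(source, (str, os.PathLike)) and not (
        isinstance(source, str) and "\n" in source
    ):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, str):
        yield from source.splitlines()
    else:
        yield from source


def _attr(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _build_transcript(
    tx_id: str,
    gene_id: str,
    chrom: str,
    strand: str,
    exons: list[Interval],
    cds: list[Interval],
    chrom_seq: str,
    stop_included: bool,
) -> TranscriptModel:
    exons = sorted(exons)
    cds = sorted(cds)
    for s, e in exons:
        if not 1 <= s <= e <= len(chrom_seq):
            raise AnnotationError(
                f"{tx_id}: exon {s}-{e} outside chromosome {chrom} "
                f"(length {len(chrom_seq)})"
            )
    for cs, ce in cds:
        if not any(s <= cs and ce <= e for s, e in exons):
            raise ValueError(f"{tx_id}: CDS {cs}-{ce} not contained in any exon")
    raw = "".join(chrom_seq[s - 1 : e] for s, e in exons)
    spliced = raw if strand == "+" else revcomp(raw)

    # Transcript coordinate of the 3'-most CDS base.
    stop_genomic = max(e for _, e in cds) if strand == "+" else min(s for s, _ in cds)
    model = TranscriptModel(
        transcript_id=tx_id,
        gene_id=gene_id,
        chromosome=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_intervals=tuple(cds),
        spliced_sequence=spliced,
        stop_end_tx=1,  # placeholder, replaced below
        utr3_length_tx=0,
    )
    stop_tx = _genomic_to_tx(model, stop_genomic)
    if not stop_included:
        stop_tx = min(stop_tx + 3, len(spliced))
    return TranscriptModel(
        transcript_id=tx_id,
        gene_id=gene_id,
        chromosome=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_intervals=tuple(cds),
        spliced_sequence=spliced,
        stop_end_tx=stop_tx,
        utr3_length_tx=len(spliced) - stop_tx,
    )


def _genomic_to_tx(tx: TranscriptModel, g: int) -> int:
    offset = 0
    order = tx.exons if tx.strand == "+" else tx.exons[::-1]
    for s, e in order:
        if s <= g <= e:
            return offset + (g - s + 1 if tx.strand == "+" else e - g + 1)
        offset += e - s + 1
    raise ValueError(f"{tx.transcript_id}: genomic position {g} not exonic")


def parse_gene_models(
    gff3_source,
    fasta_source,
    stop_included: bool = True,
) -> tuple[list[GeneModel], list[ParseIssue]]:
    """Parse gene models from GFF3 + FASTA.

    Every mRNA becomes a :class:`TranscriptModel` with its spliced sequence
    extracted and strand-normalized. Genes without any CDS-bearing
    transcript, or with a CDS escaping its exons, are excluded and reported
    as :class:`ParseIssue` records. A missing chromosome sequence is fatal.

    Parameters
    ----------
    stop_included
        Whether the annotated CDS includes the stop codon (the common GFF3
        dialect). If False, the stop-codon anchor is extended 3 bases
        downstream.
    """
    chroms = _read_fasta(fasta_source)

    mrna_parent: dict[str, str] = {}
    mrna_meta: dict[str, tuple[str, str]] = {}  # tx -> (chrom, strand)
    gene_meta: dict[str, tuple[str, str]] = {}
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    gene_order: list[str] = []

    for line in _gff3_lines(gff3_source):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            continue
        chrom, _, ftype, start, end, _, strand, _, attrs = cols
        a = _attr(attrs)
        if ftype == "gene":
            gid = a.get("ID", "")
            gene_meta[gid] = (chrom, strand)
            gene_order.append(gid)
        elif ftype == "mRNA":
            tid, parent = a.get("ID", ""), a.get("Parent", "")
            mrna_parent[tid] = parent
            mrna_meta[tid] = (chrom, strand)
        elif ftype in ("exon", "CDS"):
            parent = a.get("Parent", "")
            target = exons if ftype == "exon" else cds
            for tid in parent.split(","):
                target.setdefault(tid, []).append((int(start), int(end)))

    genes: list[GeneModel] = []
    issues: list[ParseIssue] = []
    by_gene: dict[str, list[str]] = {}
    for tid, gid in mrna_parent.items():
        by_gene.setdefault(gid, []).append(tid)

    for gid in gene_order:
        tids = sorted(by_gene.get(gid, []))
        chrom, strand = gene_meta[gid]
        if chrom not in chroms:
            raise AnnotationError(f"gene {gid}: chromosome {chrom} absent from FASTA")
        built, bad = [], None
        for tid in tids:
            if tid not in cds or not cds[tid]:
                continue  # non-coding isoform: not usable for probe anchoring
            try:
                built.append(
                    _build_transcript(
                        tid, gid, chrom, strand, exons.get(tid, []),
                        cds[tid], chroms[chrom], stop_included,
                    )
                )
            except AnnotationError:
                raise
            except ValueError as exc:
                bad = str(exc)
                break
        if bad is not None:
            issues.append(ParseIssue(gid, bad))
            continue
        if not built:
            issues.append(ParseIssue(gid, "no CDS-bearing transcript"))
            continue
        genes.append(GeneModel(gid, chrom, strand, tuple(built)))
    return genes, issues


def select_representative(gene: GeneModel) -> TranscriptModel:
    """Pick the representative isoform: longest CDS, then longest spliced
    sequence, then lexicographically smallest transcript id."""
    candidates = [t for t in gene.transcripts if t.cds_intervals]
    if not candidates:
        raise ValueError(f"gene {gene.gene_id} is non-coding: no CDS-bearing isoform")
    return min(
        candidates,
        key=lambda t: (-t.cds_length, -len(t), t.transcript_id),
    )


def find_unique_exons(
    gene: GeneModel, representative: TranscriptModel
) -> list[UniqueExon]:
    """Exons of the representative whose genomic boundaries match no exon of
    any sibling isoform (exact-interval test), sorted by transcript coord."""
    sibling_exons: set[Interval] = set()
    for t in gene.transcripts:
        if t.transcript_id != representative.transcript_id:
            sibling_exons.update(t.exons)
    if not sibling_exons and len(gene.transcripts) == 1:
        return []
    out = []
    tx_ivals = representative.exon_tx_intervals()
    order = (
        representative.exons
        if representative.strand == "+"
        else representative.exons[::-1]
    )
    for genomic, tx_iv in zip(order, tx_ivals):
        if genomic not in sibling_exons:
            out.append(
                UniqueExon(
                    transcript_id=representative.transcript_id,
                    exon_interval_tx=tx_iv,
                    length=tx_iv[1] - tx_iv[0] + 1,
                )
            )
    return sorted(out, key=lambda u: u.exon_interval_tx)


def write_gff3(genes: Sequence[GeneModel]) -> str:
    """Serialize gene models back to GFF3 (round-trips through the parser)."""
    lines = ["##gff-version 3"]
    for g in genes:
        g_start = min(s for t in g.transcripts for s, _ in t.exons)
        g_end = max(e for t in g.transcripts for _, e in t.exons)
        lines.append(
            f"{g.chromosome}\tdroughtmem\tgene\t{g_start}\t{g_end}\t.\t"
            f"{g.strand}\t.\tID={g.gene_id}"
        )
        for t in g.transcripts:
            t_start = min(s for s, _ in t.exons)
            t_end = max(e for _, e in t.exons)
            lines.append(
                f"{g.chromosome}\tdroughtmem\tmRNA\t{t_start}\t{t_end}\t.\t"
                f"{g.strand}\t.\tID={t.transcript_id};Parent={g.gene_id}"
            )
            for s, e in t.exons:
                lines.append(
                    f"{g.chromosome}\tdroughtmem\texon\t{s}\t{e}\t.\t"
                    f"{g.strand}\t.\tParent={t.transcript_id}"
                )
            for s, e in t.cds_intervals:
                lines.append(
                    f"{g.chromosome}\tdroughtmem\tCDS\t{s}\t{e}\t.\t"
                    f"{g.strand}\t0\tParent={t.transcript_id}"
                )
    return "\n".join(lines) + "\n"


def transcript_table(genes: Sequence[GeneModel]):
    """Per-transcript summary TSV-ready table."""
    import pandas as pd

    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": g.gene_id,
            "strand": g.strand,
            "n_exons": len(t.exons),
            "cds_len": t.cds_length,
            "utr3_len": t.utr3_length_tx,
        }
        for g in genes
        for t in g.transcripts
    ]
    return pd.DataFrame(rows)
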
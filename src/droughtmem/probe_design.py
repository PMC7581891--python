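"""60-mer probe design anchored at the stop codon.

Three 60-nt tiling probes are placed per transcript, stepping 30 bp, so
that with full flanks their union covers exactly 120 bases: the final 60
bases of the coding sequence and the first 60 bases of the 3'-UTR. When
the 3'-UTR is shorter than 60 bases the whole three-probe frame shifts
upstream so the last probe ends at the transcript end; probes that would
then start before the transcript start are omitted. Additional probes
target unique exons of alternatively spliced loci, and control sequences
(organellar genes, selection markers such as gfp/gus/hyg/bar/kan) get
end-anchored tiles.

Cross-hybridization screening drops probes whose exact 60-mer (or its
reverse complement) occurs in a transcript of a different gene, keeping at
least two tiling probes per gene.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from droughtmem.annotation_io import (
    GeneModel,
    TranscriptModel,
    UniqueExon,
    find_unique_exons,
    revcomp,
    select_representative,
)

PROBE_LEN = 60
STEP = 30

TILE_CATEGORIES = ("TILE1", "TILE2", "TILE3")


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    gene_id: str
    transcript_id: str
    start_tx: int  # 1-based transcript coordinate
    length: int
    sequence: str
    category: str  # TILE1|TILE2|TILE3|UE|ORGANELLAR|MARKER_CONTROL
    dropped: bool = False
    reason: str = ""

    @property
    def end_tx(self) -> int:
        return self.start_tx + self.length - 1


@dataclass
class ChipManifest:
    probes: list[ProbeRecord]
    controls: list[str]

    @property
    def counts(self) -> dict[str, int]:
        c: dict[str, int] = defaultdict(int)
        for p in self.probes:
            c[p.category] += 1
        return dict(c)

    def kept(self) -> list[ProbeRecord]:
        return [p for p in self.probes if not p.dropped]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "probe_id": p.probe_id,
                    "gene_id": p.gene_id,
                    "transcript_id": p.transcript_id,
                    "start_tx": p.start_tx,
                    "category": p.category,
                    "sequence": p.sequence,
                    "dropped": p.dropped,
                    "reason": p.reason,
                }
                for p in self.probes
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for p in self.probes:
                if not p.dropped:
                    fh.write(f">{p.probe_id}\n{p.sequence}\n")


def _tile_starts(anchor: int, total_len: int) -> list[int]:
    """Start positions of the three tiles for a stop-codon anchor.

    ``anchor`` is where TILE1 ends; TILE3 ends at ``anchor + 60``. The
    frame is clipped so TILE3 never runs past the transcript end.
    """
    anchor = min(anchor, total_len - PROBE_LEN)
    return [anchor - PROBE_LEN + 1, anchor - STEP + 1, anchor + 1]


def tile_probes(
    transcript: TranscriptModel,
    gene_id: str | None = None,
    category_suffix: Mapping[str, str] | None = None,
) -> list[ProbeRecord]:
    """Design up to three stop-codon-anchored tiling probes.

    With >= 60 bases of CDS upstream flank and >= 60 bases of 3'-UTR the
    probes sit at [stop-59, stop], [stop-29, stop+30] and [stop+1, stop+60],
    covering 120 bases split evenly across the CDS/UTR boundary. A short
    3'-UTR shifts the frame upstream by (60 - utr3) bases; probes whose
    start would fall before position 1 are omitted.
    """
    gene_id = gene_id or transcript.gene_id
    seq = transcript.spliced_sequence
    if len(seq) < PROBE_LEN:
        return [
            ProbeRecord(
                probe_id=f"{transcript.transcript_id}_P1",
                gene_id=gene_id,
                transcript_id=transcript.transcript_id,
                start_tx=1,
                length=len(seq),
                sequence=seq,
                category="TILE1",
                dropped=True,
                reason="too short",
            )
        ]
    out = []
    for i, start in enumerate(_tile_starts(transcript.stop_end_tx, len(seq))):
        if start < 1:
            continue
        out.append(
            ProbeRecord(
                probe_id=f"{transcript.transcript_id}_P{i + 1}",
                gene_id=gene_id,
                transcript_id=transcript.transcript_id,
                start_tx=start,
                length=PROBE_LEN,
                sequence=seq[start - 1 : start - 1 + PROBE_LEN],
                category=TILE_CATEGORIES[i],
            )
        )
    return out


def design_ue_probe(
    transcript: TranscriptModel, ue: UniqueExon
) -> ProbeRecord | None:
    """One probe centered in a unique exon, or None if the exon is < 60 nt."""
    if ue.transcript_id != transcript.transcript_id:
        raise ValueError(
            f"unique exon belongs to {ue.transcript_id}, "
            f"not {transcript.transcript_id}"
        )
    lo, hi = ue.exon_interval_tx
    exon_len = hi - lo + 1
    if exon_len < PROBE_LEN:
        return None
    start = lo + (exon_len - PROBE_LEN) // 2
    return ProbeRecord(
        probe_id=f"{transcript.transcript_id}_UE",
        gene_id=transcript.gene_id,
        transcript_id=transcript.transcript_id,
        start_tx=start,
        length=PROBE_LEN,
        sequence=transcript.spliced_sequence[start - 1 : start - 1 + PROBE_LEN],
        category="UE",
    )


def _kmer_gene_index(
    transcriptome: Mapping[str, tuple[str, str]], k: int = PROBE_LEN
) -> dict[str, list[str]]:
    """Map each k-mer of the transcriptome to the genes it occurs in
    (with multiplicity, forward strand only)."""
    index: dict[str, list[str]] = defaultdict(list)
    for _, (gene_id, seq) in transcriptome.items():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].append(gene_id)
    return index


def screen_cross_hybridization(
    probes: Sequence[ProbeRecord],
    transcriptome: Mapping[str, tuple[str, str]],
) -> list[ProbeRecord]:
    """Flag cross-hybridizing probes.

    A probe cross-matches when its exact 60-mer, or the reverse complement,
    occurs in a transcript of a *different* gene (same-gene isoform hits are
    exempt). Per gene at most one of the three tiling probes is dropped:
    the two with the fewest cross-matches are retained (ties keep the
    lower transcript start). Unique-exon probes with any cross-match are
    dropped outright.

    ``transcriptome`` maps transcript_id -> (gene_id, sequence).
    """
    index = _kmer_gene_index(transcriptome)

    def cross_matches(p: ProbeRecord) -> int:
        hits = index.get(p.sequence, []) + index.get(revcomp(p.sequence), [])
        return sum(1 for g in hits if g != p.gene_id)

    n_cross = {p.probe_id: cross_matches(p) if not p.dropped else 0 for p in probes}

    by_gene: dict[str, list[ProbeRecord]] = defaultdict(list)
    for p in probes:
        if p.category in TILE_CATEGORIES and not p.dropped:
            by_gene[p.gene_id].append(p)

    to_drop: set[str] = set()
    for gene_id, tiles in by_gene.items():
        offenders = [p for p in tiles if n_cross[p.probe_id] > 0]
        if not offenders or len(tiles) < 3:
            continue  # keep >= 2 tiling probes per gene
        worst = max(offenders, key=lambda p: (n_cross[p.probe_id], p.start_tx))
        to_drop.add(worst.probe_id)

    out = []
    for p in probes:
        if p.probe_id in to_drop:
            out.append(replace(p, dropped=True, reason="cross-hybridization"))
        elif p.category == "UE" and n_cross.get(p.probe_id, 0) > 0 and not p.dropped:
            out.append(replace(p, dropped=True, reason="cross-hybridization"))
        else:
            out.append(p)
    return out


def _control_transcript(seq_id: str, sequence: str, category: str) -> list[ProbeRecord]:
    """Three end-anchored tiles for a control sequence with no CDS model."""
    seq = sequence.upper()
    if len(seq) < PROBE_LEN:
        return [
            ProbeRecord(
                probe_id=f"{seq_id}_P1",
                gene_id=seq_id,
                transcript_id=seq_id,
                start_tx=1,
                length=len(seq),
                sequence=seq,
                category=category,
                dropped=True,
                reason="too short",
            )
        ]
    out = []
    for i, start in enumerate(_tile_starts(len(seq), len(seq))):
        if start < 1:
            continue
        out.append(
            ProbeRecord(
                probe_id=f"{seq_id}_P{i + 1}",
                gene_id=seq_id,
                transcript_id=seq_id,
                start_tx=start,
                length=PROBE_LEN,
                sequence=seq[start - 1 : start - 1 + PROBE_LEN],
                category=category,
            )
        )
    return out


def assemble_chip(
    gene_models: Sequence[GeneModel],
    organellar: Mapping[str, str] | None = None,
    markers: Mapping[str, str] | None = None,
    screen: bool = True,
) -> ChipManifest:
    """Assemble the full probe manifest.

    Tiling probes are designed for the representative transcript of every
    gene and for each additional annotated isoform; unique-exon probes are
    added where an alternatively spliced representative has a UE >= 60 nt;
    organellar and selection-marker control sequences get end-anchored
    tiles. Identical inputs yield a byte-identical manifest.
    """
    seen: set[str] = set()
    for g in gene_models:
        for t in g.transcripts:
            if t.transcript_id in seen:
                raise ValueError(f"duplicate transcript id {t.transcript_id}")
            seen.add(t.transcript_id)

    probes: list[ProbeRecord] = []
    transcriptome: dict[str, tuple[str, str]] = {}
    for g in gene_models:
        rep = select_representative(g)
        ordered = [rep] + [
            t for t in g.transcripts if t.transcript_id != rep.transcript_id
        ]
        for t in ordered:
            probes.extend(tile_probes(t, gene_id=g.gene_id))
            transcriptome[t.transcript_id] = (g.gene_id, t.spliced_sequence)
        if g.alternatively_spliced:
            for ue in find_unique_exons(g, rep):
                p = design_ue_probe(rep, ue)
                if p is not None:
                    probes.append(p)
                    break  # one UE probe per representative
    controls: list[str] = []
    for mapping, category in (
        (organellar or {}, "ORGANELLAR"),
        (markers or {}, "MARKER_CONTROL"),
    ):
        for seq_id in sorted(mapping):
            probes.extend(_control_transcript(seq_id, mapping[seq_id], category))
            controls.append(seq_id)
    if screen:
        probes = screen_cross_hybridization(probes, transcriptome)
    return ChipManifest(probes=probes, controls=controls)
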
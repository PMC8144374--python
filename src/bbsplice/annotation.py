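"""Transcript annotation (GTF) and genome (FASTA) access for effect prediction.

Reads gene/transcript/exon/CDS/stop_codon features from a GTF with gffutils
and exposes them as lightweight transcript models with 1-based inclusive
genomic coordinates.  The coding span of a transcript is the union of its CDS
and stop_codon features, so it runs from the first base of the start codon to
the last base of the stop codon.  Genome sequence is served through pyfaidx.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
from Bio.Seq import Seq
from pyfaidx import Fasta


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: sorted exons plus the genomic coding span (incl. stop)."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_interval: tuple[int, int] | None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        for (s, e) in exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: empty exon ({s}, {e})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron boundary pairs (last exonic base, first exonic base)."""
        return tuple((a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]))

    @property
    def is_coding(self) -> bool:
        return self.cds_interval is not None

    def contains_position(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)


class Annotation:
    """GTF-backed transcript catalog plus genome sequence access."""

    def __init__(self, gtf_path, fasta_path):
        self._db = gffutils.create_db(
            str(gtf_path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        self._fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
        self.transcripts: dict[str, TranscriptModel] = {}
        self.by_gene: dict[str, list[str]] = {}
        for t in self._db.features_of_type("transcript"):
            tid = t.attributes["transcript_id"][0]
            gid = t.attributes["gene_id"][0]
            exons = sorted((f.start, f.end) for f in self._db.children(t, featuretype="exon"))
            coding = [(f.start, f.end) for f in self._db.children(t, featuretype="CDS")]
            coding += [(f.start, f.end) for f in self._db.children(t, featuretype="stop_codon")]
            cds = (min(s for s, _ in coding), max(e for _, e in coding)) if coding else None
            biotype = t.attributes.get("transcript_biotype", ["protein_coding" if cds else "misc_RNA"])[0]
            model = TranscriptModel(tid, gid, t.seqid, t.strand, tuple(exons), cds, biotype)
            self.transcripts[tid] = model
            self.by_gene.setdefault(gid, []).append(tid)
        for tids in self.by_gene.values():
            tids.sort()
        self._protein_cache: dict[str, str] = {}

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Genome sequence on the forward strand, 1-based inclusive."""
        return str(self._fasta[contig][start - 1:end])

    def coding_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[t] for t in self.by_gene.get(gene_id, [])
                if self.transcripts[t].is_coding]

    def gene_proteins(self, gene_id: str) -> list[str]:
        """Canonical protein sequences (no trailing stop mark) for one gene."""
        proteins = []
        for t in self.coding_transcripts(gene_id):
            if t.transcript_id not in self._protein_cache:
                p = translate_transcript(t, self)
                self._protein_cache[t.transcript_id] = (p or "").rstrip("*")
            if self._protein_cache[t.transcript_id]:
                proteins.append(self._protein_cache[t.transcript_id])
        return proteins


def spliced_sequence(transcript: TranscriptModel, genome: Annotation) -> str:
    """Mature transcript sequence 5'->3' (reverse-complemented on '-')."""
    seq = "".join(genome.fetch(transcript.contig, s, e) for s, e in transcript.exons)
    if transcript.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _transcript_offset(transcript: TranscriptModel, genomic_pos: int) -> int | None:
    """0-based offset of a genomic position within the mature (5'->3') sequence."""
    if not transcript.contains_position(genomic_pos):
        return None
    off = 0
    if transcript.strand == "+":
        for s, e in transcript.exons:
            if s <= genomic_pos <= e:
                return off + (genomic_pos - s)
            off += e - s + 1
    else:
        for s, e in reversed(transcript.exons):
            if s <= genomic_pos <= e:
                return off + (e - genomic_pos)
            off += e - s + 1
    return None


def translate_transcript(transcript: TranscriptModel, genome: Annotation) -> str | None:
    """Translate from the annotated start codon to the first stop codon.

    Returns the protein with a trailing ``'*'`` when a stop codon is reached;
    a protein without ``'*'`` means translation ran off the end of the
    transcript (stop lost).  Returns None when the transcript is non-coding or
    the start codon is absent from the (possibly edited) exon structure.
    """
    if transcript.cds_interval is None:
        return None
    start_genomic = (transcript.cds_interval[0] if transcript.strand == "+"
                     else transcript.cds_interval[1])
    offset = _transcript_offset(transcript, start_genomic)
    if offset is None:
        return None
    mrna = spliced_sequence(transcript, genome)
    coding = mrna[offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    if len(coding) < 3:
        return None
    protein = str(Seq(coding).translate())
    stop = protein.find("*")
    return protein[: stop + 1] if stop >= 0 else protein
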
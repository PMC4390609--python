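"""Construction of the 3'-UTR sequence space and the mature-miRNA registry.

The target-prediction engines in this package all scan one shared sequence
space: one 3'-UTR per transcript isoform, for *every* annotated biotype
(coding, non-coding, pseudogene).  Transcripts whose annotated 3'-UTR is
missing or shorter than ``min_utr_length`` (default 50 nt) receive a proxy
UTR instead: the ``proxy_length`` (default 130 nt) genomic bases immediately
downstream of the last exon, in transcription direction.  130 nt is the
rounded mode of known 3'-UTR lengths across human, mouse and rat.

Coordinates are 0-based half-open throughout; GTF input (1-based inclusive)
is converted on read, and BED output keeps the internal convention.
Sequences are held in RNA alphabet (ACGU), 5'->3'.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pyfaidx
from Bio import SeqIO

log = logging.getLogger(__name__)

_RNA_COMPLEMENT = str.maketrans("ACGUTacgut", "UGCAAugcaa")


def to_rna(seq: str) -> str:
    """Uppercase and normalize T->U."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    """Reverse complement in RNA space (accepts DNA input, returns RNA)."""
    return seq.translate(_RNA_COMPLEMENT)[::-1].upper()


class AnnotationError(ValueError):
    """Raised for unusable genome/annotation combinations."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript isoform with its exon chain.

    ``cds_end`` is the genomic boundary between the coding region (stop codon
    included) and the 3'-UTR: on '+', UTR bases are exonic positions at or
    beyond ``cds_end``; on '-', exonic positions strictly below it.  ``None``
    for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    biotype: str
    exons: tuple[GenomeInterval, ...]
    cds_end: int | None = None
    principal_isoform: bool | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons on mixed chrom/strand")
        prev_end = -1
        for e in self.exons:
            if e.start < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand


@dataclass(frozen=True)
class UTRRecord:
    """One 3'-UTR sequence with its (possibly spliced) genomic mapping.

    ``intervals`` are stored in genomic order; the sequence is 5'->3' in
    transcription direction, so for '-' strand records the first sequence
    base maps to the *last* interval's rightmost position.
    """

    transcript_id: str
    sequence: str
    intervals: tuple[GenomeInterval, ...]
    utr_source: str  # "annotated" | "proxy"
    gene_id: str = ""
    gene_symbol: str = ""
    biotype: str = ""
    principal_isoform: bool | None = None

    def __post_init__(self) -> None:
        if self.utr_source not in ("annotated", "proxy"):
            raise ValueError(f"bad utr_source {self.utr_source!r}")
        if sum(len(iv) for iv in self.intervals) != len(self.sequence):
            raise ValueError(
                f"{self.transcript_id}: interval span != sequence length"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def chrom(self) -> str:
        return self.intervals[0].chrom

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    def _blocks_tx_order(self) -> list[GenomeInterval]:
        blocks = list(self.intervals)
        return blocks[::-1] if self.strand == "-" else blocks

    def local_to_genomic(self, lo: int, hi: int) -> tuple[GenomeInterval, ...]:
        """Map a local [lo, hi) span to genomic intervals (genomic order)."""
        if not (0 <= lo < hi <= self.length):
            raise ValueError(f"local span [{lo}, {hi}) outside UTR of {self.length}")
        pieces: list[GenomeInterval] = []
        acc = 0
        for block in self._blocks_tx_order():
            blen = len(block)
            a, b = max(lo, acc), min(hi, acc + blen)
            if a < b:
                oa, ob = a - acc, b - acc
                if self.strand == "+":
                    pieces.append(
                        GenomeInterval(block.chrom, block.start + oa, block.start + ob, "+")
                    )
                else:
                    pieces.append(
                        GenomeInterval(block.chrom, block.end - ob, block.end - oa, "-")
                    )
            acc += blen
        return tuple(sorted(pieces, key=lambda p: p.start))

    def genomic_to_local(self, interval: GenomeInterval) -> tuple[int, int]:
        """Inverse of :meth:`local_to_genomic` for a contiguous genomic piece.

        Returns the local [lo, hi) span covered; the piece must lie within a
        single UTR block.
        """
        acc = 0
        for block in self._blocks_tx_order():
            blen = len(block)
            if (
                interval.chrom == block.chrom
                and block.start <= interval.start
                and interval.end <= block.end
            ):
                if self.strand == "+":
                    lo = acc + (interval.start - block.start)
                else:
                    lo = acc + (block.end - interval.end)
                return lo, lo + len(interval)
            acc += blen
        raise ValueError(f"{interval} not contained in UTR blocks of {self.transcript_id}")


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA with its precomputed seed (positions 2-8, 5'->3')."""

    mirna_id: str
    sequence: str  # RNA, 5'->3'
    accession: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 15:
            raise ValueError(f"{self.mirna_id}: mature sequence shorter than 15 nt")
        bad = set(self.sequence) - set("ACGU")
        if bad:
            raise ValueError(f"{self.mirna_id}: non-ACGU characters {sorted(bad)}")

    @property
    def seed(self) -> str:
        """Nucleotides 2-8 (1-based), the 7-nt seed region."""
        return self.sequence[1:8]

    @property
    def organism(self) -> str:
        return self.mirna_id.split("-", 1)[0]


# ---------------------------------------------------------------------------
# genome access helpers


def _contig_names(genome) -> set[str]:
    if isinstance(genome, Mapping):
        return set(genome.keys())
    return set(genome.keys())


def _contig_len(genome, chrom: str) -> int:
    if isinstance(genome, Mapping):
        return len(genome[chrom])
    return len(genome[chrom])


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genomic [start, end) as an uppercase DNA/RNA string."""
    if isinstance(genome, Mapping):
        return genome[chrom][start:end].upper()
    return str(genome[chrom][start:end]).upper()


# ---------------------------------------------------------------------------
# annotation loading


_BIOTYPE_KEYS = ("transcript_biotype", "gene_biotype", "biotype", "transcript_type", "gene_type")


def load_annotation(gtf_path, genome_path) -> list[TranscriptRecord]:
    """Read transcript models from a GTF against an indexed genome FASTA.

    All biotypes are retained.  A transcript referencing a contig absent from
    the FASTA is a hard error; a transcript with no exon features is skipped
    with a warning.
    """
    genome = pyfaidx.Fasta(str(genome_path))
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    contigs = set(genome.keys())
    records: list[TranscriptRecord] = []
    for tx in db.features_of_type("transcript", order_by=("seqid", "start")):
        if tx.seqid not in contigs:
            raise AnnotationError(
                f"contig {tx.seqid!r} (transcript {tx.id}) absent from genome FASTA"
            )
        exons = sorted(
            db.children(tx, featuretype="exon"), key=lambda f: f.start
        )
        if not exons:
            log.warning("transcript %s has no exons; skipped", tx.id)
            continue
        strand = tx.strand
        exon_ivs = tuple(
            GenomeInterval(e.seqid, e.start - 1, e.end, strand) for e in exons
        )
        cds = list(db.children(tx, featuretype=("CDS", "stop_codon")))
        cds_end: int | None = None
        if cds:
            if strand == "+":
                cds_end = max(f.end for f in cds)  # 0-based exclusive == 1-based end
            else:
                cds_end = min(f.start for f in cds) - 1
        attrs = tx.attributes
        def _attr(*keys: str) -> str | None:
            for k in keys:
                if k in attrs and attrs[k]:
                    return attrs[k][0]
            return None

        biotype = _attr(*_BIOTYPE_KEYS) or "unknown"
        gene_id = _attr("gene_id") or tx.id
        gene_symbol = _attr("gene_name", "gene_symbol") or gene_id
        principal: bool | None = None
        tags = attrs.get("tag", [])
        if any(t.startswith("appris_principal") for t in tags):
            principal = True
        elif "principal_isoform" in attrs:
            principal = attrs["principal_isoform"][0] in ("1", "true", "True")
        records.append(
            TranscriptRecord(
                transcript_id=tx.id,
                gene_id=gene_id,
                gene_symbol=gene_symbol,
                biotype=biotype,
                exons=exon_ivs,
                cds_end=cds_end,
                principal_isoform=principal,
            )
        )
    return records


# ---------------------------------------------------------------------------
# UTR extraction


def _annotated_utr_parts(tx: TranscriptRecord) -> list[GenomeInterval]:
    """Exonic pieces 3' of the stop codon, in genomic order."""
    if tx.cds_end is None:
        return []
    parts: list[GenomeInterval] = []
    for e in tx.exons:
        if tx.strand == "+":
            s, t = max(e.start, tx.cds_end), e.end
        else:
            s, t = e.start, min(e.end, tx.cds_end)
        if s < t:
            parts.append(GenomeInterval(e.chrom, s, t, tx.strand))
    return parts


def _splice(genome, parts: Sequence[GenomeInterval], strand: str) -> str:
    raw = "".join(_fetch(genome, p.chrom, p.start, p.end) for p in parts)
    rna = to_rna(raw)
    return reverse_complement(rna) if strand == "-" else rna


def extract_3utr(
    tx: TranscriptRecord,
    genome,
    proxy_length: int = 130,
    min_utr_length: int = 50,
) -> UTRRecord:
    """Extract the transcript's 3'-UTR, falling back to the proxy rule.

    An annotated UTR (exonic sequence 3' of ``cds_end``) of at least
    ``min_utr_length`` nt is returned spliced, strand-corrected and in RNA
    alphabet.  Otherwise the ``proxy_length`` genomic bases immediately
    downstream of the last exon (transcription direction, unspliced) are used;
    a proxy window running off the contig is truncated with a warning.
    """
    meta = dict(
        gene_id=tx.gene_id,
        gene_symbol=tx.gene_symbol,
        biotype=tx.biotype,
        principal_isoform=tx.principal_isoform,
    )
    parts = _annotated_utr_parts(tx)
    utr_len = sum(len(p) for p in parts)
    if parts and utr_len >= min_utr_length:
        seq = _splice(genome, parts, tx.strand)
        return UTRRecord(tx.transcript_id, seq, tuple(parts), "annotated", **meta)

    clen = _contig_len(genome, tx.chrom)
    if tx.strand == "+":
        start = tx.exons[-1].end
        end = min(start + proxy_length, clen)
    else:
        end = tx.exons[0].start
        start = max(end - proxy_length, 0)
    if start >= end:
        raise AnnotationError(
            f"{tx.transcript_id}: proxy UTR window empty at contig boundary"
        )
    if end - start < proxy_length:
        log.warning(
            "%s: proxy UTR truncated to %d nt at contig boundary",
            tx.transcript_id,
            end - start,
        )
    iv = GenomeInterval(tx.chrom, start, end, tx.strand)
    seq = _splice(genome, [iv], tx.strand)
    return UTRRecord(tx.transcript_id, seq, (iv,), "proxy", **meta)


def build_utr_space(
    transcripts: Iterable[TranscriptRecord],
    genome,
    proxy_length: int = 130,
    min_utr_length: int = 50,
) -> list[UTRRecord]:
    """Extract one UTRRecord per transcript (all biotypes)."""
    return [
        extract_3utr(tx, genome, proxy_length=proxy_length, min_utr_length=min_utr_length)
        for tx in transcripts
    ]


def mode_utr_length(utrs: Iterable[UTRRecord]) -> int:
    """Most frequent annotated-UTR length; ties broken by the smaller value."""
    lengths = [u.length for u in utrs if u.utr_source == "annotated"]
    if not lengths:
        raise ValueError("no annotated UTRs to take the mode of")
    counts = Counter(lengths)
    best = max(counts.values())
    return min(l for l, c in counts.items() if c == best)


# ---------------------------------------------------------------------------
# miRNA registry

_ACCESSION_RE = re.compile(r"^MIMAT\d+$|^MI\d+$")


def load_mirnas(fasta_path, organism_filter: str | None = None) -> list[MiRNARecord]:
    """Load mature miRNAs from a miRBase-style FASTA.

    Sequences are normalized T->U; the organism is parsed from the id prefix
    (``hsa-``, ``mmu-``, ...).  Duplicate ids and non-ACGU(T) characters are
    errors naming the offending record.
    """
    records: dict[str, MiRNARecord] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        mirna_id = rec.id
        if mirna_id in records:
            raise ValueError(f"duplicate miRNA id {mirna_id!r}")
        tokens = rec.description.split()
        accession = next((t for t in tokens[1:] if _ACCESSION_RE.match(t)), None)
        seq = to_rna(str(rec.seq))
        records[mirna_id] = MiRNARecord(mirna_id, seq, accession)
    out = list(records.values())
    if organism_filter:
        prefix = organism_filter.rstrip("-") + "-"
        out = [m for m in out if m.mirna_id.startswith(prefix)]
    return out


# ---------------------------------------------------------------------------
# serialization: FASTA + BED12 + metadata TSV

_META_COLUMNS = (
    "transcript_id",
    "gene_id",
    "gene_symbol",
    "biotype",
    "utr_source",
    "length",
    "principal_isoform",
)


def write_utr_fasta(utrs: Sequence[UTRRecord], path) -> None:
    with open(path, "w") as fh:
        for u in utrs:
            fh.write(f">{u.transcript_id}\n")
            for i in range(0, len(u.sequence), 60):
                fh.write(u.sequence[i : i + 60] + "\n")


def write_utr_bed(utrs: Sequence[UTRRecord], path) -> None:
    """BED12; blocks are the (spliced) UTR intervals, 0-based half-open."""
    with open(path, "w") as fh:
        for u in utrs:
            start = min(iv.start for iv in u.intervals)
            end = max(iv.end for iv in u.intervals)
            sizes = ",".join(str(len(iv)) for iv in u.intervals)
            offsets = ",".join(str(iv.start - start) for iv in u.intervals)
            fh.write(
                "\t".join(
                    [
                        u.chrom,
                        str(start),
                        str(end),
                        u.transcript_id,
                        "0",
                        u.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(u.intervals)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def write_utr_metadata(utrs: Sequence[UTRRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_META_COLUMNS) + "\n")
        for u in utrs:
            principal = "" if u.principal_isoform is None else str(int(u.principal_isoform))
            fh.write(
                "\t".join(
                    [
                        u.transcript_id,
                        u.gene_id,
                        u.gene_symbol,
                        u.biotype,
                        u.utr_source,
                        str(u.length),
                        principal,
                    ]
                )
                + "\n"
            )


def read_utr_space(fasta_path, bed_path, metadata_path=None) -> list[UTRRecord]:
    """Rebuild UTRRecords from the FASTA + BED12 (+ metadata TSV) trio."""
    seqs = {rec.id: to_rna(str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    meta: dict[str, dict] = {}
    if metadata_path is not None:
        import csv

        with open(metadata_path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                principal = row.get("principal_isoform", "")
                meta[row["transcript_id"]] = dict(
                    gene_id=row.get("gene_id", ""),
                    gene_symbol=row.get("gene_symbol", ""),
                    biotype=row.get("biotype", ""),
                    utr_source=row.get("utr_source", "annotated"),
                    principal_isoform=None if principal == "" else bool(int(principal)),
                )
    utrs: list[UTRRecord] = []
    with open(bed_path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            ivs = tuple(
                GenomeInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offsets, sizes)
            )
            m = meta.get(name, {})
            utrs.append(
                UTRRecord(
                    transcript_id=name,
                    sequence=seqs[name],
                    intervals=ivs,
                    utr_source=m.get("utr_source", "annotated"),
                    gene_id=m.get("gene_id", ""),
                    gene_symbol=m.get("gene_symbol", ""),
                    biotype=m.get("biotype", ""),
                    principal_isoform=m.get("principal_isoform"),
                )
            )
    return utrs
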
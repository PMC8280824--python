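"""Genome/annotation input and intron catalog extraction.

Reads a genome FASTA and a transcript GTF, and derives a deduplicated
catalog of introns with the strand-aware sequence windows the U12-type
classifier needs: the donor (5' splice site) region at the intron start
and the last ``bps_search_len`` transcribed nucleotides, which contain
the branch-point search window upstream of the 3' splice site.

Coordinates are 0-based half-open internally; GTF input is 1-based
inclusive; BED output is 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Introns shorter than this are skipped: the branch-point search window
#: (-40..-3 of the 3'ss) must retain room for at least one motif window.
MIN_INTRON_LENGTH = 30

#: Transcribed nucleotides kept from the intron start (extended U12 5'ss).
DEFAULT_DONOR_WINDOW = 9

#: Transcribed nucleotides kept from the intron end (covers -40..-1).
DEFAULT_BPS_SEARCH_LEN = 40


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """In-memory genome with strand-aware interval lookup.

    Sequences are stored upper-cased. ``fetch`` on the minus strand
    returns the reverse complement of the genomic interval, i.e. the
    transcribed sequence of a minus-strand feature.
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("genome contains no sequences")
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self._seqs

    def __getitem__(self, contig: str) -> str:
        return self._seqs[contig]

    @property
    def contigs(self) -> list[str]:
        return list(self._seqs)

    def length(self, contig: str) -> int:
        return len(self._seqs[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Return the transcribed sequence of [start, end) on ``strand``."""
        if contig not in self._seqs:
            raise KeyError(f"unknown contig {contig!r}")
        seq = self._seqs[contig]
        if start < 0 or end > len(seq) or start >= end:
            raise ValueError(
                f"interval [{start},{end}) out of bounds for contig "
                f"{contig!r} of length {len(seq)}"
            )
        sub = seq[start:end]
        return reverse_complement(sub) if strand == "-" else sub


def read_genome(path: str) -> Genome:
    """Read a FASTA file into a :class:`Genome` (sequences upper-cased)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(records)


@dataclass
class TranscriptModel:
    """One transcript as an ordered list of exon intervals.

    ``exons`` are 0-based half-open, sorted in genomic order and
    non-overlapping.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")


def read_annotation(path: str) -> list[TranscriptModel]:
    """Read exon features from a GTF into transcript models.

    GTF 1-based inclusive coordinates are converted to 0-based
    half-open. A GTF without exon features yields an empty list with a
    warning; an exon feature lacking a ``transcript_id`` attribute is an
    error.
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, TranscriptModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    n_exons = 0
    for feat in db.features_of_type("exon"):
        n_exons += 1
        tids = feat.attributes.get("transcript_id")
        if not tids:
            raise ValueError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks transcript_id"
            )
        gids = feat.attributes.get("gene_id") or ["NA"]
        tid = tids[0]
        exons.setdefault(tid, []).append((feat.start - 1, feat.end))
        meta.setdefault(tid, (gids[0], feat.seqid, feat.strand))
    if n_exons == 0:
        warnings.warn(f"no exon features in {path}; returning empty collection")
        return []
    for tid, ivals in exons.items():
        gene_id, contig, strand = meta[tid]
        grouped[tid] = TranscriptModel(
            transcript_id=tid, gene_id=gene_id, contig=contig,
            strand=strand, exons=ivals,
        )
    return list(grouped.values())


@dataclass(frozen=True)
class Intron:
    """A deduplicated intron with its classifier-facing sequence windows.

    ``donor_region_seq`` is the first ``donor_window`` transcribed
    intronic nucleotides; ``three_prime_region_seq`` the last
    ``bps_search_len`` (both strand-aware). ``terminal_label`` is e.g.
    ``"AT-AC"`` or ``"GT-AG"``.
    """

    contig: str
    start: int
    end: int
    strand: str
    host_gene: str
    intron_index: int
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    terminal_label: str
    donor_region_seq: str
    three_prime_region_seq: str

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}:{self.strand}"

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_introns(
    transcripts: list[TranscriptModel],
    genome: Genome,
    donor_window: int = DEFAULT_DONOR_WINDOW,
    bps_search_len: int = DEFAULT_BPS_SEARCH_LEN,
    min_intron_length: int = MIN_INTRON_LENGTH,
) -> list[Intron]:
    """Extract the deduplicated intron catalog from transcript models.

    One intron per gap between consecutive exons; introns identical in
    (contig, start, end, strand) across transcripts are emitted once,
    with ``host_gene`` taken from the first contributing transcript.
    ``intron_index`` is the 1-based ordinal of the intron within its
    host gene in transcription order (5' to 3' of the gene).
    """
    seen: dict[tuple[str, int, int, str], str] = {}
    order: list[tuple[str, int, int, str]] = []
    for tx in transcripts:
        if tx.contig not in genome:
            raise KeyError(
                f"transcript {tx.transcript_id}: contig {tx.contig!r} not in genome"
            )
        for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
            key = (tx.contig, e1, s2, tx.strand)
            if key in seen:
                if seen[key] != tx.gene_id:
                    logger.warning(
                        "intron %s shared by genes %s and %s; keeping %s",
                        key, seen[key], tx.gene_id, seen[key],
                    )
                continue
            seen[key] = tx.gene_id
            order.append(key)

    # transcription-order index per gene
    per_gene: dict[str, list[tuple[str, int, int, str]]] = {}
    for key in order:
        per_gene.setdefault(seen[key], []).append(key)
    index_of: dict[tuple[str, int, int, str], int] = {}
    for gene, keys in per_gene.items():
        minus = keys[0][3] == "-"
        for i, key in enumerate(
            sorted(keys, key=lambda k: k[1], reverse=minus), start=1
        ):
            index_of[key] = i

    introns: list[Intron] = []
    for key in order:
        contig, start, end, strand = key
        if end - start < min_intron_length:
            warnings.warn(
                f"intron {contig}:{start}-{end} shorter than "
                f"{min_intron_length} nt; skipped"
            )
            continue
        if end > genome.length(contig):
            raise ValueError(
                f"intron {contig}:{start}-{end} extends beyond contig end"
            )
        seq = genome.fetch(contig, start, end, strand)
        donor = seq[:2]
        acceptor = seq[-2:]
        introns.append(
            Intron(
                contig=contig,
                start=start,
                end=end,
                strand=strand,
                host_gene=seen[key],
                intron_index=index_of[key],
                donor_dinucleotide=donor,
                acceptor_dinucleotide=acceptor,
                terminal_label=f"{donor}-{acceptor}",
                donor_region_seq=seq[:donor_window],
                three_prime_region_seq=seq[-bps_search_len:],
            )
        )
    return introns


_TSV_COLUMNS = [
    "intron_key", "contig", "start", "end", "strand", "host_gene",
    "intron_index", "donor_dinucleotide", "acceptor_dinucleotide",
    "terminal_label", "donor_region_seq", "three_prime_region_seq",
]


def introns_to_frame(introns: list[Intron]) -> pd.DataFrame:
    rows = [
        {
            "intron_key": it.key,
            "contig": it.contig,
            "start": it.start,
            "end": it.end,
            "strand": it.strand,
            "host_gene": it.host_gene,
            "intron_index": it.intron_index,
            "donor_dinucleotide": it.donor_dinucleotide,
            "acceptor_dinucleotide": it.acceptor_dinucleotide,
            "terminal_label": it.terminal_label,
            "donor_region_seq": it.donor_region_seq,
            "three_prime_region_seq": it.three_prime_region_seq,
        }
        for it in introns
    ]
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_intron_tsv(introns: list[Intron], path: str) -> None:
    introns_to_frame(introns).to_csv(path, sep="\t", index=False)


def read_intron_tsv(path: str) -> list[Intron]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Intron(
                contig=str(row.contig),
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                host_gene=row.host_gene,
                intron_index=int(row.intron_index),
                donor_dinucleotide=row.donor_dinucleotide,
                acceptor_dinucleotide=row.acceptor_dinucleotide,
                terminal_label=row.terminal_label,
                donor_region_seq=row.donor_region_seq,
                three_prime_region_seq=row.three_prime_region_seq,
            )
        )
    return out


def write_intron_bed(introns: list[Intron], path: str) -> None:
    """BED6 catalog; name is ``gene:index:label``."""
    with open(path, "w") as fh:
        for it in introns:
            name = f"{it.host_gene}:{it.intron_index}:{it.terminal_label}"
            fh.write(
                f"{it.contig}\t{it.start}\t{it.end}\t{name}\t0\t{it.strand}\n"
            )


def read_intron_bed(path: str) -> list[tuple[str, int, int, str]]:
    """Read back the (contig, start, end, strand) tuples of a BED6 catalog."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[5]))
    return out
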
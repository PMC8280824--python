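"""Synthetic study-condition generators for every pipeline stage.

Three generators, all pure functions of (config, seed):

* a toy genome/annotation pair whose genes carry minor A-type
  (AT-AC), minor G-type (GT-AG / GC-AG), major (GT-AG) and major
  AT-AC introns — minor introns get a planted U12 5' splice-site
  motif and a planted branch point inside the -40..-3 window, major
  introns the major-spliceosome consensus;
* two-condition replicate read counts with subtype-dependent
  retention shifts (A-type ΔΨ 0.36, G-type ΔΨ 0.07 by default, on
  baseline Ψ levels around 0.08-0.13) and beta-binomial replicate
  overdispersion, optionally realized as SAM records;
* binary phylogenetic profiles with a planted co-occurring module.

Default design is 3 vs 3 replicates at a per-replicate mean coverage
of 67 informative reads per intron (about 200 pooled per condition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import Genome, TranscriptModel, reverse_complement
from .motifs import MAJOR_FIVE_PRIME_CONSENSUS

_BASES = np.array(list("ACGT"))

CLASS_MINOR_A = "minor_A"
CLASS_MINOR_G = "minor_G"
CLASS_MAJOR = "major"
CLASS_MAJOR_ATAC = "major_AT_AC"

#: 5' splice-site motifs planted per class, with sampling weights.
_FIVE_PRIME_CHOICES = {
    CLASS_MINOR_A: (["ATATCCTTT", "ATATCCTTC"], [0.8, 0.2]),
    CLASS_MINOR_G: (["GTATCCTTT", "GTATCCTTC", "GCATCCTTT"], [0.7, 0.15, 0.15]),
    CLASS_MAJOR: ([MAJOR_FIVE_PRIME_CONSENSUS], [1.0]),
    CLASS_MAJOR_ATAC: (["AT" + MAJOR_FIVE_PRIME_CONSENSUS[2:]], [1.0]),
}

_BPS_CHOICES = (
    ["TTCCTTAAC", "CTCCTTAAC", "TTCCTTGAC", "TTCCTTAAT", "TCCCTTAAC"],
    [0.6, 0.1, 0.1, 0.1, 0.1],
)

_ACCEPTOR = {
    CLASS_MINOR_A: "AC",
    CLASS_MINOR_G: "AG",
    CLASS_MAJOR: "AG",
    CLASS_MAJOR_ATAC: "AC",
}


def _default_baseline_psi() -> dict:
    # control-condition retention levels of retained A/G minor introns
    # and low-level background retention of major introns
    return {
        CLASS_MINOR_A: 0.115,
        CLASS_MINOR_G: 0.130,
        CLASS_MAJOR: 0.05,
        CLASS_MAJOR_ATAC: 0.05,
    }


def _default_delta_psi() -> dict:
    # planted treatment shifts: strong for A-type, weak for G-type
    return {
        CLASS_MINOR_A: 0.36,
        CLASS_MINOR_G: 0.07,
        CLASS_MAJOR: 0.0,
        CLASS_MAJOR_ATAC: 0.0,
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study design."""

    seed: int = 0
    n_minor_a: int = 25
    n_minor_g: int = 25
    n_major: int = 180
    n_major_atac: int = 20
    exon_length: int = 100
    intron_length: int = 150
    read_length: int = 100
    baseline_psi: dict = field(default_factory=_default_baseline_psi)
    delta_psi: dict = field(default_factory=_default_delta_psi)
    coverage_mean: float = 67.0
    coverage_dispersion: float = 0.1
    rho: float = 0.02
    replicates_control: int = 3
    replicates_treatment: int = 3

    def __post_init__(self) -> None:
        bps_margin = 40 + 2  # BPS search window + acceptor dinucleotide
        if self.intron_length < 9 + bps_margin:
            raise ValueError(
                "intron_length too short for the 5'ss motif plus the "
                "-40..-3 branch-point window"
            )
        for cls, base in self.baseline_psi.items():
            if not 0 <= base <= 1:
                raise ValueError(f"baseline psi for {cls} outside [0,1]")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _choice(rng: np.random.Generator, options, weights) -> str:
    return options[rng.choice(len(options), p=weights)]


def _intron_sequence(
    rng: np.random.Generator, cls: str, intron_length: int
) -> tuple[str, int]:
    """Build one transcribed intron sequence; returns (seq, bps_offset)."""
    five = _choice(rng, *_FIVE_PRIME_CHOICES[cls])
    middle = _random_dna(rng, intron_length - len(five) - 40)
    tail = list(_random_dna(rng, 40))
    bps_offset = -1
    if cls in (CLASS_MINOR_A, CLASS_MINOR_G):
        bps = _choice(rng, *_BPS_CHOICES)
        bps_offset = int(rng.integers(-40, -10))  # start in [-40, -11]
        start = 40 + bps_offset
        tail[start : start + len(bps)] = list(bps)
    acceptor = _ACCEPTOR[cls]
    tail[-2:] = list(acceptor)
    return five + middle + "".join(tail), bps_offset


def simulate_genome(
    config: SimulationConfig,
) -> tuple[Genome, list[TranscriptModel], pd.DataFrame]:
    """Generate the toy genome, one single-intron transcript per gene.

    Each gene sits on its own contig (exon-intron-exon, alternating
    strands) and carries exactly one intron of its class. Returns the
    genome, the transcript models, and the truth table.
    """
    rng = np.random.default_rng(config.seed)
    classes = (
        [CLASS_MINOR_A] * config.n_minor_a
        + [CLASS_MINOR_G] * config.n_minor_g
        + [CLASS_MAJOR] * config.n_major
        + [CLASS_MAJOR_ATAC] * config.n_major_atac
    )
    ex, il = config.exon_length, config.intron_length
    contig_len = 2 * ex + il
    seqs: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    truth_rows = []
    for i, cls in enumerate(classes):
        gene = f"gene{i + 1:04d}"
        contig = f"ctg{i + 1:04d}"
        strand = "+" if i % 2 == 0 else "-"
        intron_seq, bps_offset = _intron_sequence(rng, cls, il)
        transcribed = _random_dna(rng, ex) + intron_seq + _random_dna(rng, ex)
        seqs[contig] = transcribed if strand == "+" else reverse_complement(transcribed)
        # symmetric layout: the intron occupies [ex, ex+il) genomically
        # on either strand
        exons = [(0, ex), (ex + il, contig_len)]
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene}.t1", gene_id=gene, contig=contig,
                strand=strand, exons=exons,
            )
        )
        donor = intron_seq[:2]
        acceptor = intron_seq[-2:]
        base = config.baseline_psi[cls]
        delta = config.delta_psi[cls]
        subtype = {"AT": "A"}.get(donor, "G" if donor in ("GT", "GC") else "")
        if cls in (CLASS_MAJOR, CLASS_MAJOR_ATAC):
            subtype = ""
        truth_rows.append(
            {
                "gene": gene,
                "contig": contig,
                "strand": strand,
                "intron_start": ex,
                "intron_end": ex + il,
                "intron_key": f"{contig}:{ex}-{ex + il}:{strand}",
                "class_label": cls,
                "subtype": subtype,
                "terminal_label": f"{donor}-{acceptor}",
                "psi_control": base,
                "psi_treatment": float(np.clip(base + delta, 0.0, 1.0)),
                "bps_offset": bps_offset,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return Genome(seqs), transcripts, truth


def write_genome_fasta(genome: Genome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in genome.contigs:
            fh.write(f">{contig}\n")
            seq = genome[contig]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(transcripts: list[TranscriptModel], path: str) -> None:
    """Write transcript models as GTF exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            lo = tx.exons[0][0] + 1
            hi = tx.exons[-1][1]
            fh.write(
                f"{tx.contig}\tminorlens\ttranscript\t{lo}\t{hi}\t.\t{tx.strand}\t.\t{attrs}\n"
            )
            for s, e in tx.exons:
                fh.write(
                    f"{tx.contig}\tminorlens\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def _negative_binomial(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if dispersion <= 0:
        return int(rng.poisson(mean))
    size = 1.0 / dispersion
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def simulate_counts(
    truth: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
    rho: float | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Draw per-replicate retention counts from the truth table.

    Per intron and replicate the number of informative units is
    negative-binomial around the mean coverage; the retained count is
    beta-binomial around the condition's true Ψ with intra-class
    correlation ``rho``. Emitted as a counts table with J = spliced
    junctions, B = 2 x retained boundary evidence, R = retained body
    reads. Returns (counts, design map sample -> condition).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rho = config.rho if rho is None else rho
    samples = [
        (f"control_{j + 1}", "control", "psi_control")
        for j in range(config.replicates_control)
    ] + [
        (f"treatment_{j + 1}", "treatment", "psi_treatment")
        for j in range(config.replicates_treatment)
    ]
    body_per_unit = max(config.intron_length // config.read_length, 1)
    rows = []
    for t in truth.itertuples(index=False):
        for sample, _cond, psi_col in samples:
            psi = getattr(t, psi_col)
            n = _negative_binomial(rng, config.coverage_mean, config.coverage_dispersion)
            if n == 0:
                r = 0
            elif rho > 0 and 0 < psi < 1:
                a = psi * (1 - rho) / rho
                b = (1 - psi) * (1 - rho) / rho
                r = int(rng.binomial(n, rng.beta(a, b)))
            else:
                r = int(rng.binomial(n, psi))
            rows.append(
                {
                    "intron_key": t.intron_key,
                    "sample": sample,
                    "J": n - r,
                    "B": 2 * r,
                    "R": r * body_per_unit,
                }
            )
    counts = pd.DataFrame(rows, columns=["intron_key", "sample", "J", "B", "R"])
    design = {s: cond for s, cond, _ in samples}
    return counts, design


def write_sam(
    counts: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
    path: str,
    sample: str,
) -> None:
    """Realize one sample's counts as SAM records.

    Each spliced unit becomes one junction read (two half-read blocks
    across the intron gap); each retained unit becomes two boundary
    reads, one per exon-intron boundary. Sequences are omitted ('*').
    """
    half = config.read_length // 2
    by_key = truth.set_index("intron_key")
    contig_len = 2 * config.exon_length + config.intron_length
    sub = counts[counts["sample"] == sample]
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for contig in by_key["contig"]:
            fh.write(f"@SQ\tSN:{contig}\tLN:{contig_len}\n")
        qn = 0
        for row in sub.itertuples(index=False):
            t = by_key.loc[row.intron_key]
            contig, start, end = t["contig"], int(t["intron_start"]), int(t["intron_end"])
            ilen = end - start
            for _ in range(int(row.J)):
                qn += 1
                pos = start - half + 1  # 1-based
                cigar = f"{half}M{ilen}N{half}M"
                fh.write(
                    f"r{qn}\t0\t{contig}\t{pos}\t60\t{cigar}\t*\t0\t0\t*\t*\n"
                )
            for boundary in (start, end):
                for _ in range(int(row.B) // 2):
                    qn += 1
                    pos = boundary - half + 1
                    fh.write(
                        f"r{qn}\t0\t{contig}\t{pos}\t60\t{config.read_length}M\t*\t0\t0\t*\t*\n"
                    )


def simulate_profiles(
    n_genes: int = 100,
    n_species: int = 60,
    module_size: int = 10,
    flip_prob: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Binary phylogenetic profiles with a planted co-occurring module.

    The query gene and ``module_size - 1`` partners share one random
    loss pattern; all other genes get independent random profiles;
    every entry is then flipped with probability ``flip_prob``.
    Returns (matrix, truth) with truth holding the query id and the
    module member set (query included).
    """
    if module_size > n_genes:
        raise ValueError("module_size cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 2, size=n_species)
    while base.min() == base.max():  # a constant pattern carries no signal
        base = rng.integers(0, 2, size=n_species)
    genes = ["QUERY"] + [f"MOD{i:02d}" for i in range(1, module_size)] + [
        f"G{i:04d}" for i in range(1, n_genes - module_size + 1)
    ]
    profiles = np.empty((n_genes, n_species), dtype=np.int8)
    for i in range(module_size):
        profiles[i] = base
    for i in range(module_size, n_genes):
        profiles[i] = rng.integers(0, 2, size=n_species)
    flips = rng.random((n_genes, n_species)) < flip_prob
    profiles = np.where(flips, 1 - profiles, profiles).astype(np.int8)
    matrix = pd.DataFrame(
        profiles, index=pd.Index(genes, name="gene"),
        columns=[f"sp{j + 1:02d}" for j in range(n_species)],
    )
    truth = {"query": "QUERY", "module": set(genes[:module_size])}
    return matrix, truth
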
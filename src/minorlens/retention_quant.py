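"""Intron-retention evidence counting and Ψ estimation from alignments.

For each intron and sample three read counts are collected:

* ``J`` — junction reads spliced exactly at the intron boundaries
  (a skipped-region gap matching the intron, with at least ``k``
  aligned nucleotides on each side);
* ``B`` — boundary reads crossing an exon–intron boundary with at
  least ``k`` aligned nucleotides on both sides (at most two per read
  per intron, one per boundary);
* ``R`` — intron-body reads with at least ``k`` aligned nucleotides
  strictly inside the intron and not already counted as junction reads.

Ψ (the retained fraction) is estimated in boundary mode as
``(B/2) / (B/2 + J)``: a retained transcript presents two boundaries,
a spliced transcript one junction. Body mode normalizes ``R`` by the
number of read placements fully inside the intron and is provided for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation_io import Intron

#: Minimum aligned nucleotides required on each side of a junction or
#: boundary, and inside the intron for body evidence.
DEFAULT_ANCHOR = 8

#: Read-count filters from the differential analyses: introns enter the
#: retention comparison with at least 5 junction reads in total, or at
#: least 5 intron-body reads on average across samples.
DEFAULT_MIN_JUNCTION = 5
DEFAULT_MIN_AVG_BODY = 5.0


@dataclass
class AlignmentRecord:
    """A gapped alignment reduced to its reference-aligned blocks.

    ``blocks`` are 0-based half-open intervals; consecutive blocks are
    separated by skipped-region (intron) gaps. Deletions extend the
    enclosing block; insertions and clips consume no reference.
    """

    contig: str
    pos: int
    blocks: list[tuple[int, int]]
    sample_id: str = ""


def _blocks_from_cigar(pos: int, cigartuples) -> list[tuple[int, int]]:
    blocks: list[tuple[int, int]] = []
    cur_start = pos
    cur_end = pos
    for op, length in cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D extend the current block
            cur_end += length
        elif op == 3:  # N closes the block
            if cur_end > cur_start:
                blocks.append((cur_start, cur_end))
            cur_start = cur_end + length
            cur_end = cur_start
        elif op in (1, 4, 5, 6):  # I, S, H, P: no reference advance
            continue
        else:
            raise ValueError(f"unsupported CIGAR operation code {op}")
    if cur_end > cur_start:
        blocks.append((cur_start, cur_end))
    return blocks


def read_alignments(path: str, sample_id: str | None = None) -> Iterator[AlignmentRecord]:
    """Stream mapped, primary alignment records from a SAM file."""
    if sample_id is None:
        sample_id = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    with pysam.AlignmentFile(path, "r") as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigartuples is None:
                continue
            try:
                blocks = _blocks_from_cigar(rec.reference_start, rec.cigartuples)
            except ValueError as exc:
                raise ValueError(f"record {rec.query_name}: {exc}") from exc
            yield AlignmentRecord(
                contig=rec.reference_name,
                pos=rec.reference_start,
                blocks=blocks,
                sample_id=sample_id,
            )


def count_intron_evidence(
    alignments: Iterable[AlignmentRecord],
    introns: list[Intron],
    anchor: int = DEFAULT_ANCHOR,
) -> pd.DataFrame:
    """Tally J/B/R evidence per intron per sample.

    Returns a tidy frame with columns ``intron_key, sample, J, B, R``
    (every catalog intron appears for every sample seen, zero-filled).
    Records on contigs absent from the catalog are ignored (tallied).
    """
    if anchor < 1:
        raise ValueError("anchor must be >= 1")
    junction_index: dict[tuple[str, int, int], int] = {}
    trees: dict[str, IntervalTree] = {}
    for idx, it in enumerate(introns):
        junction_index[(it.contig, it.start, it.end)] = idx
        trees.setdefault(it.contig, IntervalTree())[it.start:it.end] = idx

    counts: dict[tuple[int, str], list[int]] = {}
    samples: set[str] = set()
    unknown_contigs = 0

    def bucket(idx: int, sample: str) -> list[int]:
        key = (idx, sample)
        if key not in counts:
            counts[key] = [0, 0, 0]
        return counts[key]

    for rec in alignments:
        samples.add(rec.sample_id)
        tree = trees.get(rec.contig)
        if tree is None:
            unknown_contigs += 1
            continue
        junction_hits: set[int] = set()
        for (s1, e1), (s2, e2) in zip(rec.blocks, rec.blocks[1:]):
            idx = junction_index.get((rec.contig, e1, s2))
            if idx is not None and (e1 - s1) >= anchor and (e2 - s2) >= anchor:
                if idx not in junction_hits:
                    bucket(idx, rec.sample_id)[0] += 1
                    junction_hits.add(idx)
        span_lo = rec.blocks[0][0]
        span_hi = rec.blocks[-1][1]
        for iv in tree.overlap(span_lo, span_hi):
            idx = iv.data
            istart, iend = iv.begin, iv.end
            boundaries = 0
            body = False
            for bs, be in rec.blocks:
                if bs <= istart - anchor and be >= istart + anchor:
                    boundaries += 1
                if bs <= iend - anchor and be >= iend + anchor:
                    boundaries += 1
                inside = min(be, iend) - max(bs, istart)
                if inside >= anchor:
                    body = True
            if boundaries:
                bucket(idx, rec.sample_id)[1] += min(boundaries, 2)
            if body and idx not in junction_hits:
                bucket(idx, rec.sample_id)[2] += 1

    rows = []
    for idx, it in enumerate(introns):
        for sample in sorted(samples):
            j, b, r = counts.get((idx, sample), (0, 0, 0))
            rows.append(
                {"intron_key": it.key, "sample": sample, "J": j, "B": b, "R": r}
            )
    df = pd.DataFrame(rows, columns=["intron_key", "sample", "J", "B", "R"])
    df.attrs["unknown_contig_records"] = unknown_contigs
    return df


def compute_psi(
    counts: pd.DataFrame,
    design: dict[str, str],
    mode: str = "boundary",
    intron_lengths: dict[str, int] | None = None,
    read_length: int = 100,
) -> pd.DataFrame:
    """Pool counts per condition and estimate Ψ per intron.

    Boundary mode: retained_units = B/2, spliced_units = J. Body mode:
    retained_units = R scaled by read placements fully inside the
    intron (requires ``intron_lengths``), spliced_units = J. Ψ is
    retained / (retained + spliced); NaN when the denominator is zero.
    """
    if mode not in ("boundary", "body"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "body" and intron_lengths is None:
        raise ValueError("body mode requires intron_lengths")
    df = counts.copy()
    df["condition"] = df["sample"].map(design)
    if df["condition"].isna().any():
        missing = sorted(df.loc[df["condition"].isna(), "sample"].unique())
        raise ValueError(f"samples missing from design: {missing}")
    pooled = df.groupby(["intron_key", "condition"], sort=True)[["J", "B", "R"]].sum()
    rows = []
    for (key, cond), row in pooled.iterrows():
        if mode == "boundary":
            retained = row["B"] / 2.0
        else:
            length = intron_lengths[key]
            placements = max(length - read_length + 1, 1)
            retained = row["R"] * read_length / placements
        spliced = float(row["J"])
        denom = retained + spliced
        psi = retained / denom if denom > 0 else np.nan
        rows.append(
            {
                "intron_key": key,
                "condition": cond,
                "retained_units": retained,
                "spliced_units": spliced,
                "psi": psi,
            }
        )
    return pd.DataFrame(
        rows, columns=["intron_key", "condition", "retained_units", "spliced_units", "psi"]
    )


def filter_introns(
    counts: pd.DataFrame,
    min_junction: int | None = None,
    min_avg_body: float | None = None,
) -> pd.DataFrame:
    """Apply the read-count filters; which filter applies is caller-chosen.

    Junction filter: total J across the comparison's samples >=
    ``min_junction``. Body filter: mean R across samples >=
    ``min_avg_body``. Equality survives ("at least").
    """
    if counts.empty:
        return counts.copy()
    keep = pd.Series(True, index=counts["intron_key"].unique())
    grouped = counts.groupby("intron_key")
    if min_junction is not None:
        keep &= grouped["J"].sum() >= min_junction
    if min_avg_body is not None:
        keep &= grouped["R"].mean() >= min_avg_body
    surviving = set(keep[keep].index)
    return counts[counts["intron_key"].isin(surviving)].reset_index(drop=True)
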
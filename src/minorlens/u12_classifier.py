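"""Position-weight-matrix scoring and minor/major intron classification.

An intron is called minor (U12-type) when both its 5' splice-site score
and its best branch-point score reach the published thresholds (0.07
and 0.14 respectively), or when it is on a user-supplied allowlist.
Minor introns are subtyped by donor dinucleotide: AT donors are A-type
(AT-AN terminal dinucleotides), GT and GC donors are G-type.

The score of a k-mer against a PWM is a normalized likelihood,

    score(s) = prod_i p_i(s_i) / prod_i max_b p_i(b),

which lies in (0, 1] and equals 1 exactly for per-position-argmax
(consensus) sequences. ``N`` contributes the 0.25 background in the
numerator. The branch point is located by scanning all motif windows
fully contained in transcribed positions -40..-3 upstream of the 3'
splice site and keeping the best; ties go to the window nearest the
3' splice site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import Intron
from .motifs import BRANCH_POINT_U12_TRAINING, FIVE_PRIME_U12_TRAINING

#: Published classification thresholds on the (0,1] score scale.
THETA_FIVE_PRIME = 0.07
THETA_BRANCH_POINT = 0.14

#: Branch-point search spans transcribed positions -40..-3 (position -1
#: being the last intronic base).
BPS_WINDOW_START = -40
BPS_WINDOW_END = -3

DEFAULT_PSEUDOCOUNT = 0.25

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class SpliceSitePWM:
    """Per-position base probabilities for a splice-site motif."""

    label: str
    probs: np.ndarray  # shape (motif_length, 4), rows sum to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must have shape (motif_length, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must sum to 1")
        # zero entries are only reachable with pseudocount 0
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")

    @property
    def motif_length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))


def build_pwm(
    aligned_sequences: list[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    label: str = "motif",
) -> SpliceSitePWM:
    """Build a pseudocount-smoothed PWM from equal-length training k-mers.

    ``probs[pos][base] = (count + pseudocount) / (n + 4 * pseudocount)``;
    an ``N`` in the training data contributes 0.25 of a count to each
    base at its position.
    """
    if not aligned_sequences:
        raise ValueError("empty training set")
    length = len(aligned_sequences[0])
    if any(len(s) != length for s in aligned_sequences):
        raise ValueError("training sequences have ragged lengths")
    counts = np.zeros((length, 4), dtype=float)
    for seq in aligned_sequences:
        for pos, base in enumerate(seq.upper()):
            if base == "N":
                counts[pos] += 0.25
            elif base in _BASE_INDEX:
                counts[pos, _BASE_INDEX[base]] += 1.0
            else:
                raise ValueError(f"invalid base {base!r} in training sequence")
    n = len(aligned_sequences)
    probs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    return SpliceSitePWM(label=label, probs=probs)


def score_sequence(pwm: SpliceSitePWM, seq: str) -> float:
    """Normalized likelihood score in (0, 1]; 1 on consensus sequences."""
    seq = seq.upper()
    if len(seq) != pwm.motif_length:
        raise ValueError(
            f"sequence length {len(seq)} != motif length {pwm.motif_length}"
        )
    num = 1.0
    denom = 1.0
    maxima = pwm.probs.max(axis=1)
    for pos, base in enumerate(seq):
        if base == "N":
            num *= 0.25
        elif base in _BASE_INDEX:
            num *= pwm.probs[pos, _BASE_INDEX[base]]
        else:
            raise ValueError(f"invalid base {base!r}")
        denom *= maxima[pos]
    return num / denom


def scan_branch_point(
    pwm: SpliceSitePWM, region_seq: str
) -> tuple[float, int | None]:
    """Locate the best branch-point window in a 3'-terminal intron region.

    ``region_seq`` holds the last (up to 40) transcribed intronic
    nucleotides, its final base being position -1. Every motif window
    fully contained in positions [-40, -3] is scored; returns
    ``(best_score, offset)`` where ``offset`` is the window start as a
    negative offset from the 3' splice site. Ties are broken toward the
    3' splice site. Returns ``(0.0, None)`` when the region is too short
    for any window.
    """
    region = region_seq.upper()
    r = len(region)
    L = pwm.motif_length
    # window at index i occupies offsets [i - r, i - r + L - 1]; the
    # window must end at or before offset -3
    last_start = r - L - 2
    if last_start < 0:
        return 0.0, None
    best = 0.0
    best_i: int | None = None
    for i in range(last_start + 1):
        s = score_sequence(pwm, region[i : i + L])
        if s >= best:  # >= keeps the later (3'-most) window on ties
            best = s
            best_i = i
    if best_i is None:
        return 0.0, None
    return best, best_i - r


@dataclass
class IntronClassification:
    """Scored classification of one intron."""

    intron_key: str
    terminal_label: str
    s5: float
    s_bps: float
    bps_offset: int | None
    spliceosome_type: str  # "minor" | "major"
    subtype: str  # "A" | "G" | "not_applicable"
    source: str  # "scored" | "allowlist"


def _subtype_from_donor(donor: str) -> str:
    if donor == "AT":
        return "A"
    if donor in ("GT", "GC"):
        return "G"
    return "not_applicable"


def classify_intron(
    intron: Intron,
    pwm5: SpliceSitePWM,
    pwm_bps: SpliceSitePWM,
    theta5: float = THETA_FIVE_PRIME,
    theta_bps: float = THETA_BRANCH_POINT,
    allowlist: frozenset | set = frozenset(),
) -> IntronClassification:
    """Classify one intron as minor/major and subtype minor introns.

    ``allowlist`` holds (contig, start, end, strand) keys of introns to
    be called minor regardless of score (curated additions whose branch
    point scores poorly).
    """
    donor_seq = intron.donor_region_seq[: pwm5.motif_length]
    s5 = score_sequence(pwm5, donor_seq) if len(donor_seq) == pwm5.motif_length else 0.0
    s_bps, offset = scan_branch_point(pwm_bps, intron.three_prime_region_seq)
    allowlisted = (intron.contig, intron.start, intron.end, intron.strand) in allowlist
    minor = (s5 >= theta5 and s_bps >= theta_bps) or allowlisted
    subtype = _subtype_from_donor(intron.donor_dinucleotide) if minor else "not_applicable"
    return IntronClassification(
        intron_key=intron.key,
        terminal_label=intron.terminal_label,
        s5=s5,
        s_bps=s_bps,
        bps_offset=offset,
        spliceosome_type="minor" if minor else "major",
        subtype=subtype,
        source="allowlist" if allowlisted and not (s5 >= theta5 and s_bps >= theta_bps) else "scored",
    )


def classify_catalog(
    introns: list[Intron],
    pwm5: SpliceSitePWM | None = None,
    pwm_bps: SpliceSitePWM | None = None,
    theta5: float = THETA_FIVE_PRIME,
    theta_bps: float = THETA_BRANCH_POINT,
    allowlist: frozenset | set = frozenset(),
) -> pd.DataFrame:
    """Classify every intron of a catalog; returns a tidy table."""
    if pwm5 is None:
        pwm5 = default_five_prime_pwm()
    if pwm_bps is None:
        pwm_bps = default_branch_point_pwm()
    catalog_keys = {(i.contig, i.start, i.end, i.strand) for i in introns}
    for key in allowlist:
        if key not in catalog_keys:
            warnings.warn(f"allowlisted intron {key} absent from catalog; skipped")
    rows = []
    for intron in introns:
        c = classify_intron(intron, pwm5, pwm_bps, theta5, theta_bps, allowlist)
        rows.append(
            {
                "intron_key": c.intron_key,
                "terminal_label": c.terminal_label,
                "s5": c.s5,
                "s_bps": c.s_bps,
                "bps_offset": c.bps_offset if c.bps_offset is not None else "",
                "spliceosome_type": c.spliceosome_type,
                "subtype": c.subtype,
                "source": c.source,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "intron_key", "terminal_label", "s5", "s_bps", "bps_offset",
            "spliceosome_type", "subtype", "source",
        ],
    )


def default_five_prime_pwm(pseudocount: float = DEFAULT_PSEUDOCOUNT) -> SpliceSitePWM:
    """PWM built from the bundled U12 5'ss training alignment."""
    return build_pwm(FIVE_PRIME_U12_TRAINING, pseudocount, label="five_prime_ss")


def default_branch_point_pwm(pseudocount: float = DEFAULT_PSEUDOCOUNT) -> SpliceSitePWM:
    """PWM built from the bundled U12 branch-point training alignment."""
    return build_pwm(BRANCH_POINT_U12_TRAINING, pseudocount, label="branch_point")


def read_allowlist(path: str) -> frozenset:
    """Read an allowlist TSV of contig, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return frozenset(
        (str(r.iloc[0]), int(r.iloc[1]), int(r.iloc[2]), str(r.iloc[3]))
        for _, r in df.iterrows()
    )
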
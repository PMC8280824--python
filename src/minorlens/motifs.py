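"""Bundled training alignments for the U12-type splice-site matrices.

These are small synthetic curated alignments written from the canonical
U12-dependent consensus motifs: the extended 5' splice site
([AG]TATCCTTT, read from the first intronic base) and the branch-point
sequence (TTCCTTAAC, branch adenosine at position 7). They are variant
sets, not matrices copied from any published tool; every member scores
above the classification thresholds under the package's normalized
likelihood score, so planting any member in a simulated intron yields a
minor call. Users may substitute their own alignments (FASTA).
"""

#: Extended U12 5' splice-site training set, 9 nt from the first
#: intronic base. Includes AT-, GT- and GC-donor variants.
FIVE_PRIME_U12_TRAINING = [
    "ATATCCTTT",
    "ATATCCTTT",
    "ATATCCTTT",
    "GTATCCTTT",
    "GTATCCTTT",
    "GTATCCTTT",
    "ATATCCTTC",
    "GTATCCTTC",
    "GCATCCTTT",
]

#: U12 branch-point training set, 9 nt windows; consensus TTCCTTAAC.
BRANCH_POINT_U12_TRAINING = [
    "TTCCTTAAC",
    "TTCCTTAAC",
    "TTCCTTAAC",
    "TTCCTTAAC",
    "CTCCTTAAC",
    "TTCCTTGAC",
    "TTCCTTAAT",
    "TCCCTTAAC",
]

#: Major (U2-type) 5' splice-site consensus used by the simulator for
#: GT-donor major introns (and, with an AT donor substituted, for the
#: major AT-AC class). Scores far below the U12 thresholds.
MAJOR_FIVE_PRIME_CONSENSUS = "GTAAGTAAG"
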
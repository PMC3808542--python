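"""Physical constants and fixed experimental-design values shared across modules."""

AVOGADRO = 6.02214076e23
"""Avogadro constant, mol^-1 (2019 SI exact value)."""

NT_MW = 339.5
"""Mean molecular weight of an RNA monophosphate nucleotide, g/mol
(average over AMP, CMP, GMP, UMP)."""

TIME_GRID_HR = (0.0, 1.5, 3.0, 6.0, 9.0, 12.0)
"""Default apoptosis time course, hours after proteasome-inhibitor exposure."""

TIME_LABELS = ("t0", "t1p5", "t3", "t6", "t9", "t12")
"""Column labels for the six time points, in order."""

ITRAQ_CHANNEL_MAP = {"113": 0.0, "115": 1.5, "116": 3.0, "117": 6.0, "118": 9.0, "119": 12.0}
"""iTRAQ reporter-channel -> time (hr) assignment used throughout."""

FOOTPRINT_LEN_RANGE = (26, 36)
"""Accepted ribosome-footprint read lengths, nt (inclusive)."""

MRNA_FRAG_LEN_RANGE = (50, 90)
"""mRNA-seq fragment lengths, nt (inclusive)."""

ARCHETYPES = ("Upreg", "Downreg", "Stable", "TE_Up", "TE_Down")
"""The five transcript-trajectory classes used for clustering and simulation."""

CLEAVAGE_CLUSTERS = ("Fastest", "Faster", "Mid", "Slow", "Slowest/No Change")
"""Kinetic classes of proteolytic cleavage, ordered fastest to slowest."""
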
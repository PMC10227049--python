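"""Versioned categorical code tables for graph features.

Atom and bond properties are stored as small integer codes.  The model
one-hot encodes them against the vocabulary sizes below, so these tables
are part of the serialized-model contract: changing them invalidates
saved weights (the archive records ``CODE_TABLE_VERSION``).
"""

CODE_TABLE_VERSION = 1

# Atomic numbers seen in normal-phase chiral HPLC datasets; anything else
# maps to the trailing "other" bucket.
ATOMIC_NUMS = (1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 35, 53)
ATOMIC_NUM_OTHER = len(ATOMIC_NUMS)

# Vocabulary sizes for the 9 atom-feature columns, in order:
# atomic number, chiral tag, degree, explicit valence, formal charge
# (offset by +2), hybridization, implicit valence, aromaticity, total Hs.
ATOM_FEATURE_SIZES = (
    len(ATOMIC_NUMS) + 1,  # atomic number code
    4,   # chiral tag (unspecified / CW / CCW / other)
    7,   # degree 0..6
    8,   # explicit valence 0..7
    5,   # formal charge -2..+2
    8,   # hybridization
    7,   # implicit valence 0..6
    2,   # aromatic flag
    5,   # number of connected hydrogens 0..4
)

# Bond-feature columns: direction, type, ring flag.
BOND_DIR_SIZE = 7      # rdkit BondDir enum range
BOND_TYPE_CODES = {1.0: 0, 2.0: 1, 3.0: 2, 1.5: 3}  # single/double/triple/aromatic
BOND_TYPE_OTHER = 4
BOND_TYPE_SIZE = 5
BOND_RING_SIZE = 2

FORMAL_CHARGE_OFFSET = 2

# Dead-time lower bound for RTv (min·mL/min), from dataset analysis.
DEADTIME_RTV = 2.0

# Records with RTv above this are outliers and dropped by the standard filter.
RTV_MAX = 60.0
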
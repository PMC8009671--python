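"""Physical constants and sentinels shared across modules."""

import math

#: Mass difference between deuterium and protium, Da.
DEUTERIUM_MASS_SHIFT = 1.00628

#: Proton mass used for m/z <-> neutral-mass conversion, Da.
PROTON_MASS = 1.007276

#: Exposure sentinel marking the long-incubation out-exchange control.
#: Stored as +inf internally; serialized as "inf" in CSV, which round-trips.
OUT_EXCHANGE_EXPOSURE = math.inf

#: The 20 canonical amino acids (one-letter codes).
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
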
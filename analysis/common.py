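"""Shared study conditions for the analysis scripts.

Every script regenerates the synthetic benchmark deterministically from
these constants rather than passing large work tables between steps.
"""

from pathlib import Path

SEED = 11
N_RES = 144          # benchmark size (57:48:39 ASP/GLU/LYS composition)
SIGMA = 5.0          # work-distribution width, kJ/mol
N_TRANSITIONS = 200  # transitions per direction per leg

RESULTS = Path(__file__).resolve().parent.parent / "results"
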
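"""Bundled example data.

A small physicochemical phase table from a triplicate batch anaerobic
digestion experiment: three digesters (D1-D3) sampled at three operational
phases (P1 start-up/inhibition, P2 peak methane production, P3 plateau).
Columns: volatile fatty acids (propionate, acetate, butyrate; mg/L), pH,
ammoniacal nitrogen (N-NH3; mg/L), chemical oxygen demand (COD; mg/L) and
biochemical methane potential (BMP).
"""

from __future__ import annotations

import pandas as pd

from .data_io import PhaseTable

__all__ = ["digester_phase_table"]

_PARAMETERS = ["propionate", "acetate", "butyrate", "pH", "N-NH3", "COD", "BMP"]

# rows: (digester, phase) -> parameter values in _PARAMETERS order
_VALUES = {
    ("D1", "P1"): [826.60, 105.99, 0.00, 6.82, 483.80, 27595.16, 0.0],
    ("D1", "P2"): [739.78, 1115.62, 33.57, 7.77, 789.40, 12392.50, 142.69],
    ("D1", "P3"): [18.49, 65.78, 0.00, 8.05, 1107.25, 3959.78, 216.63],
    ("D2", "P1"): [922.86, 233.48, 84.35, 6.86, 479.75, 25457.29, 0.0],
    ("D2", "P2"): [494.45, 685.91, 31.25, 7.79, 844.90, 11204.79, 139.95],
    ("D2", "P3"): [16.00, 312.87, 0.00, 8.01, 1302.35, 4316.09, 191.52],
    ("D3", "P1"): [860.45, 349.16, 93.02, 6.84, 501.20, 26526.22, 0.0],
    ("D3", "P2"): [32.44, 185.83, 0.00, 7.74, 1217.00, 3484.69, 135.74],
    ("D3", "P3"): [17.33, 311.68, 12.84, 7.94, 1146.05, 5503.80, 155.49],
}


def digester_phase_table() -> PhaseTable:
    """Phase table for the bundled three-digester batch experiment."""
    idx = pd.MultiIndex.from_tuples(sorted(_VALUES), names=["digester", "phase"])
    df = pd.DataFrame([_VALUES[k] for k in sorted(_VALUES)], index=idx, columns=_PARAMETERS)
    return PhaseTable(data=df)
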
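"""Half-up decimal rounding for report layouts.

Python's builtin ``round`` is banker's rounding; published decision tables
round halves away from zero, so 4.9815 must print as 4.982.  Internal
computation never rounds — these helpers are for the reporting layer only.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def round_half_up(x: float, decimals: int = 3) -> float:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_series_half_up(s: pd.Series, decimals: int = 3) -> pd.Series:
    return s.map(lambda v: round_half_up(v, decimals))
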
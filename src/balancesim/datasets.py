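"""Packaged reference tables for the 30-condition protocol.

Benchmark values from the published perturbed-balance study this model
family reproduces: the dominant balance strategy per condition and the CCI
cycle integrals per muscle pair.  Used as fixtures for the analysis
operations (dominance arithmetic, delay-trend comparisons); the simulator
does not read them.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    text = resources.files("balancesim.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text))


def reference_dominant_strategy() -> pd.DataFrame:
    """Dominant strategy per (delay, magnitude); ties as 'A/B'."""
    df = _read("reference_dominant_strategy.csv").set_index("delay_ms")
    df.columns = [float(c) for c in df.columns]
    return df


def reference_cci_integrals() -> pd.DataFrame:
    """CCI cycle integrals, index (delay_ms, pair), columns magnitude mm."""
    df = _read("reference_cci_integrals.csv").set_index(["delay_ms", "pair"])
    df.columns = [float(c) for c in df.columns]
    return df
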
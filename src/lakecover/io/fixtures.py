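"""Packaged reference data.

``monthly_area_series.csv`` is the published monthly area accounting for
a large seasonal lake (2013-2021): 41 dated records of water, vegetation
and mudflat&sand areas in km² at 4-decimal precision.  Row totals are
constant at ~3294.36 km² (the fixed analysis boundary).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..timeseries import AreaSeries

_FIXTURE = "monthly_area_series.csv"


def load_monthly_areas() -> AreaSeries:
    """The bundled 41-record monthly area series (2013-05-14 ... 2021-11-12)."""
    ref = resources.files("lakecover.data").joinpath(_FIXTURE)
    with ref.open("r") as fh:
        df = pd.read_csv(fh)
    return AreaSeries.from_frame(df, source="packaged monthly area table")
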
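"""Bundled reference tables.

``regional_summary.csv`` holds published pan-tropical regional summary
statistics (multi-year warming means in °C, populations in persons,
annual attributable deaths) from a published satellite-based
deforestation–warming–mortality assessment.  They serve as fixed inputs
for report arithmetic (shares, rates, percentages) — nothing in this
package derives them.

``hvi_default.csv`` is the editable default heat-vulnerability table
(continental values; tropical Africa falls back to the South American
value, the lowest continental average).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from deforheat.heat_mortality import HVITable

__all__ = ["load_regional_summary", "load_default_hvi"]


def _data_path(name: str):
    return resources.files("deforheat.data").joinpath(name)


def load_regional_summary() -> pd.DataFrame:
    """Published regional warming/exposure/mortality summary, indexed by scope."""
    with resources.as_file(_data_path("regional_summary.csv")) as p:
        return pd.read_csv(p).set_index("scope")


def load_default_hvi() -> HVITable:
    """Default continental heat-vulnerability indices (%-pt per °C)."""
    with resources.as_file(_data_path("hvi_default.csv")) as p:
        return HVITable.from_csv(p)
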
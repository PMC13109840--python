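"""Destrieux cortical parcellation region-to-lobe lookup.

The Destrieux scheme divides each hemisphere into 74 sulco-gyral regions. The
bundled table assigns each region name to one of five lobes (frontal,
parietal, temporal, occipital, insular); peri-rolandic and limbic structures
that straddle classical lobe boundaries are placed so the per-lobe totals are
28 frontal, 11 parietal, 14 temporal, 13 occipital and 8 insular regions.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = ["load_destrieux_lobe_table", "LOBES"]

LOBES = ("frontal", "parietal", "temporal", "occipital", "insular")


@lru_cache(maxsize=1)
def _table() -> pd.DataFrame:
    with resources.files("zmapsoz.data").joinpath("destrieux_lobes.csv").open() as fh:
        df = pd.read_csv(fh)
    bad = set(df["lobe"]) - set(LOBES) - {"unclassified"}
    if bad:
        raise ValueError(f"bundled lobe table carries unknown lobes: {bad}")
    return df


def load_destrieux_lobe_table() -> dict[str, str]:
    """Return the region-name -> lobe mapping (74 regions per hemisphere).

    The same mapping applies to both hemispheres; callers that need
    hemisphere-qualified keys pair it with a hemisphere tag.
    """
    df = _table()
    return dict(zip(df["region"], df["lobe"]))
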
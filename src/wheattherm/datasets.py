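"""Packaged study tables: published per-stage WSI, per-variety WCI, and
yield components for the nine durum and nine common wheat varieties.

These ship as small CSVs inside the package because the raw infrared
image sequences behind them were never deposited; the tables are the
study's printed summaries at 2-decimal precision and serve both as the
reproduction inputs (index-vs-yield correlations) and as realistic
targets for the synthetic field generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .frames import STAGES, YieldTable
from .indices import IndexTable


def _data_path(name: str):
    return resources.files("wheattherm.data").joinpath(name)


def _read_csv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path)


def load_wsi_table(species: str) -> IndexTable:
    """Published variety x stage WSI matrix for one species as an IndexTable."""
    df = _read_csv("wsi_stages.csv")
    df = df[df["species"] == species]
    if df.empty:
        raise ValueError(f"unknown species {species!r}")
    matrix = df.set_index("variety")[list(STAGES)]
    wci = load_wci_frame(species)
    wci_df = pd.DataFrame({"wci_m": wci["wci_m"], "se": wci["wci_sd"], "n": 0})
    printed = df.set_index("variety")["wsi_m"]
    return IndexTable(species=species, stage_matrix=matrix,
                      wci=wci_df.reindex(matrix.index),
                      printed_wsi_m=printed)


def load_wci_frame(species: str) -> pd.DataFrame:
    """Published per-variety mean WCI with its printed dispersion."""
    df = _read_csv("wci.csv")
    df = df[df["species"] == species].set_index("variety")
    if df.empty:
        raise ValueError(f"unknown species {species!r}")
    return df[["wci_m", "wci_sd"]]


def load_yield_table(species: str) -> YieldTable:
    """Published yield components (t/ha, counts per m2) for one species."""
    if species not in ("durum", "common"):
        raise ValueError(f"unknown species {species!r}")
    return YieldTable(species=species, data=_read_csv(f"yield_{species}.csv"))


def paper_fixture_tables() -> tuple[dict[str, IndexTable], dict[str, YieldTable]]:
    """All packaged study tables, keyed by species."""
    species = ("durum", "common")
    return ({s: load_wsi_table(s) for s in species},
            {s: load_yield_table(s) for s in species})
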
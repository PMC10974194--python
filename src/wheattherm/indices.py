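"""Wheat stress and cover indices, per frame and aggregated.

WSI = (T_S - T_W) / T_S is the soil-normalized canopy temperature
depression: T_S and T_W are the mean soil and wheat temperatures of one
frame, both in degC.  In the observed regime T_S > T_W > 0 the index
lies in (0, 1); *lower* values flag *higher* crop stress.  Because of
the bare T_S in the denominator the index is tied to the Celsius scale
and is undefined near or below 0 degC.

WCI = P_W / (P_W + P_S) is the fraction of classified pixels that are
wheat — a thermal proxy for fractional ground cover.  It is only
meaningful at stem elongation, before the canopy closes over the soil,
and the aggregation enforces that restriction.

Aggregation follows the study layout: per-frame WSI values are averaged
into a variety x stage matrix; row means give the per-variety WSI_m,
column means the per-stage PP-WSI_m.  WSI is computed per frame from
that frame's class means and then averaged (rather than pooling all
temperatures first) so that a dispersion is estimable; rounding to the
2 printed decimals happens only at report time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import IndexDomainError, OutOfRegimeWarning, ValidationError
from .frames import STAGES, VARIETIES

logger = logging.getLogger(__name__)

WCI_STAGE = "stem_elongation"


def compute_wsi(t_s: float, t_w: float) -> float:
    """Wheat stress index (T_S - T_W)/T_S from class mean temperatures in degC.

    Raises IndexDomainError when t_s <= 0 (the normalization loses
    meaning near the Celsius origin).  Inputs outside the observed
    regime 0 < T_W < T_S return the arithmetic value but emit an
    OutOfRegimeWarning.
    """
    if not np.isfinite(t_s) or not np.isfinite(t_w):
        raise IndexDomainError("WSI requires finite class mean temperatures")
    if t_s <= 0:
        raise IndexDomainError(f"WSI undefined for soil temperature {t_s} degC <= 0")
    if not 0 < t_w < t_s:
        warnings.warn(
            f"WSI inputs outside the regime 0 < T_W < T_S (T_W={t_w}, T_S={t_s})",
            OutOfRegimeWarning, stacklevel=2)
    return (t_s - t_w) / t_s


def compute_wci(p_w: int, p_s: int) -> float:
    """Wheat cover index P_W/(P_W + P_S) from class pixel counts."""
    if p_w < 0 or p_s < 0:
        raise IndexDomainError("pixel counts must be non-negative")
    if p_w + p_s == 0:
        raise IndexDomainError("WCI undefined with zero classified pixels")
    return p_w / (p_w + p_s)


@dataclass
class IndexRecord:
    """Per-frame index values; wci is populated only at stem elongation."""

    species: str
    variety: str
    stage: str
    session: str
    wsi: float
    wci: float | None
    t_w_mean: float
    t_s_mean: float

    def as_dict(self) -> dict:
        return {"species": self.species, "variety": self.variety, "stage": self.stage,
                "session": self.session, "wsi": self.wsi, "wci": self.wci,
                "t_w_mean": self.t_w_mean, "t_s_mean": self.t_s_mean}


def record_from_segmentation(seg, meta) -> IndexRecord:
    """Turn one frame's segmentation into an index record.

    Frames where one class is empty have no defined WSI and are
    rejected; WCI is attached only for stem-elongation frames.
    """
    if seg.p_w == 0 or seg.p_s == 0:
        raise IndexDomainError(
            f"frame of {meta.variety} at {meta.stage} segmented into a single "
            f"class (p_w={seg.p_w}, p_s={seg.p_s}); WSI undefined")
    wci = compute_wci(seg.p_w, seg.p_s) if meta.stage == WCI_STAGE else None
    return IndexRecord(species=meta.species, variety=meta.variety, stage=meta.stage,
                       session=meta.session, wsi=compute_wsi(seg.t_s_mean, seg.t_w_mean),
                       wci=wci, t_w_mean=seg.t_w_mean, t_s_mean=seg.t_s_mean)


def _round_half_up(x: float, decimals: int = 2) -> float:
    if isinstance(x, float) and np.isnan(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class IndexTable:
    """Aggregated index summary for one species (study-table layout).

    stage_matrix: variety x stage mean WSI (full precision; NaN = empty
    cell).  wsi_m / pp_wsi_m: its row / column means.  wci: per-variety
    mean WCI over stem-elongation frames with its standard error and
    frame count (se/n are NaN/0 for fixture-derived tables).
    """

    species: str
    stage_matrix: pd.DataFrame
    wci: pd.DataFrame  # columns: wci_m, se, n
    printed_wsi_m: pd.Series | None = None  # fixture tables carry the published column

    def __post_init__(self) -> None:
        if list(self.stage_matrix.columns) != list(STAGES):
            raise ValidationError("stage matrix columns must be the four stages")

    @property
    def wsi_m(self) -> pd.Series:
        """Per-variety mean over the four stages (row means)."""
        return self.stage_matrix.mean(axis=1, skipna=False).rename("wsi_m")

    @property
    def wsi_m_report(self) -> pd.Series:
        """Per-variety WSI_m at report precision: the published column for
        fixture tables, otherwise the full-precision row means."""
        if self.printed_wsi_m is not None:
            return self.printed_wsi_m.rename("wsi_m")
        return self.wsi_m

    @property
    def pp_wsi_m(self) -> pd.Series:
        """Per-stage mean over varieties (column means, empty cells excluded)."""
        return self.stage_matrix.mean(axis=0, skipna=True).rename("pp_wsi_m")

    @property
    def wci_m(self) -> pd.Series:
        return self.wci["wci_m"]

    def rendered(self, decimals: int = 2) -> pd.DataFrame:
        """Report-format table: stage WSI + WSI_m, rounded half-up."""
        out = self.stage_matrix.copy()
        out["wsi_m"] = self.wsi_m
        out = out.map(lambda v: _round_half_up(v, decimals))
        out.loc["pp_wsi_m"] = [_round_half_up(v, decimals) for v in self.pp_wsi_m] + [np.nan]
        return out

    def rendered_wci(self, decimals: int = 2) -> pd.DataFrame:
        out = self.wci.copy()
        out["wci_m"] = out["wci_m"].map(lambda v: _round_half_up(v, decimals))
        return out


def aggregate_indices(records: list[IndexRecord] | pd.DataFrame,
                      species: str | None = None) -> IndexTable:
    """Aggregate frame-level records into the variety x stage study table.

    Each cell is the unweighted mean of all frame-level WSI values for
    that variety and stage, pooled over sessions and replicates.  An
    empty cell stays NaN, is excluded from column means, and is logged.
    WCI statistics use stem-elongation frames only.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.as_dict() for r in records])
    if df.empty:
        raise ValidationError("no index records to aggregate")
    if species is None:
        uniq = df["species"].unique()
        if len(uniq) != 1:
            raise ValidationError(
                f"records span several species {sorted(uniq)}; pass species explicitly")
        species = str(uniq[0])
    df = df[df["species"] == species]
    varieties = [v for v in VARIETIES[species] if v in set(df["variety"])]
    bad_stage = set(df["stage"]) - set(STAGES)
    if bad_stage:
        raise ValidationError(f"unknown stage(s) in records: {sorted(bad_stage)}")

    matrix = (df.pivot_table(index="variety", columns="stage", values="wsi",
                             aggfunc="mean")
                .reindex(index=varieties, columns=list(STAGES)))
    for variety in varieties:
        for stage in STAGES:
            if np.isnan(matrix.loc[variety, stage]):
                logger.warning("no frames for %s at %s; cell left empty",
                               variety, stage)

    se_rows = {}
    cover = df[(df["stage"] == WCI_STAGE) & df["wci"].notna()]
    for variety in varieties:
        vals = cover.loc[cover["variety"] == variety, "wci"].to_numpy(dtype=float)
        n = len(vals)
        mean = vals.mean() if n else np.nan
        se = vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        se_rows[variety] = {"wci_m": mean, "se": se, "n": n}
    wci = pd.DataFrame.from_dict(se_rows, orient="index").reindex(varieties)
    wci["n"] = wci["n"].astype(int)
    return IndexTable(species=species, stage_matrix=matrix, wci=wci)
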
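"""End-to-end orchestration: simulate -> segment -> index -> correlate.

A run is driven by exactly one of three input modes:

* ``frames`` mode — an existing directory of thermal rasters plus a
  manifest CSV;
* ``simulate`` mode — a generation config, from which a synthetic study
  is produced in memory (and optionally written out);
* ``reproduce`` mode — no images at all: the packaged published summary
  tables drive the correlation stage directly.

All intermediate artifacts are plain CSV; outputs land in an output
directory together with a run log recording every parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import datasets
from .correlation import run_correlation_suite, suite_frame
from .errors import ValidationError, WheatThermError
from .frames import (ThermalFrame, YieldTable, meta_from_manifest_row,
                     read_frame, read_manifest, read_yield_table)
from .indices import IndexTable, aggregate_indices, record_from_segmentation
from .segmentation import SegmentationParams, segment_frame
from .synthetic import GenerationConfig, generate_study

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Configuration of one pipeline run; exactly one input mode is set."""

    frames_dir: Path | None = None
    manifest: Path | None = None
    generation: GenerationConfig | None = None
    reproduce: bool = False
    yield_tables: dict[str, Path] = field(default_factory=dict)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        modes = [self.frames_dir is not None or self.manifest is not None,
                 self.generation is not None,
                 self.reproduce]
        if sum(modes) != 1:
            raise ValidationError(
                "exactly one of frames+manifest, generation config, or "
                "reproduction mode must drive a run")
        if self.frames_dir is not None and self.manifest is None:
            self.manifest = Path(self.frames_dir) / "manifest.csv"


def segment_study(frames: list[ThermalFrame], manifest: pd.DataFrame,
                  params: SegmentationParams) -> pd.DataFrame:
    """Segment every frame; one result row per manifest row."""
    if len(frames) != len(manifest):
        raise ValidationError("frame list and manifest length mismatch")
    rows = []
    for frame, (_, mrow) in zip(frames, manifest.iterrows()):
        try:
            seg = segment_frame(frame, params)
        except WheatThermError as exc:
            raise WheatThermError(f"segmentation failed on {mrow['file']}: {exc}") from exc
        logger.info("%s: t_th=%.2f (%s) p_w=%d p_s=%d",
                    mrow["file"], seg.t_th, seg.method, seg.p_w, seg.p_s)
        rows.append({"file": mrow["file"], "t_th": seg.t_th, "method": seg.method,
                     "p_w": seg.p_w, "p_s": seg.p_s,
                     "t_w_mean": seg.t_w_mean, "t_s_mean": seg.t_s_mean})
    return pd.DataFrame(rows)


def index_study(seg_df: pd.DataFrame, manifest: pd.DataFrame) -> dict[str, IndexTable]:
    """Aggregate per-frame segmentations to per-species index tables."""
    merged = seg_df.merge(manifest, on="file", validate="one_to_one")
    records = []
    for _, row in merged.iterrows():
        meta = meta_from_manifest_row(row)
        seg = _SegStats(row)
        records.append(record_from_segmentation(seg, meta))
    df = pd.DataFrame([r.as_dict() for r in records])
    return {species: aggregate_indices(df, species=species)
            for species in sorted(df["species"].unique())}


class _SegStats:
    """Row adapter exposing the segmentation fields aggregate needs."""

    def __init__(self, row) -> None:
        self.p_w = int(row["p_w"])
        self.p_s = int(row["p_s"])
        self.t_w_mean = float(row["t_w_mean"])
        self.t_s_mean = float(row["t_s_mean"])


def load_frames(manifest_path: Path, frames_dir: Path | None = None
                ) -> tuple[list[ThermalFrame], pd.DataFrame]:
    manifest = read_manifest(manifest_path)
    if manifest.empty:
        raise ValidationError(f"manifest {manifest_path} lists no frames")
    base = Path(frames_dir) if frames_dir is not None else Path(manifest_path).parent
    frames = [read_frame(base / row["file"], meta=meta_from_manifest_row(row))
              for _, row in manifest.iterrows()]
    return frames, manifest


@dataclass
class RunReport:
    """Artifacts of one pipeline run."""

    index_tables: dict[str, IndexTable]
    correlations: pd.DataFrame
    segmentation: pd.DataFrame | None = None


def run_pipeline(config: StudyConfig) -> RunReport:
    """Execute the configured pipeline and (optionally) write its artifacts."""
    out = Path(config.out_dir) if config.out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if config.reproduce:
        index_tables, yield_tables = datasets.paper_fixture_tables()
        seg_df = None
    else:
        if config.generation is not None:
            study = generate_study(config.generation)
            frames, manifest = study.frames, study.manifest
        else:
            frames, manifest = load_frames(config.manifest, config.frames_dir)
        seg_df = segment_study(frames, manifest, config.segmentation)
        index_tables = index_study(seg_df, manifest)
        yield_tables = {}
        for species in index_tables:
            if species in config.yield_tables:
                yield_tables[species] = read_yield_table(
                    config.yield_tables[species], species=species)
            else:
                yield_tables[species] = datasets.load_yield_table(species)

    corr_rows = []
    for species, itable in index_tables.items():
        ytable: YieldTable = yield_tables[species]
        have_wci = itable.wci["wci_m"].notna().all()
        for exclude in (False, True):
            results = run_correlation_suite(itable, ytable, exclude_modern=exclude)
            sdf = suite_frame(results)
            sdf.insert(0, "species", species)
            sdf.insert(1, "modern_excluded", exclude)
            if not have_wci:
                sdf = sdf[sdf["x"] != "wci_m"]
            corr_rows.append(sdf)
    correlations = pd.concat(corr_rows, ignore_index=True)

    if out is not None:
        if seg_df is not None:
            seg_df.to_csv(out / "segmentation.csv", index=False)
        for species, itable in index_tables.items():
            itable.rendered().to_csv(out / f"wsi_{species}.csv")
            itable.rendered_wci().to_csv(out / f"wci_{species}.csv")
        correlations.to_csv(out / "correlations.csv", index=False)
        logger.info("pipeline outputs written to %s", out)
    return RunReport(index_tables=index_tables, correlations=correlations,
                     segmentation=seg_df)
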
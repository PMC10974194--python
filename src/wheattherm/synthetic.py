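"""Seeded synthetic thermal fields with ground truth.

The study's raw infrared sequences were never deposited, so this module
emulates what the camera saw: per-plot frames whose pixels belong to two
spatially coherent temperature classes, wheat cooler than soil.  The
wheat mask is built from vertical crop-row bands of jittered width (not
i.i.d. speckle), so temperature histograms are bimodal while masks look
like rows of plants; per-pixel Gaussian noise is then added per class.

The generator is parameterized in the quantities the downstream
pipeline must recover: the target stress index fixes the wheat mean via
wheat_mean = soil_mean * (1 - target_wsi), and the cover fraction fixes
the width of the wheat bands (met exactly at column granularity).
Sessions within a stage share an additive temperature offset drawn
Normal(0, 0.5 degC) applied to both class means, mimicking
morning/afternoon weather shifts; this preserves the target WSI to
first order (exactly in the temperature difference, approximately in
the normalization).

The module makes no attempt at canopy energy-balance physics, wind,
shadows or diurnal radiation curves; Gaussian class noise is a modelling
choice, not a measured property of the study fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .frames import (MANIFEST_COLUMNS, NATIVE_SHAPE, STAGES, FrameMeta,
                     ThermalFrame, write_frame, write_manifest)

#: Default crop-row band width range in pixels (jittered per band).
BAND_WIDTH_RANGE = (4, 12)

#: Default session-to-session temperature offset spread, degC.
SESSION_OFFSET_SD = 0.5


@dataclass
class GroundTruth:
    """Latent per-frame quantities the segmentation stage must recover."""

    mask: np.ndarray = field(repr=False)  # True = wheat
    cover_fraction: float                 # exact mask fraction
    t_w: float                            # sample mean of generated wheat pixels
    t_s: float                            # sample mean of generated soil pixels
    soil_mean: float                      # configured class means (degC)
    wheat_mean: float

    @property
    def wsi(self) -> float:
        """Stress index implied by the generated class sample means."""
        return (self.t_s - self.t_w) / self.t_s


def _row_band_mask(width: int, height: int, cover_fraction: float,
                   rng: np.random.Generator,
                   band_width_range: tuple[int, int] = BAND_WIDTH_RANGE) -> np.ndarray:
    """Column-wise crop-row mask hitting cover_fraction exactly at column
    granularity: wheat bands of jittered width separated by soil gaps."""
    n_wheat = int(round(cover_fraction * width))
    cols = np.zeros(width, dtype=bool)
    if n_wheat == 0:
        return np.tile(cols, (height, 1))
    if n_wheat == width:
        return np.tile(~cols, (height, 1))
    lo, hi = band_width_range
    widths: list[int] = []
    remaining = n_wheat
    while remaining > 0:
        w = int(rng.integers(lo, hi + 1))
        widths.append(min(w, remaining))
        remaining -= widths[-1]
    # spread soil columns over the gaps between/around the wheat bands
    n_gaps = len(widths) + 1
    gap_cols = width - n_wheat
    gaps = np.full(n_gaps, gap_cols // n_gaps)
    extra = rng.permutation(n_gaps)[: gap_cols % n_gaps]
    gaps[extra] += 1
    pos = 0
    for gap, w in zip(gaps, widths):
        pos += int(gap)
        cols[pos:pos + w] = True
        pos += w
    return np.tile(cols, (height, 1))


def generate_frame(soil_mean: float, wheat_mean: float, soil_sd: float,
                   wheat_sd: float, cover_fraction: float,
                   size: tuple[int, int] = NATIVE_SHAPE,
                   rng: np.random.Generator | int | None = None,
                   band_width_range: tuple[int, int] = BAND_WIDTH_RANGE,
                   meta: FrameMeta | None = None
                   ) -> tuple[ThermalFrame, GroundTruth]:
    """One synthetic two-class frame plus its ground truth.

    size is (height, width).  rng may be a Generator or a seed.
    """
    if not 0.0 <= cover_fraction <= 1.0:
        raise ValidationError(f"cover_fraction {cover_fraction} outside [0, 1]")
    if soil_sd <= 0 or wheat_sd <= 0:
        raise ValidationError("class standard deviations must be positive")
    if soil_mean <= wheat_mean:
        raise ValidationError("soil must be warmer than wheat (soil_mean > wheat_mean)")
    rng = np.random.default_rng(rng)
    height, width = size
    mask = _row_band_mask(width, height, cover_fraction, rng, band_width_range)
    pixels = np.where(mask,
                      rng.normal(wheat_mean, wheat_sd, size),
                      rng.normal(soil_mean, soil_sd, size))
    n_w = int(mask.sum())
    t_w = float(pixels[mask].mean()) if n_w else float("nan")
    t_s = float(pixels[~mask].mean()) if n_w < mask.size else float("nan")
    truth = GroundTruth(mask=mask, cover_fraction=n_w / mask.size,
                        t_w=t_w, t_s=t_s,
                        soil_mean=soil_mean, wheat_mean=wheat_mean)
    return ThermalFrame(pixels, meta=meta), truth


@dataclass(frozen=True)
class CellSpec:
    """Generation parameters for one variety at one phenological stage."""

    species: str
    variety: str
    stage: str
    soil_mean: float        # degC, > 0
    target_wsi: float       # in (0, 1); fixes wheat_mean = soil_mean*(1-target_wsi)
    cover_fraction: float   # in [0, 1]
    soil_sd: float = 0.5    # degC
    wheat_sd: float = 0.5   # degC

    def __post_init__(self) -> None:
        if not 0.0 < self.target_wsi < 1.0:
            raise ValidationError(f"target_wsi {self.target_wsi} outside (0, 1)")
        if self.soil_mean <= 0:
            raise ValidationError("soil_mean must be positive (degC)")
        if not 0.0 <= self.cover_fraction <= 1.0:
            raise ValidationError("cover_fraction outside [0, 1]")

    @property
    def wheat_mean(self) -> float:
        return self.soil_mean * (1.0 - self.target_wsi)


@dataclass
class GenerationConfig:
    """Full study design: which cells to simulate and at what sampling effort.

    Defaults follow the field protocol: four sessions per stage (two per
    day on two consecutive days) and ten frames per crop per session
    (the per-replicate acquisition count), at the camera's native
    320 x 240 resolution.
    """

    cells: list[CellSpec]
    frames_per_session: int = 10
    sessions_per_stage: int = 4
    size: tuple[int, int] = NATIVE_SHAPE
    seed: int = 0
    session_offset_sd: float = SESSION_OFFSET_SD
    band_width_range: tuple[int, int] = BAND_WIDTH_RANGE

    def __post_init__(self) -> None:
        if self.frames_per_session < 1 or self.sessions_per_stage < 1:
            raise ValidationError("frame and session counts must be >= 1")
        seen = set()
        for c in self.cells:
            key = (c.species, c.variety, c.stage)
            if key in seen:
                raise ValidationError(f"duplicate cell spec for {key}")
            seen.add(key)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenerationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cells = [CellSpec(**c) for c in raw.pop("cells")]
        if "size" in raw:
            raw["size"] = tuple(raw["size"])
        if "band_width_range" in raw:
            raw["band_width_range"] = tuple(raw["band_width_range"])
        return cls(cells=cells, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {"cells": [vars(c).copy() for c in self.cells],
               "frames_per_session": self.frames_per_session,
               "sessions_per_stage": self.sessions_per_stage,
               "size": list(self.size), "seed": self.seed,
               "session_offset_sd": self.session_offset_sd,
               "band_width_range": list(self.band_width_range)}
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class StudyData:
    """In-memory result of a simulated study."""

    frames: list[ThermalFrame]
    truths: list[GroundTruth]
    manifest: pd.DataFrame


def generate_study(config: GenerationConfig, out_dir: str | Path | None = None
                   ) -> StudyData:
    """Simulate every configured cell across sessions and frames.

    Iteration order (and hence the random stream) is fixed: stage ->
    session -> cell -> frame, so identical config and seed reproduce
    identical frames, masks and manifest.  With out_dir set, frames are
    written as CSV rasters plus manifest.csv and truth.csv.
    """
    rng = np.random.default_rng(config.seed)
    stages_present = [s for s in STAGES if any(c.stage == s for c in config.cells)]
    frames: list[ThermalFrame] = []
    truths: list[GroundTruth] = []
    rows: list[dict] = []
    for stage in stages_present:
        stage_cells = [c for c in config.cells if c.stage == stage]
        for session in range(1, config.sessions_per_stage + 1):
            # weather drift shared by every plot measured in this session
            offsets = {sp: rng.normal(0.0, config.session_offset_sd)
                       for sp in sorted({c.species for c in stage_cells})}
            for cell in stage_cells:
                delta = offsets[cell.species]
                for k in range(config.frames_per_session):
                    meta = FrameMeta(species=cell.species, variety=cell.variety,
                                     stage=stage, session=f"S{session}",
                                     replicate=1, frame_index=k)
                    frame, truth = generate_frame(
                        cell.soil_mean + delta, cell.wheat_mean + delta,
                        cell.soil_sd, cell.wheat_sd, cell.cover_fraction,
                        size=config.size, rng=rng,
                        band_width_range=config.band_width_range, meta=meta)
                    frames.append(frame)
                    truths.append(truth)
                    rows.append({
                        "file": f"{cell.species}_{cell.variety}_{stage}_S{session}_{k:02d}.csv",
                        "species": cell.species, "variety": cell.variety,
                        "stage": stage, "session": f"S{session}",
                        "replicate": 1, "frame_index": k})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for frame, row in zip(frames, rows):
            write_frame(frame, out_dir / row["file"], format="csv")
        write_manifest(rows, out_dir / "manifest.csv")
        truth_df = pd.DataFrame({
            "file": [r["file"] for r in rows],
            "cover_fraction": [t.cover_fraction for t in truths],
            "t_w": [t.t_w for t in truths],
            "t_s": [t.t_s for t in truths],
            "wsi": [t.wsi for t in truths]})
        truth_df.to_csv(out_dir / "truth.csv", index=False)
    return StudyData(frames=frames, truths=truths, manifest=manifest)


def config_from_study_tables(species: str, soil_mean: float = 25.0,
                             late_cover: float = 0.85, **kwargs
                             ) -> GenerationConfig:
    """Build a generation config whose targets are the published tables.

    target_wsi per variety x stage comes from the published stage WSI
    matrix; cover_fraction at stem elongation comes from the published
    per-variety WCI, and ``late_cover`` is used at the three later
    stages (cover there does not enter any published quantity; a closed
    canopy still needs visible soil for the soil reference).
    """
    from .datasets import load_wci_frame, load_wsi_table

    wsi = load_wsi_table(species).stage_matrix
    wci = load_wci_frame(species)["wci_m"]
    cells = [CellSpec(species=species, variety=v, stage=s,
                      soil_mean=soil_mean, target_wsi=float(wsi.loc[v, s]),
                      cover_fraction=float(wci[v]) if s == "stem_elongation" else late_cover)
             for v in wsi.index for s in STAGES]
    return GenerationConfig(cells=cells, **kwargs)
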
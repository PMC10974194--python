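"""Thermal frame data model and file I/O.

A frame is a 2-D raster of surface temperatures in degrees Celsius, as
exported by a radiometric long-wave infrared camera after internal
calibration (the package never touches detector counts or emissivity).
Two on-disk formats are supported: a plain CSV matrix with the literal
token ``NA`` marking missing pixels, and single-band 32-bit float TIFF
with NaN marking missing pixels.  CSV round-trips are lossless.

Temperatures are degrees Celsius throughout.  This matters: the wheat
stress index (T_S - T_W)/T_S is *not* invariant under a change of
temperature unit or origin, and all published values assume Celsius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .errors import FrameFormatError, ValidationError

#: Missing-pixel sentinel used in CSV frame files.
NA_TOKEN = "NA"

#: Native detector resolution (rows, cols) of the study camera; configurable
#: everywhere, this is only the default frame size.
NATIVE_SHAPE = (240, 320)

#: The four monitored phenological stages, in chronological order.
STAGES = ("stem_elongation", "heading_begins", "milky_waxy", "full_ripening")

#: Variety codes per species (9 each: 3 ancient landraces, 4 seeded mixtures,
#: 2 modern cultivars).
VARIETIES = {
    "durum": ("SC", "MZ", "SL", "MixD1", "MixD2", "MixD3", "MixD4", "PG", "SV"),
    "common": ("RS", "RM", "GR", "MixC1", "MixC2", "MixC3", "MixC4", "AX", "AL"),
}

#: Modern (recently bred) cultivars; the rest are landraces or their mixtures.
MODERN_VARIETIES = {"durum": frozenset({"PG", "SV"}), "common": frozenset({"AX", "AL"})}

MANIFEST_COLUMNS = ["file", "species", "variety", "stage", "session", "replicate", "frame_index"]
YIELD_COLUMNS = ["variety", "yield_t_ha", "culms_m2", "spikes_m2", "biomass_t_ha"]


def species_of(variety: str) -> str:
    """Return the species a variety code belongs to.

    Raises ValidationError for codes outside the 18 monitored varieties.
    """
    for species, codes in VARIETIES.items():
        if variety in codes:
            return species
    raise ValidationError(f"unknown variety code {variety!r}")


def is_modern(variety: str) -> bool:
    return variety in MODERN_VARIETIES[species_of(variety)]


@dataclass(frozen=True)
class FrameMeta:
    """Acquisition metadata for one thermal frame."""

    species: str
    variety: str
    stage: str
    session: str
    replicate: int = 1
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.species not in VARIETIES:
            raise ValidationError(f"unknown species {self.species!r}")
        if self.variety not in VARIETIES[self.species]:
            raise ValidationError(
                f"variety {self.variety!r} is not a {self.species} wheat code"
            )
        if self.stage not in STAGES:
            raise ValidationError(f"unknown phenological stage {self.stage!r}")


@dataclass
class ThermalFrame:
    """A 2-D grid of temperatures (degC); NaN marks missing pixels."""

    pixels: np.ndarray
    meta: FrameMeta | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("frame pixels must form a non-empty 2-D grid")
        finite_or_nan = np.isfinite(self.pixels) | np.isnan(self.pixels)
        if not finite_or_nan.all():
            raise ValidationError("non-missing temperatures must be finite")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.pixels)

    @property
    def valid_values(self) -> np.ndarray:
        """1-D array of non-missing temperatures."""
        return self.pixels[self.valid_mask]

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def n_missing(self) -> int:
        return self.pixels.size - self.n_valid


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("tiff", "csv"):
            raise ValidationError(f"unsupported frame format {format!r}")
        return format
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".csv":
        return "csv"
    raise ValidationError(f"cannot infer frame format from {path.name!r}")


def read_frame(path: str | Path, format: str | None = None,
               meta: FrameMeta | None = None) -> ThermalFrame:
    """Read a thermal frame from CSV or single-band float TIFF.

    Non-numeric CSV cells other than the ``NA`` sentinel raise
    FrameFormatError naming the offending cell; multi-band TIFFs are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FrameFormatError(f"frame file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "csv":
        try:
            raw = pd.read_csv(path, header=None, dtype=str,
                              keep_default_na=False, skip_blank_lines=True)
        except Exception as exc:  # malformed CSV structure
            raise FrameFormatError(f"unreadable CSV frame {path}: {exc}") from exc
        values = raw.to_numpy()
        pixels = np.empty(values.shape, dtype=np.float64)
        for (i, j), cell in np.ndenumerate(values):
            cell = cell.strip()
            if cell == NA_TOKEN:
                pixels[i, j] = np.nan
                continue
            try:
                pixels[i, j] = float(cell)
            except ValueError:
                raise FrameFormatError(
                    f"non-numeric cell {cell!r} at row {i}, column {j} in {path}"
                ) from None
    else:
        try:
            pixels = tifffile.imread(path)
        except Exception as exc:
            raise FrameFormatError(f"unreadable TIFF frame {path}: {exc}") from exc
        if pixels.ndim != 2:
            raise FrameFormatError(
                f"expected a single-band raster, got shape {pixels.shape} in {path}"
            )
        pixels = np.asarray(pixels, dtype=np.float64)
    return ThermalFrame(pixels, meta=meta)


def write_frame(frame: ThermalFrame, path: str | Path, format: str | None = None) -> Path:
    """Write a frame to CSV (lossless, ``NA`` sentinel) or 32-bit float TIFF."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        # repr round-trips float64 exactly
        with open(path, "w") as fh:
            for row in frame.pixels:
                fh.write(",".join(NA_TOKEN if np.isnan(v) else repr(float(v))
                                  for v in row))
                fh.write("\n")
    else:
        tifffile.imwrite(path, frame.pixels.astype(np.float32))
    return path


@dataclass
class YieldTable:
    """Per-variety yield components of one species, harvest measurements.

    Columns: variety, yield_t_ha, culms_m2, spikes_m2, biomass_t_ha,
    is_modern.  Units: grain yield and total above-ground biomass in
    t/ha; culm and spike densities per square metre.
    """

    species: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in YIELD_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"yield table missing column(s): {missing}")
        unknown = [v for v in df["variety"] if v not in VARIETIES[self.species]]
        if unknown:
            raise ValidationError(f"unknown variety code(s) for {self.species}: {unknown}")
        if len(df) != len(set(df["variety"])):
            raise ValidationError("duplicate variety codes in yield table")
        numeric = df[YIELD_COLUMNS[1:]].to_numpy(dtype=float)
        if not np.isfinite(numeric).all() or (numeric < 0).any():
            raise ValidationError("yield components must be finite and non-negative")
        df = df.copy()
        df["is_modern"] = [is_modern(v) for v in df["variety"]]
        self.data = df.set_index("variety", drop=False)

    @property
    def varieties(self) -> list[str]:
        return list(self.data["variety"])


def read_yield_table(path: str | Path, species: str | None = None) -> YieldTable:
    """Read a yield-components CSV; species is inferred from variety codes."""
    df = pd.read_csv(path)
    missing = [c for c in YIELD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"yield table {path} missing column(s): {missing}")
    if species is None:
        if len(df) == 0:
            raise ValidationError(f"empty yield table {path}")
        species = species_of(str(df["variety"].iloc[0]))
    return YieldTable(species=species, data=df)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the study-level frame manifest (one row per frame file)."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest {path} missing column(s): {missing}")
    for _, row in df.iterrows():
        FrameMeta(species=row["species"], variety=row["variety"], stage=row["stage"],
                  session=str(row["session"]), replicate=int(row["replicate"]),
                  frame_index=int(row["frame_index"]))
    return df


def write_manifest(rows: Iterable[dict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def meta_from_manifest_row(row) -> FrameMeta:
    return FrameMeta(species=row["species"], variety=row["variety"], stage=row["stage"],
                     session=str(row["session"]), replicate=int(row["replicate"]),
                     frame_index=int(row["frame_index"]))
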
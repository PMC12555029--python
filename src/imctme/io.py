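"""Shared data model and file formats.

Canonical on-disk formats:

* **Cell table** — CSV with a versioned header comment line
  (``# imctme-cell-table-v1``) followed by a standard header.  Required
  columns: ``cell_id, sample_id, roi_id, x_um, y_um`` plus one numeric
  column per panel marker.  Coordinates are micrometres with the origin at
  the ROI top-left and y increasing downward (image convention).  Optional
  label columns (``phenotype``, ``compartment``, ``hormone_class``) and any
  extra columns (morphology features, ground-truth sidecars) are preserved
  verbatim.
* **Sample metadata** — CSV with ``sample_id, condition, site`` (+ extras);
  ``condition`` is ``primary`` or ``recurrent``.
* **ROI image** — multipage TIFF, one float32 page per channel, channel
  names and pixel size stored as JSON in the first page description.
* **Panel / gating configs** — YAML (see :mod:`imctme.panel` and
  :mod:`imctme.phenotyping`).

Readers validate and reject malformed input rather than coercing it; every
writer/reader pair is lossless for the documented schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigurationError, ParseError, SchemaError
from .panel import MarkerPanel

CELL_TABLE_VERSION = "imctme-cell-table-v1"

#: Required identifier/coordinate columns of a cell table.
ID_COLUMNS = ["cell_id", "sample_id", "roi_id", "x_um", "y_um"]

#: Controlled vocabularies for optional label columns.
COMPARTMENT_LABELS = ("tumor", "collagen_rich", "vessel", "excluded", "background")
CONDITIONS = ("primary", "recurrent")
HORMONE_LABELS = ("PR+ERa+", "PR+ERa-", "PR-ERa+", "PR-ERa-")


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

def write_cell_table(cells: pd.DataFrame, path, panel: MarkerPanel) -> None:
    """Write a cell table CSV with the versioned header line."""
    _validate_cell_frame(cells, panel, where="write_cell_table input")
    with open(path, "w", newline="") as fh:
        fh.write(f"# {CELL_TABLE_VERSION}\n")
        cells.to_csv(fh, index=False)


def read_cell_table(path, panel: MarkerPanel) -> pd.DataFrame:
    """Read and validate a cell table.

    Unknown extra columns are preserved; row order is preserved.  Raises
    :class:`SchemaError` naming any missing required column and
    :class:`ParseError` (with row number) for non-numeric intensities.
    """
    with open(path) as fh:
        first = fh.readline()
        if first.lstrip("# ").strip() != CELL_TABLE_VERSION:
            # tolerate tables without the version comment, but not a
            # different version tag
            if first.startswith("#"):
                raise SchemaError(
                    f"{path}: unsupported cell-table version {first.strip()!r}"
                )
            fh.seek(0)
        try:
            df = pd.read_csv(fh, dtype="object")
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise ParseError(f"{path}: not a parseable cell table ({exc})")
    missing = [c for c in ID_COLUMNS + panel.names if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in ["x_um", "y_um"] + panel.names:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ParseError(f"{path}: missing value in column {col!r} at data row {row}")
        df[col] = converted
    for col in df.columns:
        if col not in ["x_um", "y_um"] + panel.names and col not in (
            "cell_id", "sample_id", "roi_id"
        ):
            # opaque extra columns: booleans and numerics restored when
            # they parse cleanly
            vals = set(df[col].dropna().unique())
            if vals and vals <= {"True", "False", True, False}:
                df[col] = df[col].map({"True": True, "False": False,
                                       True: True, False: False})
                continue
            converted = pd.to_numeric(df[col], errors="coerce")
            if not (converted.isna() & df[col].notna()).any():
                df[col] = converted
    _validate_cell_frame(df, panel, where=str(path))
    return df


def _validate_cell_frame(df: pd.DataFrame, panel: MarkerPanel, where: str) -> None:
    missing = [c for c in ID_COLUMNS + panel.names if c not in df.columns]
    if missing:
        raise SchemaError(f"{where}: missing required column(s): {', '.join(missing)}")
    intensities = df[panel.names].to_numpy(dtype=float)
    if np.any(intensities < 0):
        marker = panel.names[int(np.argwhere(intensities < 0)[0][1])]
        raise SchemaError(f"{where}: negative intensity in column {marker!r}")
    if "compartment" in df.columns:
        bad = set(df["compartment"].dropna()) - set(COMPARTMENT_LABELS)
        if bad:
            raise SchemaError(f"{where}: unknown compartment label(s) {sorted(bad)}")
    if "hormone_class" in df.columns:
        bad = set(df["hormone_class"].dropna()) - set(HORMONE_LABELS)
        if bad:
            raise SchemaError(f"{where}: unknown hormone label(s) {sorted(bad)}")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def write_sample_meta(meta: pd.DataFrame, path) -> None:
    _validate_meta(meta, where="write_sample_meta input")
    meta.to_csv(path, index=False)


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    _validate_meta(meta, where=str(path))
    return meta


def _validate_meta(meta: pd.DataFrame, where: str) -> None:
    for col in ("sample_id", "condition"):
        if col not in meta.columns:
            raise SchemaError(f"{where}: missing required column(s): {col}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"{where}: duplicate sample_id {dup!r}")
    bad = set(meta["condition"]) - set(CONDITIONS)
    if bad:
        raise SchemaError(f"{where}: unknown condition label(s) {sorted(bad)}")


# ---------------------------------------------------------------------------
# ROI images
# ---------------------------------------------------------------------------

@dataclass
class RoiImage:
    """Multichannel intensity raster for one ROI.

    ``channels`` has shape (n_channels, height, width); ``channel_names``
    maps page order to marker names.
    """

    channels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float
    roi_id: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 3:
            raise SchemaError("RoiImage channels must be (n_channels, H, W)")
        if len(self.channel_names) != self.channels.shape[0]:
            raise SchemaError(
                f"{len(self.channel_names)} channel names for "
                f"{self.channels.shape[0]} channel pages"
            )
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[self.channel_names.index(name)]
        except ValueError:
            raise SchemaError(f"image has no channel {name!r}")

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names


def write_roi_tiff(image: RoiImage, path) -> None:
    meta = {
        "channels": image.channel_names,
        "pixel_size_um": image.pixel_size_um,
        "roi_id": image.roi_id,
        "sample_id": image.sample_id,
    }
    tifffile.imwrite(path, image.channels, photometric="minisblack",
                     description=json.dumps(meta))


def read_roi_tiff(path, channel_map: list[str] | None = None,
                  pixel_size_um: float | None = None) -> RoiImage:
    """Read a multipage TIFF as a :class:`RoiImage`.

    ``channel_map`` overrides the embedded channel names; an explicit
    ``pixel_size_um`` argument wins over metadata.
    """
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if stack.ndim == 2:
        stack = stack[None]
    names = channel_map if channel_map is not None else meta.get("channels")
    if names is None:
        raise SchemaError(f"{path}: no channel names in metadata and no channel_map")
    if len(names) != stack.shape[0]:
        raise SchemaError(
            f"{path}: channel_map names {len(names)} channels but file has "
            f"{stack.shape[0]} pages"
        )
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise SchemaError(f"{path}: pixel size not in metadata; pass pixel_size_um")
    return RoiImage(
        channels=stack,
        channel_names=list(names),
        pixel_size_um=float(px),
        roi_id=str(meta.get("roi_id", "")),
        sample_id=str(meta.get("sample_id", "")),
    )


# ---------------------------------------------------------------------------
# gating config
# ---------------------------------------------------------------------------

def load_gating_config(path, panel: MarkerPanel):
    """Load and validate a gating-tree YAML against *panel*.

    Returns a :class:`imctme.phenotyping.GatingTree`; raises
    :class:`ConfigurationError` on unknown markers, duplicate leaf labels or
    structural problems.
    """
    from .phenotyping import GatingTree  # deferred: avoid import cycle

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return GatingTree.from_dict(payload, panel)
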
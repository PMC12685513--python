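"""Field images and TIFF interchange.

A :class:`FieldImage` is one imaging field at one time point: a set of
named 16-bit channels (bright-field, DPC, optionally an activation-marker
fluorescence channel and a nuclei channel) plus well/field/time metadata.
Images are exchanged as multi-page 16-bit TIFF, one page per channel, with
the channel order and metadata stored in the TIFF ImageDescription tag as
JSON, so a file round-trips bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ImageIOError

#: canonical channel names in on-disk page order
CHANNEL_ORDER = ("brightfield", "dpc", "marker", "nuclei")


@dataclass
class FieldImage:
    """One imaging field at one time point.

    Parameters
    ----------
    channels
        Mapping channel name -> 2-D ``uint16`` array.  All channels must
        share the same shape.
    well_id
        Plate well identifier, e.g. ``"B03"``.
    field_index
        1-based field number within the well.
    time_h
        Acquisition time in hours since the start of imaging.
    pixel_size
        Physical pixel size in micrometres per pixel (metadata only).
    """

    channels: dict[str, np.ndarray]
    well_id: str = ""
    field_index: int = 1
    time_h: float = 0.0
    pixel_size: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage requires at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        if self.time_h < 0:
            raise ValueError("time_h must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not present (have {list(self.channels)})"
            )
        return self.channels[name]


def write_field_tiff(image: FieldImage, path: str | Path) -> Path:
    """Write a field as a multi-page 16-bit TIFF (one page per channel)."""
    path = Path(path)
    names = [c for c in CHANNEL_ORDER if c in image.channels]
    names += [c for c in image.channels if c not in names]
    desc = json.dumps(
        {
            "channels": names,
            "well_id": image.well_id,
            "field_index": image.field_index,
            "time_h": image.time_h,
            "pixel_size": image.pixel_size,
            "meta": image.meta,
        }
    )
    stack = np.stack([np.asarray(image.channels[n], dtype=np.uint16) for n in names])
    tifffile.imwrite(path, stack, description=desc, metadata=None)
    return path


def read_field_tiff(path: str | Path, expected_channels: int | None = None) -> FieldImage:
    """Read a field written by :func:`write_field_tiff`.

    Channel names come from the JSON sidecar embedded in the TIFF
    description; a bare TIFF without one gets positional names following
    the canonical order.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such image file: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            pages = [p.asarray() for p in tf.pages]
            desc = tf.pages[0].description
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise ImageIOError(f"cannot read TIFF {path}: {exc}") from exc
    if not pages:
        raise ImageIOError(f"empty TIFF: {path}")
    info: dict = {}
    if desc:
        try:
            info = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            info = {}
    names = info.get("channels") or list(CHANNEL_ORDER[: len(pages)])
    if len(names) != len(pages):
        raise ImageIOError(
            f"{path}: metadata lists {len(names)} channels but file has "
            f"{len(pages)} pages"
        )
    if expected_channels is not None and len(pages) != expected_channels:
        raise ImageIOError(
            f"{path}: expected {expected_channels} channels, found {len(pages)}"
        )
    channels = {n: np.asarray(p, dtype=np.uint16) for n, p in zip(names, pages)}
    return FieldImage(
        channels=channels,
        well_id=info.get("well_id", ""),
        field_index=int(info.get("field_index", 1)),
        time_h=float(info.get("time_h", 0.0)),
        pixel_size=float(info.get("pixel_size", 1.0)),
        meta=info.get("meta", {}),
    )
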
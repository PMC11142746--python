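"""Readers and writers: multi-page TIFF cores, mask/label TIFFs, tables.

Cores travel as multi-page TIFF with one page per channel. On write, each
page's ImageDescription holds a small JSON record with the channel name and
pixel size; on read, channel names come from OME-XML metadata when present,
else from those page descriptions, else from an explicit override — in that
precedence.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import Core, EpithelialMask, LabelMap
from .errors import InputDataError


def write_core(core: Core, path) -> None:
    path = Path(path)
    with tifffile.TiffWriter(path) as tw:
        for name, img in core.channels.items():
            desc = json.dumps({"channel": name, "pixel_size_um": core.pixel_size_um})
            tw.write(np.asarray(img), description=desc, contiguous=False)


def _channels_from_ome(tf: tifffile.TiffFile) -> tuple[list[str] | None, float | None]:
    xml = tf.ome_metadata
    if not xml:
        return None, None
    try:
        root = ET.fromstring(xml)
    except ET.ParseError:
        return None, None
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pix = root.find(".//ome:Pixels" if ns else ".//Pixels", ns)
    if pix is None:
        return None, None
    names = [
        ch.get("Name") or f"ch{i}"
        for i, ch in enumerate(pix.findall("ome:Channel" if ns else "Channel", ns))
    ]
    size = pix.get("PhysicalSizeX")
    return (names or None), (float(size) if size else None)


def read_core(
    path,
    channel_names: list[str] | None = None,
    pixel_size_um: float | None = None,
    core_id: str | None = None,
) -> Core:
    """Read a multi-page TIFF / OME-TIFF core.

    Channel names come from OME metadata, then per-page JSON descriptions,
    then the ``channel_names`` override. An override whose length does not
    match the page count is an error.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            pages = [p.asarray() for p in tf.pages]
            # a single 3-D page (C, H, W) also counts as a channel stack
            if len(pages) == 1 and pages[0].ndim == 3:
                pages = list(pages[0])
            names = None
            px = None
            ome_names, ome_px = _channels_from_ome(tf)
            if ome_names and len(ome_names) == len(pages):
                names, px = ome_names, ome_px
            if names is None:
                descs = []
                for p in tf.pages:
                    try:
                        descs.append(json.loads(p.description))
                    except (json.JSONDecodeError, TypeError):
                        descs.append(None)
                if len(descs) == len(pages) and all(
                    isinstance(d, dict) and "channel" in d for d in descs
                ):
                    names = [d["channel"] for d in descs]
                    px = descs[0].get("pixel_size_um")
    except (tifffile.TiffFileError, FileNotFoundError, OSError) as exc:
        raise InputDataError(f"cannot read core image {path}: {exc}") from exc

    if channel_names is not None:
        if len(channel_names) != len(pages):
            raise InputDataError(
                f"{path}: override names {len(channel_names)} != {len(pages)} pages"
            )
        names = list(channel_names)
    if names is None:
        raise InputDataError(
            f"{path}: no channel names in metadata; pass channel_names explicitly"
        )
    if pixel_size_um is not None:
        px = pixel_size_um
    if px is None:
        raise InputDataError(f"{path}: pixel size not in metadata; pass pixel_size_um")
    channels = {n: np.asarray(img) for n, img in zip(names, pages)}
    return Core(channels=channels, pixel_size_um=float(px), core_id=core_id or path.stem)


def write_mask(mask: EpithelialMask, path) -> None:
    tifffile.imwrite(Path(path), mask.mask.astype(np.uint16))


def read_mask(path, source: str = "detected") -> EpithelialMask:
    arr = tifffile.imread(Path(path))
    return EpithelialMask(mask=arr > 0, source="detected") if source == "detected" else \
        EpithelialMask(mask=arr > 0, source=source)


def write_labels(labels: LabelMap, path) -> None:
    if labels.n_objects > np.iinfo(np.uint16).max:
        raise InputDataError("more than 65535 objects; cannot store as 16-bit TIFF")
    tifffile.imwrite(Path(path), labels.labels.astype(np.uint16))


def read_labels(path, kind: str) -> LabelMap:
    arr = tifffile.imread(Path(path))
    return LabelMap(labels=arr.astype(np.int32), kind=kind)


# --------------------------------------------------------------------------
# tables (missing values as empty CSV fields)
# --------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    # %.17g + round_trip parsing on read keeps floats bit-exact across a cycle
    df.to_csv(Path(path), index=False, float_format="%.17g")


def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"required table not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in (required or []) if c not in df.columns]
    if missing:
        raise InputDataError(f"{path}: missing required columns {missing}")
    return df


def _jsonable(obj):
    """Convert numpy scalars/arrays and non-finite floats (-> null)."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
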
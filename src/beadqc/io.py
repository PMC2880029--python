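"""Readers and writers for the on-disk formats.

Formats handled: 16-bit grayscale section TIFFs, the bead-level text table
(TSV of bead_type_id, x, y, intensity for decoded beads; coordinates at a
declared decimal precision), a plain binary locs dialect holding single-
precision centres for *all* grid positions including non-decoded beads, the
chip-layout JSON, and mask tables. The locs dialect is this package's own
(magic + count header, then little-endian float32 x,y pairs in grid order);
real vendor binaries are not parsed.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .array_model import ChipLayout
from .masks import MaskSet

LOCS_MAGIC = b"BLCS"
LOCS_VERSION = 1

BEADLEVEL_COLUMNS = ("bead_type_id", "x", "y", "intensity")


class FormatError(ValueError):
    """A file does not conform to the expected format."""


# ---------------------------------------------------------------------------
# TIFF


def read_tiff(path) -> np.ndarray:
    """Read a 16-bit (or 8-bit) grayscale section image."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-channel grayscale image, got shape {arr.shape}"
        )
    if arr.dtype not in (np.dtype("uint16"), np.dtype("uint8")):
        raise FormatError(
            f"{path}: expected 8/16-bit unsigned pixels, got dtype {arr.dtype}"
        )
    return arr.astype(np.uint16)


def write_tiff(path, image: np.ndarray) -> None:
    """Write a 16-bit grayscale TIFF (lossless round-trip)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise FormatError("image must be 2-D grayscale")
    if image.dtype != np.uint16:
        if np.issubdtype(image.dtype, np.integer) and image.min() >= 0 and image.max() <= 65535:
            image = image.astype(np.uint16)
        else:
            raise FormatError("image must be unsigned 16-bit (0..65535)")
    tifffile.imwrite(str(path), image)


# ---------------------------------------------------------------------------
# bead-level text table


def write_beadlevel(path, beads: pd.DataFrame, precision: int = 4) -> None:
    """Write the decoded-bead table as TSV with fixed coordinate precision."""
    missing = [c for c in BEADLEVEL_COLUMNS if c not in beads.columns]
    if missing:
        raise ValueError(f"bead table missing columns: {missing}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(BEADLEVEL_COLUMNS) + "\n")
        ids = beads["bead_type_id"].to_numpy()
        xs = beads["x"].to_numpy(dtype=float)
        ys = beads["y"].to_numpy(dtype=float)
        vals = beads["intensity"].to_numpy(dtype=float)
        fmt = f"%d\t%.{precision}f\t%.{precision}f\t%.3f\n"
        for row in zip(ids, xs, ys, vals):
            fh.write(fmt % row)


def read_beadlevel(path) -> pd.DataFrame:
    """Read a bead-level TSV, tolerating 2-4 decimal places on coordinates.

    Malformed rows and duplicated headers raise :class:`FormatError` with the
    offending line number.
    """
    path = Path(path)
    header = None
    ids, xs, ys, vals = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if header is None:
                if tuple(parts) != BEADLEVEL_COLUMNS:
                    raise FormatError(
                        f"{path}:{lineno}: bad header {parts!r}, "
                        f"expected {list(BEADLEVEL_COLUMNS)}"
                    )
                header = parts
                continue
            if parts == list(BEADLEVEL_COLUMNS):
                raise FormatError(f"{path}:{lineno}: duplicated header row")
            if len(parts) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            try:
                ids.append(int(parts[0]))
                xs.append(float(parts[1]))
                ys.append(float(parts[2]))
                vals.append(float(parts[3]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed row: {exc}") from None
    if header is None:
        raise FormatError(f"{path}: empty file (no header)")
    return pd.DataFrame({"bead_type_id": np.array(ids, dtype=np.int64),
                         "x": xs, "y": ys, "intensity": vals})


# ---------------------------------------------------------------------------
# locs binary dialect


def write_locs(path, xy: np.ndarray) -> None:
    """Write (n, 2) centres for all grid positions as the binary locs dialect."""
    xy = np.asarray(xy, dtype=np.float32)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be an (n, 2) array")
    if not np.all(np.isfinite(xy)):
        raise ValueError("locs coordinates must be finite")
    with open(path, "wb") as fh:
        fh.write(LOCS_MAGIC)
        fh.write(struct.pack("<II", LOCS_VERSION, xy.shape[0]))
        fh.write(xy.astype("<f4").tobytes())


def read_locs(path, expected_count: int | None = None,
              layout: ChipLayout | None = None) -> np.ndarray:
    """Read the locs dialect; optionally validate the record count.

    If ``layout`` is given the expected count is its beads-per-segment (one
    segment per file, the registration unit).
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 12 or data[:4] != LOCS_MAGIC:
        raise FormatError(f"{path}: not a locs file (bad magic)")
    version, count = struct.unpack("<II", data[4:12])
    if version != LOCS_VERSION:
        raise FormatError(f"{path}: unsupported locs version {version}")
    body = data[12:]
    if len(body) != count * 8:
        raise FormatError(
            f"{path}: truncated locs file: header promises {count} records "
            f"({count * 8} bytes), found {len(body)} bytes"
        )
    if layout is not None and expected_count is None:
        expected_count = layout.beads_per_segment
    if expected_count is not None and count != expected_count:
        raise FormatError(
            f"{path}: record count mismatch: expected {expected_count}, found {count}"
        )
    return np.frombuffer(body, dtype="<f4").reshape(count, 2).astype(np.float32)


# ---------------------------------------------------------------------------
# layout / mask / report JSON


def write_layout_json(path, layout: ChipLayout) -> None:
    Path(path).write_text(json.dumps(layout.to_dict(), indent=2, sort_keys=True) + "\n")


def read_layout_json(path) -> ChipLayout:
    try:
        return ChipLayout.from_dict(json.loads(Path(path).read_text()))
    except (TypeError, KeyError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: invalid layout JSON: {exc}") from exc


def write_mask_tsv(path, mask: MaskSet) -> None:
    frame = mask.to_frame()
    with open(path, "w", newline="\n") as fh:
        fh.write("bead_index\treason\n")
        for row in frame.itertuples(index=False):
            fh.write(f"{row.bead_index}\t{row.reason}\n")


def read_mask_tsv(path, n_beads: int) -> MaskSet:
    frame = pd.read_csv(path, sep="\t")
    if list(frame.columns) != ["bead_index", "reason"]:
        raise FormatError(f"{path}: expected columns bead_index, reason")
    return MaskSet.from_frame(frame, n_beads)


def write_json_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
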
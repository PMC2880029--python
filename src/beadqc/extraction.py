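"""Illumina-style feature-intensity extraction.

The pipeline mirrors the vendor's three-step scheme: a sharpening convolution
concentrates fluorescence toward feature centres, the *foreground* is a
weighted average over a 4x4 pixel window about the bead centre in the
sharpened image, and the *background* is a robustified summary of the five
lowest pixels in a 17x17 window of the raw image. The final intensity is
foreground minus background (negative values are preserved; downstream
log-domain summaries mask non-positives).

The exact vendor sharpening coefficients and weight tables are not public;
the laws implemented here are documented dialects chosen to satisfy the
published constraints (centre 2x2 of the foreground window always maximally
weighted, outer weights driven by the fractional part of the centre; kernel a
unit-sum centre-surround filter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .array_model import BG_HALF, FG_HI, FG_LO
from .masks import MaskSet

#: unit-sum centre-surround sharpening kernel (dialect; vendor kernel unpublished)
SHARPEN_KERNEL = np.array([[0, -1, 0],
                           [-1, 5, -1],
                           [0, -1, 0]], dtype=float)

_BG_N_PIXELS = (2 * BG_HALF + 1) ** 2  # 289

BACKGROUND_RULES = ("mean5", "median5", "rank_k", "trimmed_mean")
WEIGHTINGS = ("fractional", "uniform")


class WindowClippedError(ValueError):
    """An extraction window extends outside the image.

    Callers should pre-screen beads with
    :func:`beadqc.array_model.flag_out_of_image` instead of catching this.
    """


@dataclass(frozen=True)
class ExtractionOptions:
    """Tunable knobs of the extraction pipeline.

    background_rule
        ``mean5`` (vendor default: mean of the 5 lowest pixels), ``median5``
        (3rd lowest; robust to single aberrant pixels), ``rank_k`` (the k-th
        lowest), or ``trimmed_mean`` (mean of the ``trim_n`` lowest after
        dropping ``trim`` from each end).
    weighting
        ``fractional`` (outer weights from the fractional part of the centre)
        or ``uniform`` (all 16 pixels equal; the location-independent variant).
    """

    background_rule: str = "mean5"
    rank_k: int = 5
    trim_n: int = 5
    trim: int = 1
    weighting: str = "fractional"
    sharpen: bool = True

    def __post_init__(self):
        if self.background_rule not in BACKGROUND_RULES:
            raise ValueError(f"background_rule must be one of {BACKGROUND_RULES}")
        if not 1 <= self.rank_k <= _BG_N_PIXELS:
            raise ValueError(f"rank_k must be in 1..{_BG_N_PIXELS}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")
        if not (self.trim >= 0 and self.trim < self.trim_n / 2):
            raise ValueError("trim must satisfy 0 <= trim < trim_n/2")


def sharpen(image: np.ndarray) -> np.ndarray:
    """Sharpening convolution with edge-replicated borders, clipped at 0.

    The kernel sums to one, so uniform images are fixed points.
    """
    if image.size == 0:
        raise ValueError("image is empty")
    out = ndimage.convolve(np.asarray(image, dtype=float), SHARPEN_KERNEL,
                           mode="nearest")
    np.clip(out, 0.0, None, out=out)
    return out


def foreground_weights(frac_x: float, frac_y: float,
                       weighting: str = "fractional") -> np.ndarray:
    """4x4 foreground weight table for a bead-centre fractional offset.

    Fractional mode: column weights ``(1-f, 1, 1, f)`` and row weights
    ``(1-g, 1, 1, g)``; the table is their outer product normalised to sum 1,
    so the centre 2x2 always carries the maximal unnormalised weight. The
    weighted-window centroid then coincides exactly with the bead centre.
    Uniform mode gives all 16 pixels weight 1/16. Index order is [row, col].
    """
    if not (0 <= frac_x < 1 and 0 <= frac_y < 1):
        raise ValueError("fractional offsets must lie in [0, 1)")
    if weighting == "uniform":
        return np.full((4, 4), 1.0 / 16.0)
    if weighting != "fractional":
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    col_w = np.array([1.0 - frac_x, 1.0, 1.0, frac_x])
    row_w = np.array([1.0 - frac_y, 1.0, 1.0, frac_y])
    w = np.outer(row_w, col_w)
    return w / w.sum()


def _anchors(x, y):
    ax = np.floor(np.asarray(x, dtype=float)).astype(np.int64)
    ay = np.floor(np.asarray(y, dtype=float)).astype(np.int64)
    return ax, ay


def _check_window(shape, ax, ay, lo, hi, what):
    h, w = shape
    bad = (ax + lo < 0) | (ax + hi > w - 1) | (ay + lo < 0) | (ay + hi > h - 1)
    if np.any(bad):
        raise WindowClippedError(
            f"{what} window extends outside the image for "
            f"{int(np.sum(bad))} bead(s); screen beads with "
            "array_model.flag_out_of_image first"
        )


def _gather_windows(image: np.ndarray, ax: np.ndarray, ay: np.ndarray,
                    lo: int, hi: int) -> np.ndarray:
    """(n, k, k) pixel windows at rows ay+lo..ay+hi, cols ax+lo..ax+hi."""
    offs = np.arange(lo, hi + 1)
    rows = ay[:, None, None] + offs[None, :, None]
    cols = ax[:, None, None] + offs[None, None, :]
    return image[rows, cols]


def compute_foreground(sharpened: np.ndarray, centre: tuple[float, float],
                       options: ExtractionOptions | None = None) -> float:
    """Weighted 4x4 foreground at one bead centre in the sharpened image."""
    options = options or ExtractionOptions()
    x, y = centre
    ax, ay = _anchors([x], [y])
    _check_window(sharpened.shape, ax, ay, FG_LO, FG_HI, "4x4 foreground")
    win = _gather_windows(np.asarray(sharpened, dtype=float), ax, ay, FG_LO, FG_HI)[0]
    w = foreground_weights(x - ax[0], y - ay[0], options.weighting)
    return float(np.sum(w * win))


def _background_from_sorted(smallest: np.ndarray, options: ExtractionOptions) -> np.ndarray:
    """Background summary from the (n, k) ascending smallest window values."""
    rule = options.background_rule
    if rule == "mean5":
        return smallest[:, :5].mean(axis=1)
    if rule == "median5":
        return smallest[:, 2].astype(float)
    if rule == "rank_k":
        return smallest[:, options.rank_k - 1].astype(float)
    if rule == "trimmed_mean":
        vals = smallest[:, : options.trim_n]
        t = options.trim
        if t:
            vals = vals[:, t:-t]
        return vals.mean(axis=1)
    raise ValueError(f"unknown background rule {rule!r}")


def _smallest_needed(options: ExtractionOptions) -> int:
    return max(5, options.rank_k, options.trim_n)


def compute_background(raw: np.ndarray, centre: tuple[float, float],
                       options: ExtractionOptions | None = None) -> float:
    """Background summary of the 17x17 raw-image window about the anchor pixel.

    The fractional part of the centre is ignored here; only the anchor pixel
    positions the window.
    """
    options = options or ExtractionOptions()
    x, y = centre
    ax, ay = _anchors([x], [y])
    _check_window(raw.shape, ax, ay, -BG_HALF, BG_HALF, "17x17 background")
    win = _gather_windows(np.asarray(raw, dtype=float), ax, ay, -BG_HALF, BG_HALF)
    k = _smallest_needed(options)
    flat = win.reshape(1, -1)
    smallest = np.sort(np.partition(flat, k - 1, axis=1)[:, :k], axis=1)
    return float(_background_from_sorted(smallest, options)[0])


def count_true_background_pixels(grid_centres, focal_centre) -> int:
    """Number of the 289 candidate background pixels not claimed by any foreground.

    Masks the 4x4 foreground window of every bead (including the focal bead)
    out of the focal bead's 17x17 background window and counts what is left.
    With no neighbours this is 289 - 16 = 273; on a pitch-6 lattice it ranges
    far lower because up to 12 bead-centres can share the window.
    """
    fx, fy = focal_centre
    fax, fay = int(np.floor(fx)), int(np.floor(fy))
    bg_cols = np.arange(fax - BG_HALF, fax + BG_HALF + 1)
    bg_rows = np.arange(fay - BG_HALF, fay + BG_HALF + 1)
    in_window = np.ones((bg_rows.size, bg_cols.size), dtype=bool)
    centres = list(grid_centres)
    if not any(np.hypot(cx - fx, cy - fy) < 1e-9 for cx, cy in centres):
        centres.append((fx, fy))
    for cx, cy in centres:
        ax, ay = int(np.floor(cx)), int(np.floor(cy))
        cmask = (bg_cols >= ax + FG_LO) & (bg_cols <= ax + FG_HI)
        rmask = (bg_rows >= ay + FG_LO) & (bg_rows <= ay + FG_HI)
        in_window[np.ix_(rmask, cmask)] = False
    return int(in_window.sum())


def extract_all(raw: np.ndarray, beads: pd.DataFrame,
                options: ExtractionOptions | None = None,
                chunk_size: int = 16384) -> tuple[pd.DataFrame, MaskSet]:
    """Extract foreground/background/intensity for every bead of a section.

    Beads whose windows would be clipped are flagged ``out_of_image`` and get
    NaN values rather than being dropped. Returns a copy of ``beads`` with
    ``foreground``, ``background`` and ``intensity`` columns plus the MaskSet.
    """
    options = options or ExtractionOptions()
    raw = np.asarray(raw, dtype=float)
    img = sharpen(raw) if options.sharpen else raw
    x = beads["x"].to_numpy(dtype=float)
    y = beads["y"].to_numpy(dtype=float)
    ax, ay = _anchors(x, y)
    h, w = raw.shape
    ok = (
        (ax - BG_HALF >= 0) & (ax + BG_HALF <= w - 1)
        & (ay - BG_HALF >= 0) & (ay + BG_HALF <= h - 1)
    )
    n = len(beads)
    fg = np.full(n, np.nan)
    bg = np.full(n, np.nan)
    idx = np.flatnonzero(ok)
    fx = x - ax
    fy = y - ay
    k = _smallest_needed(options)
    for start in range(0, idx.size, chunk_size):
        sel = idx[start : start + chunk_size]
        fwin = _gather_windows(img, ax[sel], ay[sel], FG_LO, FG_HI)
        if options.weighting == "uniform":
            fg[sel] = fwin.reshape(sel.size, -1).mean(axis=1)
        else:
            col_w = np.stack([1.0 - fx[sel], np.ones(sel.size),
                              np.ones(sel.size), fx[sel]], axis=1)
            row_w = np.stack([1.0 - fy[sel], np.ones(sel.size),
                              np.ones(sel.size), fy[sel]], axis=1)
            wsum = col_w.sum(axis=1) * row_w.sum(axis=1)
            fg[sel] = np.einsum("nr,nrc,nc->n", row_w, fwin, col_w) / wsum
        bwin = _gather_windows(raw, ax[sel], ay[sel], -BG_HALF, BG_HALF)
        flat = bwin.reshape(sel.size, -1)
        smallest = np.sort(np.partition(flat, k - 1, axis=1)[:, :k], axis=1)
        bg[sel] = _background_from_sorted(smallest, options)
    out = beads.copy()
    out["foreground"] = fg
    out["background"] = bg
    out["intensity"] = fg - bg
    ms = MaskSet(n)
    ms.add("out_of_image", ~ok)
    return out, ms
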
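"""Grid registration and mis-mapping diagnostics.

Covers four failure modes of the registration/decoding pipeline:

* per-bead departure from the segment's regular grid, quantified by the
  Euclidean residual of an affine fit of pixel coordinates on grid
  coordinates (large residuals mean the wrong feature is being interrogated);
* whole-segment mis-registration, which randomises the bead-type annotation
  and is repaired by searching integer grid shifts for the sharp drop in
  within-bead-type variance;
* gross section assembly problems, caught by comparing segments' coordinate
  extremes and spacing;
* between-channel coordinate discordance on two-colour platforms, including
  spatially varying ("variable pixel size") shift fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max

from .array_model import ROW_SPACING_FACTOR, ChipLayout
from .masks import MaskSet


class InsufficientLandmarksError(RuntimeError):
    """Too few bright beads detected to register the grid."""


# ---------------------------------------------------------------------------
# registration (simplified detect / fit / interpolate)


def _refine_peak_centroids(image: np.ndarray, peaks: np.ndarray, half: int = 2):
    """Sub-pixel spot centres: intensity-weighted centroid in a (2h+1)^2 window."""
    h, w = image.shape
    xs, ys = [], []
    offs = np.arange(-half, half + 1)
    for py, px in peaks:
        r0, r1 = max(0, py - half), min(h, py + half + 1)
        c0, c1 = max(0, px - half), min(w, px + half + 1)
        win = image[r0:r1, c0:c1].astype(float)
        win = win - win.min()
        tot = win.sum()
        if tot <= 0:
            xs.append(float(px))
            ys.append(float(py))
            continue
        cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        xs.append(float((win * cc).sum() / tot))
        ys.append(float((win * rr).sum() / tot))
    return np.array(xs), np.array(ys)


def register_grid(image: np.ndarray, layout: ChipLayout,
                  threshold: float | None = None,
                  min_landmarks: int = 10) -> tuple[tuple[float, float], float]:
    """Estimate the hex-grid origin and pitch of a rendered segment image.

    Detects bright local maxima, refines them to sub-pixel centroids, assigns
    provisional grid indices from the nominal pitch, and fits origin and pitch
    by least squares to the hexagonal model. Returns ``((x0, y0), pitch)``.
    The recovered origin is the centre of the lattice's row-0/column-0 bead,
    assuming the dimmest rows/columns are still detectable; on images where
    whole border rows fall below threshold the origin is reported modulo the
    lattice.
    """
    image = np.asarray(image, dtype=float)
    if threshold is None:
        med = float(np.median(image))
        mad = float(np.median(np.abs(image - med))) * 1.4826
        threshold = med + 5.0 * max(mad, 1e-6)
    p0 = layout.bead_pitch
    peaks = peak_local_max(image, min_distance=max(2, int(p0 // 2) - 1),
                           threshold_abs=threshold)
    if len(peaks) < min_landmarks:
        raise InsufficientLandmarksError(
            f"insufficient landmarks: detected {len(peaks)} bright beads "
            f"(need >= {min_landmarks})"
        )
    x, y = _refine_peak_centroids(image, peaks)
    row_h = p0 * ROW_SPACING_FACTOR
    # two assignment/fit passes: rough indices from the nominal pitch, then
    # re-assignment with the fitted geometry
    y0 = y.min()
    for _ in range(2):
        r_idx = np.rint((y - y0) / row_h)
        A = np.column_stack([np.ones_like(r_idx), r_idx])
        (y0, row_h), *_ = np.linalg.lstsq(A, y, rcond=None)
    r_idx = np.rint((y - y0) / row_h).astype(int)
    pitch_est = row_h / ROW_SPACING_FACTOR
    x_adj = x - (r_idx % 2) * (pitch_est / 2.0)
    x0 = x_adj.min()
    for _ in range(2):
        c_idx = np.rint((x_adj - x0) / pitch_est)
        A = np.column_stack([np.ones_like(c_idx), c_idx])
        (x0, pitch_x), *_ = np.linalg.lstsq(A, x_adj, rcond=None)
        pitch_est = pitch_x
    pitch = float((pitch_est + row_h / ROW_SPACING_FACTOR) / 2.0)
    return (float(x0), float(y0)), pitch


def refine_centres(image: np.ndarray, nominal_centres: np.ndarray,
                   search_radius: float = 2.0, n_iter: int = 2) -> np.ndarray:
    """Move each centre to the intensity-weighted centroid within a disc.

    Background (the window minimum) is subtracted before weighting, so a bead
    with no signal keeps its nominal centre. Brighter beads therefore move
    more reliably toward their true spot — the location/intensity feedback
    the extraction pipeline inherits.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    centres = np.asarray(nominal_centres, dtype=float).copy()
    half = int(np.ceil(search_radius))
    offs = np.arange(-half, half + 1)
    for _ in range(n_iter):
        out = centres.copy()
        for i, (cx, cy) in enumerate(centres):
            ax, ay = int(np.rint(cx)), int(np.rint(cy))
            if ax - half < 0 or ax + half > w - 1 or ay - half < 0 or ay + half > h - 1:
                continue
            win = image[ay - half : ay + half + 1, ax - half : ax + half + 1]
            px = ax + offs
            py = ay + offs
            dx = px[None, :] - cx
            dy = py[:, None] - cy
            disc = dx**2 + dy**2 <= search_radius**2
            wgt = (win - win.min()) * disc
            tot = wgt.sum()
            if tot <= 0:
                continue
            out[i, 0] = (wgt * px[None, :]).sum() / tot
            out[i, 1] = (wgt * py[:, None]).sum() / tot
        centres = out
    return centres


# ---------------------------------------------------------------------------
# departure from the grid


@dataclass
class GridFit:
    """Affine fit of pixel coordinates on grid coordinates for one segment."""

    coef_x: np.ndarray  # (intercept, per-grid-col, per-grid-row, row-parity) for P_x
    coef_y: np.ndarray
    residual_x: np.ndarray
    residual_y: np.ndarray
    departure: np.ndarray  # d = sqrt(rx^2 + ry^2)


def fit_grid_model(beads: pd.DataFrame) -> GridFit:
    """Least-squares affine fit P_x, P_y ~ (1, G_col, G_row) with residual d.

    The departure statistic d measures how far a bead's reported centre lies
    from the regular grid of its segment; values beyond ~1 px suggest the
    wrong feature is being interrogated.
    """
    if len(beads) < 10:
        raise ValueError("need >= 10 beads to fit the grid model")
    g_col = beads["grid_col"].to_numpy(dtype=float)
    g_row = beads["grid_row"].to_numpy(dtype=float)
    if np.linalg.matrix_rank(
            np.column_stack([np.ones_like(g_col), g_col, g_row])) < 3:
        raise ValueError("degenerate design: beads are collinear in grid space")
    # the row-parity regressor absorbs the hexagonal half-pitch offset, so a
    # perfect hex lattice (and anything affine in grid indices) fits exactly
    A = np.column_stack([np.ones_like(g_col), g_col, g_row, g_row % 2])
    px = beads["x"].to_numpy(dtype=float)
    py = beads["y"].to_numpy(dtype=float)
    coef_x, *_ = np.linalg.lstsq(A, px, rcond=None)
    coef_y, *_ = np.linalg.lstsq(A, py, rcond=None)
    rx = px - A @ coef_x
    ry = py - A @ coef_y
    return GridFit(coef_x=coef_x, coef_y=coef_y, residual_x=rx, residual_y=ry,
                   departure=np.hypot(rx, ry))


def flag_large_departure(fit: GridFit, threshold: float = 1.0) -> MaskSet:
    """Flag beads whose departure statistic exceeds ``threshold`` pixels."""
    ms = MaskSet(fit.departure.size)
    ms.add("large_departure", fit.departure > threshold)
    return ms


def segment_alignment_check(beads: pd.DataFrame, tol: float = 5.0) -> pd.DataFrame:
    """Cross-segment sanity check on coordinate extremes and y spacing.

    ``beads`` must carry a ``segment`` column. Segments should share extreme
    x coordinates and be equally spaced along y; a segment whose extremes
    deviate from the cross-segment median by more than ``tol`` px is flagged.
    """
    if "segment" not in beads.columns:
        raise ValueError("beads must carry a 'segment' column")
    segs = beads.groupby("segment")
    if segs.ngroups < 2:
        raise ValueError(">=2 segments required for an alignment check")
    stats = segs.agg(x_min=("x", "min"), x_max=("x", "max"),
                     y_min=("y", "min"), y_max=("y", "max")).sort_values("y_min")
    x_dev = np.maximum(
        np.abs(stats["x_min"] - stats["x_min"].median()),
        np.abs(stats["x_max"] - stats["x_max"].median()),
    )
    spacing = stats["y_min"].diff()
    med_spacing = spacing.dropna().median() if segs.ngroups > 2 else 0.0
    spacing_dev = (spacing - med_spacing).abs().fillna(0.0)
    # a displaced segment perturbs the gap on both sides; attribute to worse side
    spacing_flag = (spacing_dev > tol) | (spacing_dev.shift(-1).fillna(0.0) > tol)
    out = stats.copy()
    out["x_deviation"] = x_dev
    out["y_spacing"] = spacing
    out["flagged"] = (x_dev > tol) | spacing_flag
    return out.reset_index()


# ---------------------------------------------------------------------------
# whole-segment remapping


@dataclass
class RemapResult:
    best_shift: tuple[int, int]  # (d_col, d_row)
    profile: pd.DataFrame  # columns d_col, d_row, variance, n_types
    correlation: float | None = None


def _mean_within_type_variance(ids: np.ndarray, values: np.ndarray) -> tuple[float, int]:
    """Mean within-bead-type variance of values (types with >= 2 beads)."""
    ok = (ids >= 0) & np.isfinite(values)
    ids = ids[ok]
    values = values[ok]
    if ids.size == 0:
        return np.nan, 0
    n = np.bincount(ids)
    s = np.bincount(ids, weights=values)
    s2 = np.bincount(ids, weights=values * values)
    multi = n >= 2
    if not multi.any():
        return np.nan, 0
    nn = n[multi]
    var = (s2[multi] - s[multi] ** 2 / nn) / (nn - 1)
    return float(var.mean()), int(multi.sum())


def remap_segment(beads: pd.DataFrame, max_shift: int = 10,
                  reference_medians: pd.Series | None = None) -> RemapResult:
    """Search integer grid shifts for the bead-type annotation of a segment.

    For every candidate shift (d_col, d_row) in the square ±``max_shift``, the
    id recorded at grid node (r + d_row, c + d_col) is paired with the
    intensity observed at node (r, c), and the mean within-bead-type variance
    of log2 intensity is computed. A correctly annotated segment has its
    unique sharp minimum at (0, 0); a mis-registered one at the injected
    shift. Optionally also reports the correlation of type medians against a
    reference segment at the best shift.
    """
    rows = int(beads["grid_row"].max()) + 1
    cols = int(beads["grid_col"].max()) + 1
    ids_grid = np.full((rows, cols), -1, dtype=np.int64)
    val_grid = np.full((rows, cols), np.nan)
    rr = beads["grid_row"].to_numpy()
    cc = beads["grid_col"].to_numpy()
    ids_grid[rr, cc] = beads["bead_type_id"].to_numpy()
    intens = beads["intensity"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        log2 = np.where(intens > 0, np.log2(np.clip(intens, 1e-12, None)), np.nan)
    val_grid[rr, cc] = log2

    records = []
    best = None
    for d_col, d_row in product(range(-max_shift, max_shift + 1),
                                range(-max_shift, max_shift + 1)):
        r_lo, r_hi = max(0, -d_row), min(rows, rows - d_row)
        c_lo, c_hi = max(0, -d_col), min(cols, cols - d_col)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        vals = val_grid[r_lo:r_hi, c_lo:c_hi].ravel()
        cand = ids_grid[r_lo + d_row : r_hi + d_row,
                        c_lo + d_col : c_hi + d_col].ravel()
        var, n_types = _mean_within_type_variance(cand, vals)
        records.append((d_col, d_row, var, n_types))
        if np.isfinite(var) and (best is None or var < best[2]):
            best = (d_col, d_row, var)
    if best is None:
        raise ValueError("every candidate shift pushes all beads off the grid")
    profile = pd.DataFrame(records, columns=["d_col", "d_row", "variance", "n_types"])
    corr = None
    if reference_medians is not None:
        d_col, d_row = best[0], best[1]
        r_lo, r_hi = max(0, -d_row), min(rows, rows - d_row)
        c_lo, c_hi = max(0, -d_col), min(cols, cols - d_col)
        vals = val_grid[r_lo:r_hi, c_lo:c_hi].ravel()
        cand = ids_grid[r_lo + d_row : r_hi + d_row,
                        c_lo + d_col : c_hi + d_col].ravel()
        ok = (cand >= 0) & np.isfinite(vals)
        med = pd.Series(vals[ok]).groupby(cand[ok]).median()
        joined = pd.concat([med.rename("seg"),
                            reference_medians.rename("ref")], axis=1).dropna()
        if len(joined) >= 3:
            corr = float(joined["seg"].corr(joined["ref"]))
    return RemapResult(best_shift=(best[0], best[1]), profile=profile,
                       correlation=corr)


# ---------------------------------------------------------------------------
# between-channel shift field


@dataclass
class ChannelShiftField:
    """Per-bead red-green coordinate shift and its local-median summary."""

    beads: pd.DataFrame  # dx, dy, med_dx, med_dy, discord_x, discord_y, discordance
    slopes: dict  # linear trend of shift vs grid position


def _grid_median_filter(values: np.ndarray, size: int) -> np.ndarray:
    return ndimage.generic_filter(values, np.nanmedian, size=size, mode="nearest")


def estimate_channel_shift(green: pd.DataFrame, red: pd.DataFrame,
                           window_size: int = 11) -> ChannelShiftField:
    """Per-bead (red - green) shift, local median field, and linear trend.

    ``green`` and ``red`` are matched bead tables (same order) with grid and
    pixel coordinates. The local median over a ``window_size`` x
    ``window_size`` grid-coordinate window is robust to the sparse wrongly
    mapped beads it is meant to expose; a nonzero slope of shift versus grid
    position is the signature of channels imaged at different effective pixel
    sizes.
    """
    if len(green) != len(red):
        raise ValueError("green and red bead tables must be matched")
    rr = green["grid_row"].to_numpy()
    cc = green["grid_col"].to_numpy()
    dx = red["x"].to_numpy(dtype=float) - green["x"].to_numpy(dtype=float)
    dy = red["y"].to_numpy(dtype=float) - green["y"].to_numpy(dtype=float)
    rows = int(rr.max()) + 1
    cols = int(cc.max()) + 1
    gx = np.full((rows, cols), np.nan)
    gy = np.full((rows, cols), np.nan)
    gx[rr, cc] = dx
    gy[rr, cc] = dy
    med_x = _grid_median_filter(gx, window_size)[rr, cc]
    med_y = _grid_median_filter(gy, window_size)[rr, cc]
    disc_x = dx - med_x
    disc_y = dy - med_y
    A = np.column_stack([np.ones_like(cc, dtype=float), cc, rr])
    coef_dx, *_ = np.linalg.lstsq(A, dx, rcond=None)
    coef_dy, *_ = np.linalg.lstsq(A, dy, rcond=None)
    beads = pd.DataFrame({
        "grid_row": rr, "grid_col": cc,
        "dx": dx, "dy": dy,
        "med_dx": med_x, "med_dy": med_y,
        "discord_x": disc_x, "discord_y": disc_y,
        "discordance": np.hypot(disc_x, disc_y),
    })
    slopes = {
        "dx_intercept": float(coef_dx[0]),
        "dx_per_col": float(coef_dx[1]), "dx_per_row": float(coef_dx[2]),
        "dy_intercept": float(coef_dy[0]),
        "dy_per_col": float(coef_dy[1]), "dy_per_row": float(coef_dy[2]),
    }
    return ChannelShiftField(beads=beads, slopes=slopes)


def flag_channel_discordant(field: ChannelShiftField, threshold: float = 2.0,
                            red: pd.DataFrame | None = None,
                            collision_decimals: int = 2) -> MaskSet:
    """Flag beads discordant with the local channel shift, plus collisions.

    Beads whose shift deviates from the local median by more than
    ``threshold`` px are flagged ``channel_discordant``; beads sharing
    identical red-channel coordinates (to ``collision_decimals`` places) are
    also flagged — several green beads mapping onto one red feature is a
    known failure signature.
    """
    n = len(field.beads)
    ms = MaskSet(n)
    ms.add("channel_discordant", field.beads["discordance"].to_numpy() > threshold)
    if red is not None:
        key = pd.Series(
            zip(np.round(red["x"].to_numpy(), collision_decimals),
                np.round(red["y"].to_numpy(), collision_decimals))
        )
        dup = key.duplicated(keep=False).to_numpy()
        ms.add("channel_discordant", dup)
    return ms
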
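"""BeadArray geometry: chip layouts, hexagonal bead grids, neighbour graphs.

An Illumina BeadArray chip holds several samples; each sample is scanned as
one or more *sections*, and each section is built from physically distinct
hexagonal-lattice *segments*. Beads sit on the lattice with a centre-to-centre
pitch of roughly 6 px at scan resolution and a bead radius of 2-3 px.

Coordinate convention used throughout the package: a continuous position
``(x, y)`` lives in a frame where integer coordinates are **pixel centres**
(pixel ``(ix, iy)`` = ``image[iy, ix]`` covers the square
``[ix-0.5, ix+0.5) x [iy-0.5, iy+0.5)``). The *anchor pixel* of a bead centre
is ``(floor(x), floor(y))``; a bead whose fractional parts are zero sits
exactly on a pixel centre. Extraction windows are defined relative to the
anchor pixel (see :mod:`beadqc.extraction`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masks import MaskSet

ROW_SPACING_FACTOR = np.sqrt(3.0) / 2.0

#: sentinel bead_type_id for beads that failed Illumina's decoding step
NON_DECODED = -1

# window half-sizes used by the extraction algorithm (4x4 foreground window at
# anchor-1..anchor+2; 17x17 background window at anchor-8..anchor+8)
FG_LO, FG_HI = -1, 2
BG_HALF = 8


@dataclass(frozen=True)
class ChipLayout:
    """Geometry of one BeadArray platform.

    ``segment_cols`` x ``segment_rows`` is the hexagonal bead lattice of one
    segment; sections are made of ``segments_per_section`` such segments.
    """

    platform_name: str
    n_samples: int
    sections_per_sample: int
    segments_per_section: int
    segment_cols: int
    segment_rows: int
    bead_pitch: float = 6.0
    bead_radius: float = 2.5

    def __post_init__(self):
        for name in ("n_samples", "sections_per_sample", "segments_per_section",
                     "segment_cols", "segment_rows"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.bead_pitch > 0:
            raise ValueError("bead_pitch must be positive")
        if not 0 < self.bead_radius < self.bead_pitch / 2:
            raise ValueError("bead_radius must lie in (0, bead_pitch/2)")

    @property
    def beads_per_segment(self) -> int:
        return self.segment_cols * self.segment_rows

    def to_dict(self) -> dict:
        return {
            "platform_name": self.platform_name,
            "n_samples": self.n_samples,
            "sections_per_sample": self.sections_per_sample,
            "segments_per_section": self.segments_per_section,
            "segment_cols": self.segment_cols,
            "segment_rows": self.segment_rows,
            "bead_pitch": self.bead_pitch,
            "bead_radius": self.bead_radius,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChipLayout":
        return cls(**d)


#: built-in platform geometries: the WG6 v2 expression chip (6 samples x 2
#: sections, 9 segments of 326x397 beads) and the CNV370-duo genotyping chip
#: (2 samples x 12 sections, 4 segments of 333x443 beads)
PLATFORMS: dict[str, ChipLayout] = {
    "WG6v2": ChipLayout("WG6v2", n_samples=6, sections_per_sample=2,
                        segments_per_section=9, segment_cols=326,
                        segment_rows=397),
    "CNV370": ChipLayout("CNV370", n_samples=2, sections_per_sample=12,
                         segments_per_section=4, segment_cols=333,
                         segment_rows=443),
}


def build_layout(platform_name: str) -> ChipLayout:
    """Return the geometry of a supported platform.

    Raises ``ValueError`` naming the supported platforms for unknown names.
    """
    try:
        return PLATFORMS[platform_name]
    except KeyError:
        supported = sorted(PLATFORMS)
        raise ValueError(
            f"unknown platform {platform_name!r}; supported platforms: {supported}"
        ) from None


@dataclass
class BeadGrid:
    """Nominal hexagonal lattice of one segment.

    Beads are stored in row-major grid order; odd rows are offset +pitch/2 in
    x and row spacing is pitch*sqrt(3)/2, so every nearest-neighbour distance
    equals the pitch.
    """

    rows: int
    cols: int
    pitch: float
    grid_row: np.ndarray = field(repr=False)
    grid_col: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.rows * self.cols

    def index_of(self, r, c):
        """Row-major bead index of grid position (r, c)."""
        return np.asarray(r) * self.cols + np.asarray(c)


def nominal_positions(layout: ChipLayout, origin: tuple[float, float] = (0.0, 0.0),
                      rows: int | None = None, cols: int | None = None) -> BeadGrid:
    """Nominal sub-pixel centres of a segment's hexagonal lattice.

    Row ``r``, column ``c`` maps to
    ``(origin_x + c*pitch + (r % 2)*pitch/2, origin_y + r*pitch*sqrt(3)/2)``.
    """
    rows = layout.segment_rows if rows is None else rows
    cols = layout.segment_cols if cols is None else cols
    p = layout.bead_pitch
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr = rr.ravel()
    cc = cc.ravel()
    x = origin[0] + cc * p + (rr % 2) * (p / 2.0)
    y = origin[1] + rr * p * ROW_SPACING_FACTOR
    return BeadGrid(rows=rows, cols=cols, pitch=p, grid_row=rr, grid_col=cc,
                    x=x.astype(float), y=y.astype(float))


def hex_lattice_positions(r, c, pitch, origin=(0.0, 0.0)):
    """Lattice-formula positions for arbitrary (possibly off-grid) indices."""
    r = np.asarray(r)
    c = np.asarray(c)
    x = origin[0] + c * pitch + (np.mod(r, 2)) * (pitch / 2.0)
    y = origin[1] + r * pitch * ROW_SPACING_FACTOR
    return x, y


class NeighbourGraph:
    """Symmetric adjacency over a segment's hexagonal lattice.

    Interior beads have 6 neighbours, edge beads 2-5; stored as an (n, 6)
    int array padded with -1 plus a degree vector.
    """

    def __init__(self, neighbours: np.ndarray, degree: np.ndarray):
        self._nbrs = neighbours
        self.degree = degree
        self.n = neighbours.shape[0]

    def neighbours(self, i: int) -> np.ndarray:
        return self._nbrs[i, : self.degree[i]]

    def edges(self) -> np.ndarray:
        """(m, 2) array of undirected edges, each counted once (u < v)."""
        u = np.repeat(np.arange(self.n), 6)
        v = self._nbrs.ravel()
        keep = (v >= 0) & (u < v)
        return np.column_stack([u[keep], v[keep]])

    def adjacency(self) -> dict[int, list[int]]:
        return {i: self.neighbours(i).tolist() for i in range(self.n)}


# neighbour grid offsets (dr, dc) by row parity of the source bead
_EVEN_OFFSETS = [(0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0)]
_ODD_OFFSETS = [(0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1)]


def build_neighbour_graph(grid: BeadGrid) -> NeighbourGraph:
    """Adjacency of the hexagonal lattice: each bead's <=6 pitch-distance neighbours."""
    if grid.n == 0:
        raise ValueError("grid is empty")
    R, C = grid.rows, grid.cols
    rr = grid.grid_row
    cc = grid.grid_col
    nbrs = np.full((grid.n, 6), -1, dtype=np.int64)
    degree = np.zeros(grid.n, dtype=np.int64)
    for parity, offsets in ((0, _EVEN_OFFSETS), (1, _ODD_OFFSETS)):
        sel = rr % 2 == parity
        for dr, dc in offsets:
            r2 = rr[sel] + dr
            c2 = cc[sel] + dc
            ok = (r2 >= 0) & (r2 < R) & (c2 >= 0) & (c2 < C)
            src = np.flatnonzero(sel)[ok]
            dst = r2[ok] * C + c2[ok]
            nbrs[src, degree[src]] = dst
            degree[src] += 1
    return NeighbourGraph(nbrs, degree)


def flag_out_of_image(beads: pd.DataFrame, image_dims: tuple[int, int]) -> MaskSet:
    """Flag beads whose extraction windows extend outside the image.

    ``image_dims`` is (width, height). A bead needs its 4x4 foreground window
    *and* its 17x17 background window fully inside the image; the background
    window dominates, so the test is anchor +/- 8 within bounds.
    """
    width, height = image_dims
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    ax = np.floor(beads["x"].to_numpy()).astype(np.int64)
    ay = np.floor(beads["y"].to_numpy()).astype(np.int64)
    bad = (
        (ax - BG_HALF < 0) | (ax + BG_HALF > width - 1)
        | (ay - BG_HALF < 0) | (ay + BG_HALF > height - 1)
        | (ax + FG_LO < 0) | (ax + FG_HI > width - 1)
        | (ay + FG_LO < 0) | (ay + FG_HI > height - 1)
    )
    ms = MaskSet(len(beads))
    ms.add("out_of_image", bad)
    return ms


def scan_window_occupancy(pitch: float = 6.0, window: float = 17.0,
                          step: float = 0.1) -> int:
    """Maximum number of lattice centres inside an axis-aligned window.

    Brute-force translation scan of the hexagonal lattice over one lattice
    cell at ``step``-pixel resolution; returns the maximum count of centres
    falling inside a ``window`` x ``window`` pixel square. For pitch 6 and a
    17x17 window the answer is 12, which bounds how many beads can share a
    given background pixel.
    """
    row_h = pitch * ROW_SPACING_FACTOR
    # lattice patch comfortably covering the window for any translation
    n_rows = int(np.ceil(window / row_h)) + 3
    n_cols = int(np.ceil(window / pitch)) + 3
    rr, cc = np.meshgrid(np.arange(-1, n_rows), np.arange(-1, n_cols), indexing="ij")
    x, y = hex_lattice_positions(rr.ravel(), cc.ravel(), pitch)
    tx = np.arange(0.0, pitch, step)
    ty = np.arange(0.0, 2 * row_h, step)  # lattice repeats every two rows
    best = 0
    for t in tx:
        # window spans [t, t+window] in x; vectorised over the y translations
        in_x = (x >= t) & (x <= t + window)
        ys = y[in_x]
        if ys.size == 0:
            continue
        inside = (ys[None, :] >= ty[:, None]) & (ys[None, :] <= ty[:, None] + window)
        counts = inside.sum(axis=1)
        best = max(best, int(counts.max()))
    return best
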
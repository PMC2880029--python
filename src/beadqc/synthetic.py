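"""Ground-truthed synthetic BeadArray sections.

Generates everything the raw data of a real scan would contain — a rendered
16-bit section image per channel, the bead-level text table of decoded beads,
a locs-style binary of *all* bead positions, and the chip-layout JSON — plus a
truth manifest recording exactly which beads and pixels every injected
artefact touched.

The emulated physics is deliberately simple: beads sit on a hexagonal lattice,
each bead-type has a log2-scale intensity level, replicates scatter around it,
and each bead is rendered as a projected-sphere spot added to a Gaussian
background floor. Injectable artefacts cover the phenomena seen on real
arrays: compact clusters of non-decoded beads with bright halos, saturating
beads, abnormally low pixels, whole-segment grid shifts (which scramble the
bead-type annotation), per-bead registration jitter, and spatially varying
between-channel shifts on two-colour sections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .array_model import (
    NON_DECODED,
    BeadGrid,
    ChipLayout,
    NeighbourGraph,
    build_neighbour_graph,
    hex_lattice_positions,
    nominal_positions,
)

ARTIFACT_KINDS = (
    "nondecoded_cluster",
    "bright_bead",
    "low_pixel",
    "segment_shift",
    "bead_jitter",
    "channel_shift_gradient",
    "id_scramble",
)


@dataclass(frozen=True)
class ArtifactSpec:
    """One artefact to inject; ``params`` are kind-specific."""

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"kind must be one of {ARTIFACT_KINDS}")


@dataclass
class ArtifactTruth:
    """Exact beads/pixels affected by one injected artefact."""

    kind: str
    beads: np.ndarray  # bead indices affected
    pixels: np.ndarray  # (k, 2) array of (row, col) pixels, possibly empty
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "beads": np.asarray(self.beads).astype(int).tolist(),
            "pixels": np.asarray(self.pixels).astype(int).reshape(-1, 2).tolist(),
            "details": _jsonable(self.details),
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic section.

    Defaults describe a small but realistic segment: pitch-6 hexagonal
    lattice, ~20 replicates per bead-type, a ~2% decode-failure rate, bead-
    level log2 intensities with between-type spread 1.5 and within-type
    replicate noise 0.2, and a flat Gaussian background floor (level 500,
    sd 10) typical of the low-variability background of real scans.
    """

    seed: int = 0
    rows: int = 60
    cols: int = 60
    pitch: float = 6.0
    bead_radius: float = 2.5
    n_bead_types: int = 180
    non_decode_rate: float = 0.02
    type_log2_mean: float = 10.0
    type_log2_sd: float = 1.5
    within_type_sd: float = 0.2
    nondecoded_log2_mean: float = 7.0
    nondecoded_log2_sd: float = 0.5
    background_level: float = 500.0
    background_sd: float = 10.0
    origin: tuple[float, float] = (20.0, 20.0)
    margin: int = 20
    peak_brightness: float = 65535.0
    render_supersample: int = 8
    two_channel: bool = False
    channel_base_shift: tuple[float, float] = (10.0, 0.0)
    artifacts: tuple[ArtifactSpec, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.non_decode_rate <= 1.0:
            raise ValueError("non_decode_rate must be a probability")
        for name in ("type_log2_sd", "within_type_sd", "background_sd",
                     "nondecoded_log2_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_bead_types < 1:
            raise ValueError("n_bead_types must be >= 1")
        if not 0 < self.peak_brightness <= 65535:
            raise ValueError("peak_brightness must lie in (0, 65535]")

    def layout(self) -> ChipLayout:
        """Single-segment custom layout matching this configuration."""
        return ChipLayout("synthetic", n_samples=1, sections_per_sample=1,
                          segments_per_section=1, segment_cols=self.cols,
                          segment_rows=self.rows, bead_pitch=self.pitch,
                          bead_radius=self.bead_radius)


def assign_bead_types(grid: BeadGrid, config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Random uniform i.i.d. bead-type assignment with decode failures.

    Returns one row per grid position with the type id (-1 for the
    ``non_decode_rate`` fraction that failed decoding), grid coordinates and
    nominal sub-pixel centres. Reproducible for a fixed config seed.
    """
    rng = rng or np.random.default_rng(config.seed)
    ids = rng.integers(0, config.n_bead_types, size=grid.n)
    failed = rng.random(grid.n) < config.non_decode_rate
    ids[failed] = NON_DECODED
    return pd.DataFrame({
        "bead_type_id": ids,
        "grid_row": grid.grid_row,
        "grid_col": grid.grid_col,
        "x": grid.x.copy(),
        "y": grid.y.copy(),
    })


def draw_true_intensities(beads: pd.DataFrame, config: SimulationConfig,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Attach per-bead true log2 intensities (type level + replicate noise).

    Non-decoded beads still fluoresce, at a low level independent of any type:
    decode failure says nothing about hybridization brightness.
    """
    out = beads.copy()
    type_level = config.type_log2_mean + config.type_log2_sd * rng.standard_normal(
        config.n_bead_types
    )
    ids = out["bead_type_id"].to_numpy()
    log2 = np.empty(len(out))
    dec = ids >= 0
    log2[dec] = type_level[ids[dec]] + config.within_type_sd * rng.standard_normal(
        int(dec.sum())
    )
    log2[~dec] = config.nondecoded_log2_mean + config.nondecoded_log2_sd * (
        rng.standard_normal(int((~dec).sum()))
    )
    level = np.full(len(out), np.nan)
    level[dec] = type_level[ids[dec]]
    out["type_log2_level"] = level
    out["true_log2"] = log2
    out["true_intensity"] = np.minimum(2.0 ** log2, config.peak_brightness)
    return out


def _render_spots(image: np.ndarray, xs, ys, amplitudes, radius,
                  supersample: int = 8, chunk: int = 2048) -> None:
    """Add projected-sphere spots (flux density amp*sqrt(r^2-d^2)/r) in place.

    The amplitude is the peak flux density, so the brightest pixel of an
    isolated spot is roughly ``amp``. Integration is midpoint quadrature on a
    ``supersample``-fold sub-grid per pixel.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    h, w = image.shape
    half = int(np.ceil(radius + 1.0))
    size = 2 * half + 1
    S = supersample
    sub = (np.arange(size * S) + 0.5) / S - 0.5 - half  # offsets from centre pixel
    for start in range(0, xs.size, chunk):
        sl = slice(start, min(start + chunk, xs.size))
        cx = xs[sl]
        cy = ys[sl]
        amp = amplitudes[sl]
        ax = np.rint(cx).astype(np.int64)
        ay = np.rint(cy).astype(np.int64)
        fx = cx - ax
        fy = cy - ay
        dx = sub[None, :] - fx[:, None]  # (n, size*S)
        dy = sub[None, :] - fy[:, None]
        d2 = dx[:, None, :] ** 2 + dy[:, :, None] ** 2  # (n, size*S, size*S)
        prof = np.sqrt(np.clip(radius**2 - d2, 0.0, None)) / radius
        n = prof.shape[0]
        vals = prof.reshape(n, size, S, size, S).sum(axis=(2, 4)) / (S * S)
        vals *= amp[:, None, None]
        offs = np.arange(-half, half + 1)
        rows, cols = np.broadcast_arrays(ay[:, None, None] + offs[None, :, None],
                                         ax[:, None, None] + offs[None, None, :])
        ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        np.add.at(image, (rows[ok], cols[ok]), vals[ok])


def render_section_image(beads: pd.DataFrame, intensities,
                         config: SimulationConfig,
                         rng: np.random.Generator | None = None,
                         shape: tuple[int, int] | None = None,
                         noise: bool = True) -> np.ndarray:
    """Render one section/channel as a float image (clip/round via finalize_image).

    Each bead becomes a projected-sphere spot whose peak flux density equals
    its intensity, added onto a Gaussian background floor clipped at 0.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    xs = beads["x"].to_numpy(dtype=float)
    ys = beads["y"].to_numpy(dtype=float)
    if shape is None:
        width = int(np.ceil(xs.max() if xs.size else 0)) + config.margin + 1
        height = int(np.ceil(ys.max() if ys.size else 0)) + config.margin + 1
        shape = (height, width)
    h, w = shape
    r = config.bead_radius
    if xs.size and (
        xs.min() - r < 0 or xs.max() + r > w - 1 or ys.min() - r < 0 or ys.max() + r > h - 1
    ):
        raise ValueError("bead centre outside image margin")
    if noise and config.background_sd > 0:
        image = config.background_level + config.background_sd * rng.standard_normal(shape)
        np.clip(image, 0.0, None, out=image)
    else:
        image = np.full(shape, float(config.background_level))
    amps = np.asarray(intensities, dtype=float)
    _render_spots(image, xs, ys, amps, r, config.render_supersample)
    return image


def finalize_image(image: np.ndarray) -> np.ndarray:
    """Round and clip a rendered float image to uint16 pixel values."""
    return np.clip(np.rint(image), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# artefact injection


def _hex_disc(graph: NeighbourGraph, seed_bead: int, size: int) -> np.ndarray:
    """Compact connected disc of >= size beads grown by BFS from a seed."""
    from collections import deque

    seen = {int(seed_bead)}
    order = [int(seed_bead)]
    q = deque([int(seed_bead)])
    while q and len(order) < size:
        b = q.popleft()
        for nb in graph.neighbours(b):
            nb = int(nb)
            if nb not in seen:
                seen.add(nb)
                order.append(nb)
                q.append(nb)
                if len(order) >= size:
                    break
    return np.array(order[:size], dtype=np.int64)


def _rings(graph: NeighbourGraph, members: np.ndarray, rings: int) -> np.ndarray:
    """Beads within ``rings`` graph hops of ``members`` (members excluded)."""
    inside = np.zeros(graph.n, dtype=bool)
    inside[members] = True
    frontier = set(int(m) for m in members)
    collected: set[int] = set()
    for _ in range(rings):
        nxt: set[int] = set()
        for b in frontier:
            for nb in graph.neighbours(b):
                nb = int(nb)
                if not inside[nb] and nb not in collected:
                    collected.add(nb)
                    nxt.add(nb)
        frontier = nxt
    return np.array(sorted(collected), dtype=np.int64)


def inject_artifacts(image: np.ndarray | None, beads: pd.DataFrame,
                     specs, config: SimulationConfig,
                     graph: NeighbourGraph | None = None,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[np.ndarray | None, pd.DataFrame, list[ArtifactTruth]]:
    """Apply artefact specs to a rendered section, returning full truth.

    Bead-level effects (halo brightening, bright beads) both update the truth
    intensities and add the corresponding extra flux to the image; coordinate
    effects (segment shift, jitter, channel gradients) only alter the
    *recorded* centres/ids, exactly as a registration failure would.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    beads = beads.copy()
    image = None if image is None else np.asarray(image, dtype=float).copy()
    truths: list[ArtifactTruth] = []
    claimed: dict[int, str] = {}

    def claim(indices, kind):
        for b in np.atleast_1d(indices):
            b = int(b)
            prev = claimed.get(b)
            if prev is not None and {prev, kind} <= {"nondecoded_cluster", "bright_bead"}:
                raise ValueError(
                    f"conflicting artefact specs: bead {b} is both {prev} and {kind}"
                )
            claimed[b] = kind

    for spec in specs:
        p = dict(spec.params)
        kind = spec.kind
        if kind == "nondecoded_cluster":
            if graph is None:
                raise ValueError("nondecoded_cluster requires the neighbour graph")
            size = int(p.get("size", 80))
            seed_bead = p.get("seed_bead")
            if seed_bead is None:
                interior = np.flatnonzero(graph.degree == 6)
                seed_bead = int(rng.choice(interior))
            members = _hex_disc(graph, int(seed_bead), size)
            claim(members, kind)
            beads.loc[beads.index[members], "bead_type_id"] = NON_DECODED
            rings = int(p.get("halo_rings", 2))
            factor = float(p.get("halo_factor", 4.0))
            halo = _rings(graph, members, rings)
            halo = halo[beads["bead_type_id"].to_numpy()[halo] >= 0]
            if image is not None and halo.size:
                _render_spots(
                    image,
                    beads["x"].to_numpy()[halo],
                    beads["y"].to_numpy()[halo],
                    (factor - 1.0) * beads["true_intensity"].to_numpy()[halo],
                    config.bead_radius, config.render_supersample,
                )
            if "true_intensity" in beads:
                col = beads.columns.get_loc("true_intensity")
                beads.iloc[halo, col] = beads.iloc[halo, col] * factor
                beads.loc[beads.index[halo], "true_log2"] = np.log2(
                    beads["true_intensity"].to_numpy()[halo]
                )
            truths.append(ArtifactTruth(kind, members, np.empty((0, 2), int),
                                        {"halo": halo, "seed_bead": int(seed_bead),
                                         "halo_factor": factor}))
        elif kind == "bright_bead":
            bead = p.get("bead")
            if bead is None:
                bead = int(rng.integers(0, len(beads)))
            bead = int(bead)
            claim([bead], kind)
            brightness = float(p.get("brightness", 60000.0))
            radius = float(p.get("radius", 2.0 * config.bead_radius))
            if image is not None:
                _render_spots(image, [beads["x"].iloc[bead]], [beads["y"].iloc[bead]],
                              [brightness], radius, config.render_supersample)
            if "true_intensity" in beads:
                beads.iloc[bead, beads.columns.get_loc("true_intensity")] += brightness
            truths.append(ArtifactTruth(kind, np.array([bead]), np.empty((0, 2), int),
                                        {"brightness": brightness, "radius": radius}))
        elif kind == "low_pixel":
            if image is None:
                raise ValueError("low_pixel requires an image")
            value = float(p.get("value", 5.0))
            pixels = p.get("pixels")
            if pixels is None:
                near = int(p.get("near_bead", rng.integers(0, len(beads))))
                px = int(np.rint(beads["x"].iloc[near])) + int(p.get("dx", 4))
                py = int(np.rint(beads["y"].iloc[near])) + int(p.get("dy", 0))
                pixels = [(py, px)]
            pixels = np.asarray(pixels, dtype=int).reshape(-1, 2)
            for py, px in pixels:
                image[py, px] = value
            truths.append(ArtifactTruth(kind, np.empty(0, int), pixels,
                                        {"value": value}))
        elif kind in ("segment_shift", "id_scramble"):
            dcol = int(p.get("dcol", 0))
            drow = int(p.get("drow", 0))
            rr = beads["grid_row"].to_numpy()
            cc = beads["grid_col"].to_numpy()
            r2 = rr + drow
            c2 = cc + dcol
            rows = int(rr.max()) + 1
            cols = int(cc.max()) + 1
            if kind == "segment_shift":
                # recorded centres displaced by (dcol, drow) lattice steps:
                # every recorded id now points at the bead that many steps away
                origin_x = beads["x"].iloc[0] - hex_lattice_positions(
                    rr[0], cc[0], config.pitch)[0]
                origin_y = beads["y"].iloc[0] - hex_lattice_positions(
                    rr[0], cc[0], config.pitch)[1]
                nx, ny = hex_lattice_positions(r2, c2, config.pitch,
                                               (origin_x, origin_y))
                beads["x"] = nx
                beads["y"] = ny
            else:
                # same scramble expressed on the annotation: the id recorded at
                # a node is the true id of the node (dcol, drow) steps back
                inside = (r2 >= 0) & (r2 < rows) & (c2 >= 0) & (c2 < cols)
                if not inside.any():
                    raise ValueError("shift pushes every bead off the grid")
                ids = beads["bead_type_id"].to_numpy().copy()
                new_ids = np.full_like(ids, NON_DECODED)
                dst = r2[inside] * cols + c2[inside]
                new_ids[dst] = ids[inside]
                beads["bead_type_id"] = new_ids
            mapping = np.column_stack([np.arange(len(beads)), r2 * cols + c2])
            truths.append(ArtifactTruth(kind, np.arange(len(beads)),
                                        np.empty((0, 2), int),
                                        {"dcol": dcol, "drow": drow,
                                         "maps_to": mapping[:, 1]}))
        elif kind == "bead_jitter":
            indices = p.get("beads")
            n = int(p.get("n", 7))
            if indices is None:
                indices = rng.choice(len(beads), size=n, replace=False)
            indices = np.asarray(indices, dtype=int)
            mag_lo = float(p.get("magnitude_lo", 2.5))
            mag_hi = float(p.get("magnitude_hi", 4.0))
            mags = rng.uniform(mag_lo, mag_hi, size=indices.size)
            theta = rng.uniform(0, 2 * np.pi, size=indices.size)
            cols_xy = p.get("channel_suffix", "")
            xcol, ycol = "x" + cols_xy, "y" + cols_xy
            beads.loc[beads.index[indices], xcol] = (
                beads[xcol].to_numpy()[indices] + mags * np.cos(theta))
            beads.loc[beads.index[indices], ycol] = (
                beads[ycol].to_numpy()[indices] + mags * np.sin(theta))
            truths.append(ArtifactTruth(kind, indices, np.empty((0, 2), int),
                                        {"magnitudes": mags, "channel": cols_xy}))
        elif kind == "channel_shift_gradient":
            if "x_red" not in beads:
                raise ValueError("channel_shift_gradient requires two-channel beads "
                                 "(x_red/y_red columns)")
            base = p.get("base", config.channel_base_shift)
            slope_col = float(p.get("slope_x_per_col", 0.0))
            slope_row = float(p.get("slope_y_per_row", 0.0))
            cc = beads["grid_col"].to_numpy()
            rr = beads["grid_row"].to_numpy()
            beads["x_red"] = beads["x"] + base[0] + slope_col * cc
            beads["y_red"] = beads["y"] + base[1] + slope_row * rr
            truths.append(ArtifactTruth(kind, np.arange(len(beads)),
                                        np.empty((0, 2), int),
                                        {"base": list(base),
                                         "slope_x_per_col": slope_col,
                                         "slope_y_per_row": slope_row}))
        else:  # pragma: no cover - guarded by ArtifactSpec
            raise ValueError(f"unknown artefact kind {kind!r}")
    return image, beads, truths


# ---------------------------------------------------------------------------
# full-section orchestration


@dataclass
class SectionData:
    """Everything known about one simulated section."""

    config: SimulationConfig
    grid: BeadGrid
    graph: NeighbourGraph
    beads: pd.DataFrame
    image: np.ndarray | None
    image_red: np.ndarray | None
    truth: list[ArtifactTruth]


def simulate_section(config: SimulationConfig, render: bool = True) -> SectionData:
    """Generate one synthetic section under ``config``.

    The single RNG stream seeded from ``config.seed`` drives assignment,
    intensities, background noise and artefact randomness, so a fixed config
    is fully reproducible.
    """
    rng = np.random.default_rng(config.seed)
    layout = config.layout()
    grid = nominal_positions(layout, config.origin, rows=config.rows,
                             cols=config.cols)
    graph = build_neighbour_graph(grid)
    beads = assign_bead_types(grid, config, rng)
    beads = draw_true_intensities(beads, config, rng)
    if config.two_channel:
        beads["x_red"] = beads["x"] + config.channel_base_shift[0]
        beads["y_red"] = beads["y"] + config.channel_base_shift[1]
    image = None
    if render:
        image = render_section_image(beads, beads["true_intensity"], config, rng)
    image, beads, truth = inject_artifacts(image, beads, config.artifacts,
                                           config, graph, rng)
    image_red = None
    if render and config.two_channel:
        red = beads.copy()
        shift = config.channel_base_shift
        red["x"] = beads["x_red"] if "x_red" in beads else beads["x"] + shift[0]
        red["y"] = beads["y_red"] if "y_red" in beads else beads["y"] + shift[1]
        # same dimensions as the green image; the base shift must fit the margin
        image_red = render_section_image(red, beads["true_intensity"], config,
                                         rng, shape=image.shape)
    return SectionData(config=config, grid=grid, graph=graph, beads=beads,
                       image=None if image is None else finalize_image(image),
                       image_red=None if image_red is None else finalize_image(image_red),
                       truth=truth)


def generate_dataset(config: SimulationConfig, out_dir) -> dict:
    """Write a full synthetic data set to ``out_dir`` and return its manifest.

    Files: section image TIFF(s), bead-level text table(s) of decoded beads,
    locs binary of all positions, layout JSON and truth JSON. Output is
    byte-deterministic for a fixed config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    section = simulate_section(config)
    beads = section.beads
    layout = config.layout()

    paths = {}

    def _write(name, writer, *args):
        path = out_dir / name
        try:
            writer(path, *args)
        except OSError as exc:  # surface the failing path
            raise OSError(f"failed writing {path}: {exc}") from exc
        paths[name] = str(path)
        return path

    _write("section_Grn.tif", bio.write_tiff, section.image)
    decoded = beads[beads["bead_type_id"] >= 0]
    green = decoded[["bead_type_id", "x", "y"]].copy()
    green["intensity"] = decoded["true_intensity"]
    _write("beadlevel_Grn.txt", bio.write_beadlevel, green)
    if config.two_channel:
        _write("section_Red.tif", bio.write_tiff, section.image_red)
        red = decoded[["bead_type_id"]].copy()
        red["x"] = decoded["x_red"] if "x_red" in decoded else decoded["x"]
        red["y"] = decoded["y_red"] if "y_red" in decoded else decoded["y"]
        red["intensity"] = decoded["true_intensity"]
        _write("beadlevel_Red.txt", bio.write_beadlevel, red)
    xy = np.column_stack([beads["x"].to_numpy(), beads["y"].to_numpy()])
    _write("section.locs", bio.write_locs, xy)
    _write("layout.json", bio.write_layout_json, layout)
    truth_doc = {
        "config": {**{k: _jsonable(v) for k, v in vars(config).items()
                      if k != "artifacts"},
                   "artifacts": [{"kind": s.kind, "params": _jsonable(s.params)}
                                 for s in config.artifacts]},
        "artifacts": [t.to_dict() for t in section.truth],
        "beads": {
            "bead_type_id": beads["bead_type_id"].astype(int).tolist(),
            "true_log2": np.round(beads["true_log2"].to_numpy(), 6).tolist(),
        },
    }
    path = out_dir / "truth.json"
    path.write_text(json.dumps(truth_doc, sort_keys=True, indent=0) + "\n")
    paths["truth.json"] = str(path)
    manifest = {
        "n_beads": int(len(beads)),
        "n_decoded": int((beads["bead_type_id"] >= 0).sum()),
        "image_shape": list(section.image.shape),
        "two_channel": config.two_channel,
        "files": paths,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return manifest


def config_with(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """Convenience: dataclasses.replace with artefact list coercion."""
    if "artifacts" in kwargs:
        kwargs["artifacts"] = tuple(kwargs["artifacts"])
    return replace(config, **kwargs)
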
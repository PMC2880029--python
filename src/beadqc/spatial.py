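"""Local spatial phenomena: non-decoded clusters, encroaching bright beads,
abnormally low pixels, neighbouring twins, and the fractional-coordinate
intensity association.

Every detector returns either a diagnostic record or a :class:`MaskSet`
keyed by reason, so summarization can exclude affected beads while keeping
full provenance of why each bead was dropped.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .array_model import NON_DECODED, BG_HALF, FG_HI, FG_LO, NeighbourGraph
from .masks import MaskSet


# ---------------------------------------------------------------------------
# non-decoded clusters


@dataclass
class Cluster:
    """One connected patch of non-decoded beads."""

    members: np.ndarray  # non-decoded bead indices, sorted
    seeds: np.ndarray  # members with six non-decoded neighbours
    halo: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


def find_nondecoded_clusters(graph: NeighbourGraph, decoded_flags: np.ndarray,
                             min_size: int = 50) -> list[Cluster]:
    """Seeded invasion process identifying compact non-decoded patches.

    A genuine cluster always contains at least one non-decoded bead whose six
    neighbours are all non-decoded; each such seed starts a flood fill over
    neighbouring non-decoded beads, and maximal networks of at least
    ``min_size`` beads are reported. Randomly scattered decode failures have
    no seed and are ignored.
    """
    decoded = np.asarray(decoded_flags, dtype=bool)
    if decoded.size != graph.n:
        raise ValueError("decoded_flags length must match the graph")
    nondec = ~decoded
    is_seed = np.zeros(graph.n, dtype=bool)
    for b in np.flatnonzero(nondec):
        if graph.degree[b] == 6 and np.all(nondec[graph.neighbours(b)]):
            is_seed[b] = True
    visited = np.zeros(graph.n, dtype=bool)
    clusters: list[Cluster] = []
    for seed in np.flatnonzero(is_seed):
        if visited[seed]:
            continue
        comp = []
        q = deque([int(seed)])
        visited[seed] = True
        while q:
            b = q.popleft()
            comp.append(b)
            for nb in graph.neighbours(b):
                nb = int(nb)
                if nondec[nb] and not visited[nb]:
                    visited[nb] = True
                    q.append(nb)
        if len(comp) >= min_size:
            comp_arr = np.array(sorted(comp), dtype=np.int64)
            clusters.append(Cluster(members=comp_arr,
                                    seeds=comp_arr[is_seed[comp_arr]]))
    return clusters


def expand_cluster(clusters: list[Cluster], graph: NeighbourGraph,
                   decoded_flags: np.ndarray, rings: int = 2) -> list[Cluster]:
    """Attach the halo: decoded beads within ``rings`` graph hops of members."""
    decoded = np.asarray(decoded_flags, dtype=bool)
    out = []
    for cl in clusters:
        inside = np.zeros(graph.n, dtype=bool)
        inside[cl.members] = True
        frontier = set(int(m) for m in cl.members)
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
        halo = np.array(sorted(h for h in collected if decoded[h]), dtype=np.int64)
        out.append(Cluster(members=cl.members, seeds=cl.seeds, halo=halo))
    return out


def flag_cluster_halo(clusters: list[Cluster], n_beads: int) -> MaskSet:
    """MaskSet with cluster members and halo beads flagged ``near_cluster``."""
    ms = MaskSet(n_beads)
    for cl in clusters:
        ms.add("near_cluster", cl.members)
        ms.add("near_cluster", cl.halo)
    return ms


# ---------------------------------------------------------------------------
# bright encroaching features


@dataclass
class BrightFeature:
    """A bright, compact image feature mapped to its nearest bead."""

    mass: int
    centroid: tuple[float, float]  # (x, y)
    circularity: float
    bead_index: int | None = None


def detect_bright_features(image: np.ndarray, intensity_threshold: float | None = None,
                           min_mass: int = 40, min_circularity: float = 0.8,
                           bead_centres: np.ndarray | None = None) -> list[BrightFeature]:
    """Segment bright features and keep large, highly circular ones.

    Thresholding (default mean + 5 sd) and connected-component labelling find
    candidate features; those of mass >= ``min_mass`` pixels and circularity
    4*pi*A/P^2 >= ``min_circularity`` are kept — the signature of a
    saturatingly bright bead rather than a streak or scratch. Feature
    centroids map to the nearest bead centre when centres are supplied.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image is empty")
    if intensity_threshold is None:
        intensity_threshold = float(image.mean() + 5.0 * image.std())
    labels = measure.label(image > intensity_threshold, connectivity=2)
    feats: list[BrightFeature] = []
    tree = None
    if bead_centres is not None and len(bead_centres):
        from scipy.spatial import cKDTree

        tree = cKDTree(np.asarray(bead_centres, dtype=float))
    for region in measure.regionprops(labels):
        if region.area < min_mass:
            continue
        perim = region.perimeter
        circ = 1.0 if perim == 0 else min(1.0, 4.0 * np.pi * region.area / perim**2)
        if circ < min_circularity:
            continue
        cy, cx = region.centroid
        bead = None
        if tree is not None:
            bead = int(tree.query([cx, cy])[1])
        feats.append(BrightFeature(mass=int(region.area), centroid=(float(cx), float(cy)),
                                   circularity=float(circ), bead_index=bead))
    return feats


def flag_bright_neighbours(features: list[BrightFeature],
                           graph: NeighbourGraph) -> MaskSet:
    """Flag bright beads and, separately, all their lattice neighbours."""
    ms = MaskSet(graph.n)
    for feat in features:
        if feat.bead_index is None:
            continue
        ms.add("bright_bead", [feat.bead_index])
        ms.add("bright_neighbour", graph.neighbours(feat.bead_index))
    return ms


# ---------------------------------------------------------------------------
# abnormally low pixels


def modal_background(image: np.ndarray) -> int:
    """Mode of the lower half of the intensity distribution."""
    image = np.asarray(image)
    lower = image[image <= np.median(image)].astype(np.int64).ravel()
    if lower.size == 0:
        raise ValueError("image is empty")
    return int(np.bincount(lower).argmax())


def detect_low_pixels(image: np.ndarray, low_fraction: float = 0.5) -> np.ndarray:
    """(k, 2) array of (row, col) pixels far below the modal background.

    A pixel counts as abnormally low when its value is below ``low_fraction``
    times the modal background — the scanner artefact seen next to
    near-saturated beads.
    """
    if not 0 < low_fraction <= 1:
        raise ValueError("low_fraction must lie in (0, 1]")
    thr = low_fraction * modal_background(image)
    return np.argwhere(np.asarray(image) < thr)


def flag_low_pixel_beads(pixels: np.ndarray, beads: pd.DataFrame,
                         image: np.ndarray) -> MaskSet:
    """Flag beads whose background is corrupted by a low pixel.

    A bead is affected when a detected low pixel falls inside its 17x17
    background window *and* ranks among that window's five smallest values —
    only then does it enter the mean-of-five background and inflate the final
    intensity.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    ms = MaskSet(len(beads))
    if len(pixels) == 0:
        return ms
    ax = np.floor(beads["x"].to_numpy(dtype=float)).astype(int)
    ay = np.floor(beads["y"].to_numpy(dtype=float)).astype(int)
    flagged = np.zeros(len(beads), dtype=bool)
    for py, px in np.asarray(pixels, dtype=int):
        near = (np.abs(ax - px) <= BG_HALF) & (np.abs(ay - py) <= BG_HALF)
        for i in np.flatnonzero(near):
            r0, r1 = ay[i] - BG_HALF, ay[i] + BG_HALF + 1
            c0, c1 = ax[i] - BG_HALF, ax[i] + BG_HALF + 1
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                continue
            win = image[r0:r1, c0:c1].ravel()
            fifth = np.partition(win, 4)[4]
            if image[py, px] <= fifth:
                flagged[i] = True
    ms.add("low_pixel", flagged)
    return ms


# ---------------------------------------------------------------------------
# neighbouring twins


def count_twin_pairs(graph: NeighbourGraph, bead_type_ids: np.ndarray) -> int:
    """Edges whose two (decoded) endpoints share a bead-type, counted once."""
    ids = np.asarray(bead_type_ids)
    e = graph.edges()
    a, b = ids[e[:, 0]], ids[e[:, 1]]
    return int(np.sum((a >= 0) & (a == b)))


def expected_twin_pairs(n_beads: int, mean_degree: float, n_types: int) -> float:
    """Expected twin pairs under i.i.d.-uniform type assignment.

    ``n_beads * mean_degree / 2`` edges, each a twin pair with probability
    1/``n_types``: the idealized-array calculation (a million beads of 50,000
    types with six neighbours each gives 60 pairs).
    """
    if n_types == 0:
        raise ValueError("n_types must be >= 1")
    return (n_beads * mean_degree / 2.0) / n_types


def permutation_null_twins(graph: NeighbourGraph, bead_type_ids: np.ndarray,
                           n_perm: int = 199, seed: int = 0
                           ) -> tuple[np.ndarray, float, int]:
    """Permutation null for the twin-pair count.

    Identities of successfully decoded beads are permuted uniformly over the
    decoded positions (non-decoded positions stay fixed), preserving the
    multiset of type counts and the neighbour structure. Returns the null
    distribution, the one-sided p-value (1 + #{null >= obs}) / (n_perm + 1),
    and the observed count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids = np.asarray(bead_type_ids).copy()
    obs = count_twin_pairs(graph, ids)
    decoded_pos = np.flatnonzero(ids != NON_DECODED)
    decoded_ids = ids[decoded_pos]
    rng = np.random.default_rng(seed)
    e = graph.edges()
    null = np.empty(n_perm, dtype=np.int64)
    perm_ids = ids.copy()
    for i in range(n_perm):
        perm_ids[decoded_pos] = decoded_ids[rng.permutation(decoded_pos.size)]
        a, b = perm_ids[e[:, 0]], perm_ids[e[:, 1]]
        null[i] = np.sum((a >= 0) & (a == b))
    p = (1.0 + np.sum(null >= obs)) / (n_perm + 1.0)
    return null, float(p), obs


def flag_twins(graph: NeighbourGraph, bead_type_ids: np.ndarray) -> MaskSet:
    """Informational flag for beads neighbouring a bead of the same type."""
    ids = np.asarray(bead_type_ids)
    e = graph.edges()
    same = (ids[e[:, 0]] >= 0) & (ids[e[:, 0]] == ids[e[:, 1]])
    ms = MaskSet(graph.n)
    ms.add("twin", e[same].ravel())
    return ms


# ---------------------------------------------------------------------------
# fractional-coordinate intensity association


def fractional_intensity_map(beads: pd.DataFrame, bins: int = 100,
                             mode: str = "log_intensity"
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Mean (residual) log2 intensity binned by fractional centre coordinates.

    A theoretical pixel is broken into ``bins`` x ``bins`` sub-bins; each
    bead's fractional centre coordinates select a bin and the bin mean of
    log2 intensity (or within-type residual log2 intensity for
    ``mode='residual_log_intensity'``) is returned along with the bin counts.
    Empty bins are NaN. Any dependence of the map on position reveals the
    location/intensity coupling of the extraction pipeline.
    """
    if mode not in ("log_intensity", "residual_log_intensity"):
        raise ValueError("mode must be 'log_intensity' or 'residual_log_intensity'")
    x = beads["x"].to_numpy(dtype=float)
    y = beads["y"].to_numpy(dtype=float)
    intens = beads["intensity"].to_numpy(dtype=float)
    ok = intens > 0
    vals = np.full(len(beads), np.nan)
    vals[ok] = np.log2(intens[ok])
    if mode == "residual_log_intensity":
        med = pd.Series(vals[ok]).groupby(
            beads["bead_type_id"].to_numpy()[ok]).transform("median")
        vals[ok] = vals[ok] - med.to_numpy()
    ok &= np.isfinite(vals)
    fx = np.mod(x[ok], 1.0)
    fy = np.mod(y[ok], 1.0)
    bx = np.minimum((fx * bins).astype(int), bins - 1)
    by = np.minimum((fy * bins).astype(int), bins - 1)
    flat = by * bins + bx
    counts = np.bincount(flat, minlength=bins * bins).reshape(bins, bins)
    sums = np.bincount(flat, weights=vals[ok], minlength=bins * bins).reshape(bins, bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts
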
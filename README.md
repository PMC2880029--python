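# beadqc

Raw-data processing and spatial quality control for Illumina BeadArray
sections: feature-intensity extraction, registration diagnostics, artefact
detection/masking, and a ground-truthed synthetic section generator.

## Why

Illumina BeadArrays are assembled by *random* sampling: each silica bead
carries one probe ("bead-type") and lands at a random position on a
hexagonal lattice (pitch ≈ 6 px at scan resolution, bead radius 2–3 px). The
platform therefore has to find every bead twice — once during decoding, once
when the hybridized array is scanned — before an intensity can be extracted.
Each of those steps can fail in ways that are invisible in the summarized
data a scanner normally returns: whole segments mis-registered (scrambling
every bead-type annotation), individual centres snapping to the wrong
feature, bright beads bleeding into their neighbours' extraction windows,
clusters of non-decoded beads surrounded by halos of inflated intensity,
single pixels far below the modal background corrupting the local background
estimate, and channels of two-colour arrays imaged at different effective
pixel sizes.

`beadqc` implements the extraction pipeline plus diagnostics for each of
these phenomena, working from the raw section files: the 16-bit grayscale
TIFF, the bead-level text table of decoded beads, and a binary locs file of
*all* centres including non-decoded beads.

## The core computations

**Extraction.** The image is sharpened with a unit-sum centre-surround
filter; the *foreground* is a weighted average over the 4×4 pixel window
about the bead centre, with centre 2×2 weights maximal and outer weights
`(1−f, 1, 1, f)` driven by the fractional part *f* of the centre coordinate;
the *background* is the mean of the five lowest pixels in the 17×17 window
of the raw image (robust alternatives: median-of-five, rank-k, trimmed
mean); intensity = foreground − background.

**Departure from the grid.** Per segment, bead centres are fit by least
squares as affine functions of their grid indices (with the hexagonal
half-pitch parity offset absorbed); the departure statistic
`d = sqrt(r_x² + r_y²)` flags beads being read at the wrong position.

**Whole-segment remapping.** A mis-registered segment carries effectively
random annotation. Searching integer grid shifts for the one that minimizes
the mean within-bead-type variance of log2 intensity recovers the true
mapping; being one row or column off scrambles everything, so the correct
shift appears as a single sharp variance minimum.

**Neighbour phenomena.** A neighbour graph over the lattice (≤6 neighbours
per bead) supports: seeded flood-fill detection of non-decoded clusters
(≥50 connected beads containing a bead with six non-decoded neighbours) and
their halos; flagging neighbours of bright, circular image features (mass ≥
40 px); and twin statistics — under i.i.d. random assembly of N beads from T
types with mean degree k, the expected number of neighbouring same-type
pairs is `N·k/2/T` (60 for a million beads of 50,000 types with six
neighbours), with a permutation null that shuffles decoded identities over
decoded positions.

**Two-pass summarization.** Beads flagged by the diagnostics are removed
first, then a generic outlier rule (median ± 3·1.4826·MAD on log2) is
applied within each type; detection calls compare summaries against the
negative-control distribution.

## Worked example

```python
import numpy as np
from beadqc import (SimulationConfig, ArtifactSpec, simulate_section,
                    extract_all, find_nondecoded_clusters, expand_cluster,
                    summarize)
from beadqc.spatial import flag_cluster_halo

cfg = SimulationConfig(seed=7, rows=40, cols=40, n_bead_types=500,
                       artifacts=(ArtifactSpec("nondecoded_cluster",
                                               {"size": 60}),))
sec = simulate_section(cfg)                      # image + ground truth
beads, mask = extract_all(sec.image, sec.beads)  # sharpen/foreground/background
decoded = beads["bead_type_id"].to_numpy() >= 0
clusters = expand_cluster(find_nondecoded_clusters(sec.graph, decoded),
                          sec.graph, decoded)
mask.update(flag_cluster_halo(clusters, len(beads)))
std, two = summarize(beads), summarize(beads, mask)
```

On this section the cluster of 61 non-decoded beads is found with a 47-bead
decoded halo, and over the 65 halo-affected bead-types the mean absolute
error of the summarized log2 intensity drops from 0.785 (standard analysis)
to 0.510 (two-pass). A representative type:

```
type 117: standard 9.90 -> two-pass 8.92 (truth 8.43)
```

i.e. masking the halo beads moves the summary a full log2 unit toward the
true level. The same pipeline is available from the shell:

```sh
beadqc simulate --out sim --seed 7 --rows 40 --cols 40 \
    --artifact '{"kind": "nondecoded_cluster", "params": {"size": 60}}'
beadqc extract --image sim/section_Grn.tif --locs sim/section.locs \
    --layout sim/layout.json --beadlevel sim/beadlevel_Grn.txt --out ext.txt
beadqc qc spatial --image sim/section_Grn.tif --locs sim/section.locs \
    --layout sim/layout.json --beadlevel ext.txt --out-prefix qc
beadqc summarize --beadlevel ext.txt --mask qc.mask.tsv --out summary.tsv
```

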
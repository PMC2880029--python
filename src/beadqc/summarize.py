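"""Two-pass bead-type summarization and detection calls.

The standard analysis summarizes each bead-type's replicates after a generic
outlier-removal step. The two-pass analysis first removes beads flagged by
the spatial diagnostics (known problems), then applies the same generic
outlier rule to the survivors; removing a known-bad bead frequently exposes
further outliers that its presence had been masking. Detection calls compare
each summarized type against the negative-control distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .masks import MaskSet

OUTLIER_RULES = ("mad3", "sd3")
_MAD_SCALE = 1.4826


def residual_log_intensity(beads: pd.DataFrame) -> np.ndarray:
    """Per-bead log2 intensity minus the median log2 of its bead-type.

    Non-positive intensities (possible after background subtraction) and
    non-decoded beads get NaN residuals.
    """
    ids = beads["bead_type_id"].to_numpy()
    intens = beads["intensity"].to_numpy(dtype=float)
    ok = (ids >= 0) & (intens > 0)
    out = np.full(len(beads), np.nan)
    log2 = np.log2(intens[ok])
    med = pd.Series(log2).groupby(ids[ok]).transform("median").to_numpy()
    out[ok] = log2 - med
    return out


def flag_outliers(values: np.ndarray, rule: str = "mad3") -> np.ndarray:
    """Generic outlier flags for one bead-type's log2 values.

    ``mad3``: |v - median| > 3 * 1.4826 * MAD; when the MAD is zero (heavily
    tied values) any value different from the median is flagged. ``sd3`` is
    the classical mean +/- 3 sd alternative. A single value is never an
    outlier.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    if values.size == 1:
        return np.zeros(1, dtype=bool)
    if rule == "mad3":
        med = np.median(values)
        mad = np.median(np.abs(values - med)) * _MAD_SCALE
        if mad == 0:
            return values != med
        return np.abs(values - med) > 3.0 * mad
    if rule == "sd3":
        mu = values.mean()
        sd = values.std(ddof=1)
        if sd == 0:
            return np.zeros(values.size, dtype=bool)
        return np.abs(values - mu) > 3.0 * sd
    raise ValueError(f"rule must be one of {OUTLIER_RULES}")


def summarize(beads: pd.DataFrame, mask: MaskSet | None = None,
              rule: str = "mad3") -> pd.DataFrame:
    """Per-bead-type summary table, optionally after artefact masking.

    Pass 1 drops masked beads (and non-positive intensities, counted as
    masked with reason ``nonpositive``); pass 2 applies the generic outlier
    rule within each type; the survivors' mean/median/sd of log2 intensity
    are reported. With an empty mask this is the standard analysis.
    """
    ids = beads["bead_type_id"].to_numpy()
    intens = beads["intensity"].to_numpy(dtype=float)
    masked = np.zeros(len(beads), dtype=bool) if mask is None else mask.any_flagged()
    nonpos = ~(intens > 0)
    excluded = masked | nonpos
    rows = []
    for type_id in np.unique(ids[ids >= 0]):
        sel = ids == type_id
        n_total = int(sel.sum())
        use = sel & ~excluded
        n_masked = n_total - int(use.sum())
        vals = np.log2(intens[use])
        if vals.size == 0:
            rows.append((type_id, n_total, n_masked, 0, 0,
                         np.nan, np.nan, np.nan))
            continue
        out = flag_outliers(vals, rule)
        kept = vals[~out]
        n_outliers = int(out.sum())
        sd = float(kept.std(ddof=1)) if kept.size > 1 else (0.0 if kept.size else np.nan)
        rows.append((type_id, n_total, n_masked, n_outliers, int(kept.size),
                     float(kept.mean()) if kept.size else np.nan,
                     float(np.median(kept)) if kept.size else np.nan,
                     sd))
    return pd.DataFrame(rows, columns=[
        "bead_type_id", "n_total", "n_masked", "n_outliers", "n_used",
        "mean_log2", "median_log2", "sd_log2",
    ]).set_index("bead_type_id")


def detection_call(summary: pd.DataFrame, negative_controls: np.ndarray,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Expressed / not-expressed calls against negative-control intensities.

    The detection score of a type is the empirical fraction of negative-
    control log2 values that exceed the type's summarized mean; a score below
    ``alpha`` calls the type expressed.
    """
    controls = np.asarray(negative_controls, dtype=float)
    controls = controls[np.isfinite(controls)]
    if controls.size < 20:
        raise ValueError(
            f"need >= 20 negative-control values, got {controls.size}"
        )
    means = summary["mean_log2"].to_numpy(dtype=float)
    score = np.array([
        np.nan if not np.isfinite(m) else float(np.mean(controls > m))
        for m in means
    ])
    out = summary.copy()
    out["detection_score"] = score
    out["expressed"] = score < alpha
    out.loc[~np.isfinite(score), "expressed"] = False
    return out
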
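"""Per-bead boolean masks keyed by artefact reason.

A :class:`MaskSet` records, for every bead of a section/segment, which
diagnostics want it excluded (or down-weighted) from summarization, and why.
Flags are idempotent under union and each reason is kept separate so the
provenance of an exclusion is never lost.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: reasons produced by the built-in diagnostics; arbitrary extra reasons are allowed
KNOWN_REASONS = (
    "near_cluster",
    "bright_bead",
    "bright_neighbour",
    "low_pixel",
    "large_departure",
    "channel_discordant",
    "out_of_image",
    "twin",
    "nonpositive",
)


class MaskSet:
    """Boolean per-bead flags keyed by reason string."""

    def __init__(self, n_beads: int):
        if n_beads < 0:
            raise ValueError("n_beads must be non-negative")
        self.n_beads = int(n_beads)
        self._flags: dict[str, np.ndarray] = {}

    # -- mutation -----------------------------------------------------------
    def add(self, reason: str, index) -> None:
        """Flag the beads in ``index`` (boolean mask or integer indices)."""
        if not reason:
            raise ValueError("reason must be a non-empty string")
        arr = self._flags.setdefault(reason, np.zeros(self.n_beads, dtype=bool))
        index = np.asarray(index)
        if index.dtype == bool:
            if index.shape != (self.n_beads,):
                raise ValueError("boolean mask length mismatch")
            arr |= index
        else:
            arr[index.astype(np.intp)] = True

    def update(self, other: "MaskSet") -> None:
        """Union another MaskSet into this one (idempotent)."""
        if other.n_beads != self.n_beads:
            raise ValueError("MaskSet sizes differ")
        for reason, arr in other._flags.items():
            self.add(reason, arr)

    # -- queries ------------------------------------------------------------
    @property
    def reasons(self) -> tuple[str, ...]:
        return tuple(sorted(self._flags))

    def flags(self, reason: str) -> np.ndarray:
        """Boolean array for one reason (all-False if never set)."""
        arr = self._flags.get(reason)
        if arr is None:
            return np.zeros(self.n_beads, dtype=bool)
        return arr.copy()

    def any_flagged(self, reasons: Iterable[str] | None = None) -> np.ndarray:
        """Beads flagged for at least one of ``reasons`` (default: all)."""
        out = np.zeros(self.n_beads, dtype=bool)
        keys = self._flags.keys() if reasons is None else reasons
        for reason in keys:
            if reason in self._flags:
                out |= self._flags[reason]
        return out

    def counts(self) -> dict[str, int]:
        return {r: int(a.sum()) for r, a in sorted(self._flags.items())}

    # -- serialisation ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long table of (bead_index, reason) rows, sorted."""
        rows = []
        for reason in self.reasons:
            idx = np.flatnonzero(self._flags[reason])
            rows.append(pd.DataFrame({"bead_index": idx, "reason": reason}))
        if not rows:
            return pd.DataFrame({"bead_index": pd.Series(dtype=int),
                                 "reason": pd.Series(dtype=str)})
        return (
            pd.concat(rows, ignore_index=True)
            .sort_values(["bead_index", "reason"], kind="mergesort")
            .reset_index(drop=True)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_beads: int) -> "MaskSet":
        ms = cls(n_beads)
        for reason, grp in frame.groupby("reason"):
            ms.add(str(reason), grp["bead_index"].to_numpy())
        return ms

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, np.ndarray], n_beads: int) -> "MaskSet":
        ms = cls(n_beads)
        for reason, idx in mapping.items():
            ms.add(reason, idx)
        return ms

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MaskSet(n_beads={self.n_beads}, counts={self.counts()})"
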
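"""Three-way chromatographic data container.

Interval-segmented GC-MS data form a three-way structure X (I x J x K):
elution scans (I, sample-specific), m/z fragments (J, shared) and samples
(K).  Because retention shifts make scan counts and peak positions differ
between samples, the slabs are kept as a list of matrices rather than a
dense cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ThreeWayTensor"]


@dataclass
class ThreeWayTensor:
    """Interval-segmented chromatographic data.

    Parameters
    ----------
    slabs
        K matrices of shape (I_k scans, J m/z bins); all share J.
    retention_time_axes
        Per-slab retention times in minutes, strictly increasing.
    mz_axis
        Shared m/z bins (length J).
    sample_ids
        K sample labels, aligned with ``slabs``.
    """

    slabs: list[np.ndarray]
    retention_time_axes: list[np.ndarray]
    mz_axis: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.slabs = [np.asarray(s, dtype=float) for s in self.slabs]
        self.retention_time_axes = [np.asarray(t, dtype=float) for t in self.retention_time_axes]
        self.mz_axis = np.asarray(self.mz_axis)
        if not self.slabs:
            raise ValueError("tensor must contain at least one slab")
        J = self.mz_axis.size
        if not self.sample_ids:
            self.sample_ids = [f"sample_{k}" for k in range(len(self.slabs))]
        if len(self.sample_ids) != len(self.slabs):
            raise ValueError("sample_ids and slabs length mismatch")
        if len(self.retention_time_axes) != len(self.slabs):
            raise ValueError("retention_time_axes and slabs length mismatch")
        for sid, slab, rt in zip(self.sample_ids, self.slabs, self.retention_time_axes):
            if slab.ndim != 2 or slab.shape[1] != J:
                raise ValueError(
                    f"slab for sample {sid!r} has {slab.shape[1] if slab.ndim == 2 else '?'} "
                    f"m/z columns, expected {J}"
                )
            if rt.shape != (slab.shape[0],):
                raise ValueError(f"retention axis length mismatch for sample {sid!r}")
            if rt.size > 1 and not np.all(np.diff(rt) > 0):
                raise ValueError(f"retention times not strictly increasing for sample {sid!r}")
            if not np.all(np.isfinite(slab)):
                raise ValueError(f"non-finite values in slab for sample {sid!r}")

    @property
    def n_samples(self) -> int:
        return len(self.slabs)

    @property
    def n_mz(self) -> int:
        return int(self.mz_axis.size)

    @property
    def scan_counts(self) -> list[int]:
        return [s.shape[0] for s in self.slabs]

    def total_ss(self) -> float:
        """Total sum of squares over all slabs."""
        return float(sum(np.sum(s * s) for s in self.slabs))

    def min_dimension(self) -> int:
        """min over slabs of (I_k, J, K): the component-count bound."""
        return int(min(min(self.scan_counts), self.n_mz, self.n_samples))
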
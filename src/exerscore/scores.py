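"""Shared similarity-score container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SimilarityScore:
    """A 0-100% similarity score plus the raw comparison values behind it.

    ``per_pair_values`` holds the unaveraged, unclamped comparison values
    (one per participant/reference repetition pair for DTW, one per
    participant repetition for the HMM); values below 0 indicate a
    performance farther from the reference than the worst-performance
    baseline.  ``value`` is their mean clamped to [0, 100].
    """

    value: float
    method: str
    per_pair_values: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in ("dtw", "hmm"):
            raise ValueError("method must be 'dtw' or 'hmm'")
        if not 0.0 <= self.value <= 100.0:
            raise ValueError("score must lie in [0, 100]")

    @property
    def standard_error(self) -> float:
        """Standard error of the retained raw values (0 for a single value)."""
        v = np.asarray(self.per_pair_values, dtype=float)
        if v.size < 2:
            return 0.0
        return float(v.std(ddof=1) / np.sqrt(v.size))


def clamp_score(x: float) -> float:
    return float(min(100.0, max(0.0, x)))
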
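"""Container for a measured or simulated reflectivity dataset."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReflectivityDataset"]


@dataclass
class ReflectivityDataset:
    """(Q, R, dR[, dQ]) with contrast and instrument metadata.

    dR are one-standard-deviation uncertainties on R; dQ, when present, are
    per-point FWHM resolution widths.
    """

    q: np.ndarray
    r: np.ndarray
    dr: np.ndarray
    dq: np.ndarray | None = None
    contrast: str | None = None
    instrument: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.dr = np.asarray(self.dr, dtype=float)
        if self.dq is not None:
            self.dq = np.asarray(self.dq, dtype=float)
        n = len(self.q)
        if len(self.r) != n or len(self.dr) != n:
            raise ValueError("Q, R, dR must have equal lengths")
        if self.dq is not None and len(self.dq) != n:
            raise ValueError("dQ must match Q in length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("Q must be strictly increasing")
        if np.any(self.dr <= 0):
            raise ValueError("dR must be positive everywhere")

    def __len__(self) -> int:
        return len(self.q)
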
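"""In-memory record of one parametric T1 map with its segmentation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass
class T1MapRecord:
    """One T1 map: pixel values in ms, binary myocardium mask, CP vector.

    ``pixels`` and ``mask`` share one row-major grid (origin top-left);
    masks are never resampled. ``source_meta`` retains raw DICOM attributes
    keyed by lowercase hex tag ``"gggg,eeee"`` for traceability and CP
    extraction.
    """

    map_id: str
    subject_id: str = ""
    cohort: str = ""
    pixels: np.ndarray | None = None
    mask: np.ndarray | None = None
    cp_values: dict = field(default_factory=dict)
    source_meta: dict = field(default_factory=dict)

    def segmented_values(self) -> np.ndarray:
        """Myocardial pixel values in ms, row-major mask order."""
        self.validate()
        return self.pixels[self.mask.astype(bool)].astype(np.float64)

    def validate(self) -> None:
        """Enforce the record invariants required for training/standardising."""
        if self.pixels is None or self.mask is None:
            raise InputError(f"map {self.map_id!r}: pixels or mask missing")
        if self.pixels.shape != self.mask.shape:
            raise InputError(
                f"map {self.map_id!r}: pixel shape {self.pixels.shape} != "
                f"mask shape {self.mask.shape}"
            )
        inside = self.mask.astype(bool)
        if not inside.any():
            raise InputError(f"map {self.map_id!r}: mask is empty")
        seg = self.pixels[inside]
        if not np.all(np.isfinite(seg)) or not np.all(seg > 0):
            raise InputError(
                f"map {self.map_id!r}: segmented pixels must be finite and > 0 ms"
            )
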
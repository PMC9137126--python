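"""Validation-assay statistics: flow-cytometry Stain Index and qPCR 2^-ddCt."""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class StainMeasurement:
    """Fluorescence summary of a stained vs background population (a.u.)."""

    mean_positive: float
    mean_background: float
    sd_background: float

    def __post_init__(self) -> None:
        if self.sd_background <= 0:
            raise ValueError("sd_background must be positive")


def stain_index(m: StainMeasurement) -> float:
    """Stain Index: (mean positive - mean background) / (2 * SD background)."""
    return (m.mean_positive - m.mean_background) / (2.0 * m.sd_background)


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct values for target and reference gene in sample and calibrator."""

    ct_target_sample: float
    ct_ref_sample: float
    ct_target_calibrator: float
    ct_ref_calibrator: float

    def __post_init__(self) -> None:
        for v in (
            self.ct_target_sample,
            self.ct_ref_sample,
            self.ct_target_calibrator,
            self.ct_ref_calibrator,
        ):
            if not math.isfinite(v):
                raise ValueError("all Ct values must be finite")

    @property
    def ddct(self) -> float:
        return (self.ct_target_sample - self.ct_ref_sample) - (
            self.ct_target_calibrator - self.ct_ref_calibrator
        )


def relative_quant(q: QpcrMeasurement) -> float:
    """Relative expression versus the calibrator, 2^(-ddCt)."""
    return 2.0 ** (-q.ddct)
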
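"""Relative RT-qPCR quantification by the 2^-ddCt (Livak) method."""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

from .iomod import HeteroseqError

logger = logging.getLogger("heteroseq")


@dataclasses.dataclass(frozen=True)
class CtMeasurement:
    """One qPCR well pair: target and reference-gene Ct for one sample."""

    sample_id: str
    condition: str  # "treatment" or "control"
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if self.condition not in ("treatment", "control"):
            raise HeteroseqError(f"condition must be treatment/control, got {self.condition!r}")
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise HeteroseqError("Ct values must be positive")
        if self.ct_target > 45 or self.ct_reference > 45:
            logger.warning("Ct above 45 cycles for sample %s; check the assay", self.sample_id)


def ddct(measurements: Sequence[CtMeasurement]) -> float:
    """2^-ddCt relative expression of treatment vs control.

    dCt = Ct(target) - Ct(reference) per sample; ddCt is the difference of
    the mean treatment dCt and the mean control dCt; the result is
    2^(-ddCt). Replicates are aggregated by the arithmetic mean of dCt.
    """
    dct = {"treatment": [], "control": []}
    for m in measurements:
        dct[m.condition].append(m.ct_target - m.ct_reference)
    for cond, vals in dct.items():
        if not vals:
            raise HeteroseqError(f"no {cond} measurements provided")
    delta_delta = sum(dct["treatment"]) / len(dct["treatment"]) - sum(dct["control"]) / len(dct["control"])
    return 2.0 ** (-delta_delta)
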
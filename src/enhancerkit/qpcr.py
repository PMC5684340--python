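"""qPCR quantification formulas used for validation readouts.

Both formulas assume perfect per-cycle doubling (amplification efficiency
2). Relative expression uses the 2^-ddCt method against a housekeeping
reference gene; ChIP enrichment is expressed as percent of input, with the
input Ct adjusted for the fraction of chromatin saved as input (e.g. a 10%
input is 1/0.10 = 10-fold diluted, i.e. log2(10) ~ 3.32 cycles behind a
hypothetical 100% input).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["QpcrMeasurement", "fold_change_ddct", "percent_input"]


@dataclass
class QpcrMeasurement:
    """Threshold cycles for one sample/condition."""

    ct_target: float | None = None
    ct_reference: float | None = None
    ct_chip: float | None = None
    ct_input: float | None = None
    input_fraction: float = 0.10
    condition: str = ""

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference", "ct_chip", "ct_input"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive")
        if not (0 < self.input_fraction <= 1):
            raise ValueError("input_fraction must be in (0, 1]")


def fold_change_ddct(trt: QpcrMeasurement, ctrl: QpcrMeasurement) -> float:
    """2^-ddCt fold change of treated over control after reference-gene
    normalization: dCt = Ct_target - Ct_reference per condition."""
    for m, label in ((trt, "treated"), (ctrl, "control")):
        if m.ct_target is None or m.ct_reference is None:
            raise ValueError(f"{label} measurement needs ct_target and ct_reference")
    dct_trt = trt.ct_target - trt.ct_reference
    dct_ctrl = ctrl.ct_target - ctrl.ct_reference
    return 2.0 ** -(dct_trt - dct_ctrl)


def percent_input(m: QpcrMeasurement, dilution_adjust: bool = True) -> float:
    """ChIP enrichment as percent of input chromatin.

    Ct_100%input = Ct_input - log2(1/input_fraction) when the dilution
    adjustment is applied (the input was only input_fraction of the
    chromatin); percent = 100 * 2^-(Ct_ChIP - Ct_100%input).
    """
    if m.ct_chip is None or m.ct_input is None:
        raise ValueError("measurement needs ct_chip and ct_input")
    ct_full_input = m.ct_input
    if dilution_adjust:
        ct_full_input = m.ct_input - math.log2(1.0 / m.input_fraction)
    return 100.0 * 2.0 ** -(m.ct_chip - ct_full_input)
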
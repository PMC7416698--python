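"""Shared prediction container."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Prediction:
    """A model prediction with its range half-width.

    ``value`` is in target units (dB for FS, decimal for VA);
    ``half_width`` is ``1.96 * RMSE`` of the evaluated model, same units.
    """

    value: float
    half_width: float

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be non-negative")

    @property
    def low(self) -> float:
        return self.value - self.half_width

    @property
    def high(self) -> float:
        return self.value + self.half_width
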
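"""Containers for gait-cycle muscle-activation data.

A gait cycle is the interval between successive heel strikes.  All signals
here are *activation envelopes*: unitless drives in [0, 1], one channel per
muscle, sampled on a common time grid within the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = ["ActivationCycle", "PairedCycle"]


@dataclass
class ActivationCycle:
    """One gait cycle of multichannel muscle activation.

    Parameters
    ----------
    values
        ``(channels, samples)`` array of activations, clipped to [0, 1].
    sample_times
        Strictly increasing sample times in seconds, length ``samples``.
    muscle_names
        One label per channel.
    subject_id, speed_id, cycle_index
        Identity of the cycle within a dataset.
    """

    values: np.ndarray
    sample_times: np.ndarray
    muscle_names: list[str]
    subject_id: str = ""
    speed_id: int = 0
    cycle_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a (channels, samples) matrix")
        if self.sample_times.ndim != 1 or self.sample_times.size != self.values.shape[1]:
            raise ValueError("sample_times length must equal the sample count")
        if self.sample_times.size > 1 and not np.all(np.diff(self.sample_times) > 0):
            raise ValueError("sample_times must be strictly increasing")
        if len(self.muscle_names) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.muscle_names)} muscle names for "
                f"{self.values.shape[0]} channels"
            )
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("activations must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def channel(self, muscle: str) -> np.ndarray:
        """Return one muscle's activation trace."""
        return self.values[self.channel_index(muscle)]

    def channel_index(self, muscle: str) -> int:
        try:
            return self.muscle_names.index(muscle)
        except ValueError:
            raise KeyError(
                f"unknown muscle {muscle!r}; available: {', '.join(self.muscle_names)}"
            ) from None

    def with_values(self, values: np.ndarray) -> "ActivationCycle":
        return replace(self, values=np.asarray(values, dtype=float))

    @property
    def identity(self) -> tuple[str, int, int]:
        return (self.subject_id, self.speed_id, self.cycle_index)


@dataclass
class PairedCycle:
    """Aligned (simulated, measured) activation cycles — one training unit.

    ``simulated`` is the musculoskeletal-simulator estimate (the network
    input); ``measured`` is the EMG-derived activation (the target).
    """

    simulated: ActivationCycle
    measured: ActivationCycle

    def __post_init__(self) -> None:
        s, m = self.simulated, self.measured
        if s.identity != m.identity:
            raise ValueError(f"identity mismatch: {s.identity} vs {m.identity}")
        if s.muscle_names != m.muscle_names:
            raise ValueError("simulated and measured channel labels differ")
        if s.n_samples != m.n_samples:
            raise ValueError("simulated and measured sample counts differ")

    @property
    def identity(self) -> tuple[str, int, int]:
        return self.simulated.identity

    @property
    def muscle_names(self) -> list[str]:
        return self.simulated.muscle_names


def stack_values(cycles: Sequence[ActivationCycle]) -> np.ndarray:
    """Stack cycles into a ``(n_cycles, channels, samples)`` array."""
    return np.stack([c.values for c in cycles])
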
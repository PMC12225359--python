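"""Two-state classification of RR intervals against a reference band.

Each RR interval is labelled Normal (``N``) when its duration lies inside
a closed reference band [lower, upper] (both bounds inclusive) and
Arrhythmic (``A``) otherwise — whether too short or too long.  Two named
presets are provided: the arachnophobia-cohort band [800, 1000] ms and
the blood-pressure-cohort band [900, 1100] ms, both centred near the
typical resting RR interval of about 900 ms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import RRSeries

__all__ = [
    "StateLabel",
    "A",
    "N",
    "AlphaBand",
    "StateSequence",
    "classify_states",
    "default_band",
    "COHORT_BANDS",
]


class StateLabel(enum.IntEnum):
    """The two-element state space S = {A, N}."""

    A = 0  # arrhythmic: RR outside the band
    N = 1  # normal: RR inside the band

    def __str__(self) -> str:  # "A" / "N"
        return self.name


A = StateLabel.A
N = StateLabel.N


@dataclass(frozen=True)
class AlphaBand:
    """Closed reference band [lower, upper] in ms defining the N state."""

    lower: float
    upper: float
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValidationError(
                f"band must satisfy 0 < lower < upper, got [{self.lower}, {self.upper}]"
            )

    def contains(self, value_ms) -> np.ndarray:
        """Elementwise inclusive membership test."""
        v = np.asarray(value_ms, dtype=float)
        return (v >= self.lower) & (v <= self.upper)


@dataclass(eq=False)
class StateSequence:
    """A realization of the label process X0, X1, X2, ... over {A, N}.

    ``labels`` stores :class:`StateLabel` values as small integers
    (A = 0, N = 1) in the same order as the source RR series.
    """

    labels: np.ndarray
    subject_id: str = ""
    band_used: AlphaBand | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.dtype.kind in "UO":  # letters -> codes
            arr = np.array([StateLabel[str(s)] for s in arr])
        arr = arr.astype(np.uint8)
        if arr.size and not np.all((arr == 0) | (arr == 1)):
            raise ValidationError("state labels must be A (0) or N (1)")
        self.labels = arr

    def __len__(self) -> int:
        return int(self.labels.size)

    def to_letters(self) -> list[str]:
        return [StateLabel(v).name for v in self.labels]

    @classmethod
    def from_letters(
        cls,
        letters,
        subject_id: str = "",
        band_used: AlphaBand | None = None,
    ) -> "StateSequence":
        codes = np.array([StateLabel[str(s)] for s in letters], dtype=np.uint8)
        return cls(codes, subject_id=subject_id, band_used=band_used)


#: Named band presets per cohort.
COHORT_BANDS: dict[str, AlphaBand] = {
    "arachnophobia": AlphaBand(800.0, 1000.0, name="alpha1"),
    "blood_pressure": AlphaBand(900.0, 1100.0, name="alpha2"),
}


def default_band(cohort: str) -> AlphaBand:
    """Return the preset band for a cohort.

    ``"arachnophobia"`` maps to [800, 1000] ms and ``"blood_pressure"``
    to [900, 1100] ms; anything else raises :class:`ValidationError`.
    """
    try:
        return COHORT_BANDS[cohort]
    except KeyError:
        raise ValidationError(
            f"unknown cohort {cohort!r}; expected one of {sorted(COHORT_BANDS)}"
        ) from None


def classify_states(rr: RRSeries, band: AlphaBand) -> StateSequence:
    """Label each RR interval N if it lies inside the closed band, else A.

    The classification is elementwise and stateless; an empty series
    yields an empty label sequence.  Values are compared at full float
    precision with inclusive bounds on both ends.
    """
    labels = np.where(band.contains(rr.intervals), np.uint8(N), np.uint8(A))
    return StateSequence(labels, subject_id=rr.subject_id, band_used=band)
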
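"""Sliding-window estimation of 2x2 transition matrices over {A, N}.

A window of fixed width W (default 10 RR intervals) slides along a state
sequence, producing label arrays V1, V2, ...  Within each window the
transition matrix is estimated by counting adjacent ordered pairs: with
n_ij pairs observed from state i to state j,

    P_ij = n_ij / (n_iA + n_iN),

so every defined row is exactly stochastic (P_iA + P_iN = 1).  A row
with no outgoing transition in the window is *undefined* (NaN), never
imputed; undefined entries are excluded from the pooled per-transition
sample vectors that feed group comparisons.

With the default step of 1 the windows overlap maximally, so each
adjacent pair contributes to up to W-1 windows — intentional, since the
unit of analysis is the window, not the pair.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySeriesWarning, ValidationError
from .io import RRSeries
from .states import A, N, AlphaBand, StateSequence, classify_states

__all__ = [
    "Transition",
    "TABLE_ORDER",
    "WindowConfig",
    "WindowView",
    "TransitionMatrix",
    "WindowEstimates",
    "sliding_windows",
    "estimate_transition_matrix",
    "window_probability_series",
]


class Transition(enum.Enum):
    """The four ordered state transitions of the two-state chain."""

    AA = ("A", "A")
    AN = ("A", "N")
    NA = ("N", "A")
    NN = ("N", "N")

    @property
    def label(self) -> str:
        return f"{self.value[0]} to {self.value[1]}"


#: Row order used in the comparison reports (A to N, A to A, N to A, N to N).
TABLE_ORDER: tuple[Transition, ...] = (
    Transition.AN,
    Transition.AA,
    Transition.NA,
    Transition.NN,
)


@dataclass(frozen=True)
class WindowConfig:
    """Moving-window geometry: width in RR intervals and advance step."""

    window_size: int = 10
    step: int = 1

    def __post_init__(self) -> None:
        if int(self.window_size) != self.window_size or self.window_size < 2:
            raise ValidationError(
                f"window_size must be an integer >= 2, got {self.window_size!r}"
            )
        if int(self.step) != self.step or self.step < 1:
            raise ValidationError(f"step must be an integer >= 1, got {self.step!r}")

    def n_windows(self, sequence_length: int) -> int:
        """Closed-form window count for a sequence of the given length."""
        if sequence_length < self.window_size:
            return 0
        return (sequence_length - self.window_size) // self.step + 1


@dataclass(eq=False)
class WindowView:
    """One label array V_n: a window-sized slice of the parent sequence."""

    labels: np.ndarray
    start_index: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)

    def __len__(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 2x2 transition-probability estimate with its counts.

    Probabilities of an undefined row (no outgoing transitions observed)
    are NaN.  Defined rows sum to 1 exactly up to float rounding.
    """

    n_aa: int
    n_an: int
    n_na: int
    n_nn: int

    def _row(self, first: int, second: int) -> float:
        total = first + second
        return first / total if total else float("nan")

    @property
    def p_aa(self) -> float:
        return self._row(self.n_aa, self.n_an)

    @property
    def p_an(self) -> float:
        return self._row(self.n_an, self.n_aa)

    @property
    def p_na(self) -> float:
        return self._row(self.n_na, self.n_nn)

    @property
    def p_nn(self) -> float:
        return self._row(self.n_nn, self.n_na)

    def count(self, t: Transition) -> int:
        return {
            Transition.AA: self.n_aa,
            Transition.AN: self.n_an,
            Transition.NA: self.n_na,
            Transition.NN: self.n_nn,
        }[t]

    def probability(self, t: Transition) -> float:
        return {
            Transition.AA: self.p_aa,
            Transition.AN: self.p_an,
            Transition.NA: self.p_na,
            Transition.NN: self.p_nn,
        }[t]

    def row_defined(self, state) -> bool:
        if state == A or str(state) == "A":
            return (self.n_aa + self.n_an) > 0
        return (self.n_na + self.n_nn) > 0

    def as_array(self) -> np.ndarray:
        """2x2 probability array with rows/columns ordered (A, N)."""
        return np.array([[self.p_aa, self.p_an], [self.p_na, self.p_nn]])


@dataclass(eq=False)
class WindowEstimates:
    """Per-window transition matrices plus pooled per-transition samples.

    ``samples[t]`` holds the defined P_t values across windows in window
    order; windows where the source row of ``t`` is undefined contribute
    nothing (rather than an imputed value).
    """

    subject_id: str
    band: AlphaBand | None
    config: WindowConfig
    start_indices: np.ndarray
    matrices: list[TransitionMatrix]
    samples: dict[Transition, np.ndarray] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.matrices)


def sliding_windows(seq: StateSequence, cfg: WindowConfig) -> list[WindowView]:
    """Cut a state sequence into windows starting at 0, step, 2*step, ...

    Every window has exactly ``cfg.window_size`` labels; a sequence
    shorter than one window yields an empty list with a warning.
    """
    n = len(seq)
    if n < cfg.window_size:
        warnings.warn(
            f"sequence of length {n} is shorter than the window "
            f"({cfg.window_size}); no windows produced",
            EmptySeriesWarning,
            stacklevel=2,
        )
        return []
    starts = range(0, n - cfg.window_size + 1, cfg.step)
    return [WindowView(seq.labels[s : s + cfg.window_size], s) for s in starts]


def estimate_transition_matrix(window) -> TransitionMatrix:
    """Estimate the 2x2 transition matrix of one window by pair counting.

    Accepts a :class:`WindowView`, a :class:`StateSequence`, or any label
    sequence (letters or {0, 1} codes) of length >= 2.  Each adjacent
    ordered pair (labels[k], labels[k+1]) increments its transition
    count; probabilities are counts normalised per source state.
    """
    if isinstance(window, (WindowView, StateSequence)):
        labels = window.labels
    else:
        labels = StateSequence(np.asarray(window)).labels
    if labels.size < 2:
        raise ValidationError(
            f"need at least 2 labels to count transitions, got {labels.size}"
        )
    frm, to = labels[:-1], labels[1:]
    n_aa = int(np.sum((frm == A) & (to == A)))
    n_an = int(np.sum((frm == A) & (to == N)))
    n_na = int(np.sum((frm == N) & (to == A)))
    n_nn = int(np.sum((frm == N) & (to == N)))
    return TransitionMatrix(n_aa, n_an, n_na, n_nn)


def _window_pair_counts(labels: np.ndarray, cfg: WindowConfig) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pair counts for every window.

    Returns ``(starts, counts)`` where ``counts`` has one row per window
    and columns (n_aa, n_an, n_na, n_nn).  Equivalent to running
    :func:`estimate_transition_matrix` on each window.
    """
    n = labels.size
    w, step = cfg.window_size, cfg.step
    starts = np.arange(0, n - w + 1, step, dtype=np.int64)
    # pair k spans labels (k, k+1); window at s uses pairs s .. s+w-2
    pair_type = 2 * labels[:-1].astype(np.int64) + labels[1:]
    one_hot = pair_type[:, None] == np.array([[2 * A + A, 2 * A + N, 2 * N + A, 2 * N + N]])
    cum = np.zeros((n, 4), dtype=np.int64)
    np.cumsum(one_hot, axis=0, out=cum[1:])
    counts = cum[starts + w - 1] - cum[starts]
    return starts, counts


def window_probability_series(
    rr: RRSeries,
    band: AlphaBand,
    cfg: WindowConfig = WindowConfig(),
) -> WindowEstimates:
    """Full per-record pipeline: classify, window, estimate, collect.

    Composes :func:`classify_states`, the moving window, and per-window
    matrix estimation, then gathers each transition's defined
    probabilities across windows (in window order) into sample vectors.
    """
    seq = classify_states(rr, band)
    n = len(seq)
    if n < cfg.window_size:
        warnings.warn(
            f"record {rr.subject_id!r}: {n} intervals < window "
            f"({cfg.window_size}); no windows produced",
            EmptySeriesWarning,
            stacklevel=2,
        )
        starts = np.empty(0, dtype=np.int64)
        counts = np.empty((0, 4), dtype=np.int64)
    else:
        starts, counts = _window_pair_counts(seq.labels, cfg)

    matrices = [TransitionMatrix(*map(int, row)) for row in counts]

    a_out = counts[:, 0] + counts[:, 1]
    n_out = counts[:, 2] + counts[:, 3]
    with np.errstate(invalid="ignore"):
        samples = {
            Transition.AA: (counts[a_out > 0, 0] / a_out[a_out > 0]),
            Transition.AN: (counts[a_out > 0, 1] / a_out[a_out > 0]),
            Transition.NA: (counts[n_out > 0, 2] / n_out[n_out > 0]),
            Transition.NN: (counts[n_out > 0, 3] / n_out[n_out > 0]),
        }
    return WindowEstimates(
        subject_id=rr.subject_id,
        band=band,
        config=cfg,
        start_indices=starts,
        matrices=matrices,
        samples=samples,
    )
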
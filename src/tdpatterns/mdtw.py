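"""Modified dynamic time warping (MDTW) over eating-event sequences.

Two recalls are compared by optimally aligning their eating events under
the classic monotone DTW step set (match, repeat-left, repeat-right) and
summing, along the alignment, the local cost

    cost(a, b) = ((e_a - e_b)/energy_scale)**2 + beta * ((t_a - t_b)/time_scale)**2

so the weight ``beta`` penalises time mismatches relative to energy
mismatches; a large beta discourages pathological matchings such as a
breakfast aligning with a late-night snack.  With the defaults, time is
measured in hours and energy in 100-kcal units, which puts the two
squared terms on comparable scales near beta = 40.

MDTW is not a metric: it is nonnegative, symmetric, and zero exactly for
identical (scaled) sequences, but it can violate the triangle inequality
like every DTW-type measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .recall import RecallDay

__all__ = [
    "MdtwConfig",
    "DistanceMatrix",
    "local_cost",
    "mdtw_distance",
    "pairwise_distance_matrix",
]


@dataclass(frozen=True)
class MdtwConfig:
    """MDTW weighting and unit conventions.

    beta
        Weight on the squared time difference (dimensionless once the
        scales are applied).  Default 40.
    time_scale
        Divisor converting minutes to model time units; 60 = hours.
    energy_scale
        Divisor converting kcal to model energy units; 100 = hectocalories.
    """

    beta: float = 40.0
    time_scale: float = 60.0
    energy_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.time_scale <= 0 or self.energy_scale <= 0:
            raise ValueError("scales must be positive")


def _event_arrays(events) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(events, RecallDay):
        return events.times, events.energies
    t = np.array([float(ev[0]) if not hasattr(ev, "time_min") else float(ev.time_min) for ev in events])
    e = np.array([float(ev[1]) if not hasattr(ev, "energy_kcal") else float(ev.energy_kcal) for ev in events])
    return t, e


def local_cost(a, b, config: MdtwConfig = MdtwConfig()) -> float:
    """Squared-difference cost between two eating events."""
    ta, ea = _event_arrays([a])
    tb, eb = _event_arrays([b])
    de = (ea[0] - eb[0]) / config.energy_scale
    dt = (ta[0] - tb[0]) / config.time_scale
    return de * de + config.beta * dt * dt


def mdtw_distance(events_a, events_b, config: MdtwConfig = MdtwConfig()) -> float:
    """MDTW distance between two nonempty, time-sorted event sequences.

    Dynamic programme over the |A| x |B| cost table; every event of each
    sequence is matched to at least one event of the other.
    """
    ta, ea = _event_arrays(events_a)
    tb, eb = _event_arrays(events_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("MDTW is undefined for empty event sequences")
    dt = (ta[:, None] - tb[None, :]) / config.time_scale
    de = (ea[:, None] - eb[None, :]) / config.energy_scale
    cost = de * de + config.beta * dt * dt

    D = np.empty_like(cost)
    D[0, :] = np.cumsum(cost[0, :])
    D[:, 0] = np.cumsum(cost[:, 0])
    for i in range(1, cost.shape[0]):
        for j in range(1, cost.shape[1]):
            D[i, j] = cost[i, j] + min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    return float(D[-1, -1])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise MDTW distances with participant ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(dtype=float))

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def pairwise_distance_matrix(
    recalls: Sequence[RecallDay], config: MdtwConfig = MdtwConfig()
) -> DistanceMatrix:
    """All-pairs MDTW over a cohort of recalls.

    Sequences are padded to the cohort's maximum event count and the DP
    recurrence is evaluated for one row of the matrix at a time,
    vectorised over the opposing participants; padded cells never reach
    the read-out entry (la-1, lb-1) so padding values are irrelevant.
    """
    n = len(recalls)
    if n < 2:
        raise ValueError("need at least two recalls")
    lens = np.array([len(r.events) for r in recalls])
    L = int(lens.max())
    T = np.zeros((n, L))
    E = np.zeros((n, L))
    for i, r in enumerate(recalls):
        T[i, : lens[i]] = r.times / config.time_scale
        E[i, : lens[i]] = r.energies / config.energy_scale

    beta = config.beta
    D = np.zeros((n, n))
    for i in range(n - 1):
        la = int(lens[i])
        tj, ej = T[i + 1 :], E[i + 1 :]          # (m, L)
        prev = None
        for a in range(la):
            ca = (E[i, a] - ej) ** 2 + beta * (T[i, a] - tj) ** 2
            cur = np.empty_like(ca)
            if prev is None:
                np.cumsum(ca, axis=1, out=cur)
            else:
                cur[:, 0] = ca[:, 0] + prev[:, 0]
                for b in range(1, L):
                    step = np.minimum(prev[:, b - 1], prev[:, b])
                    np.minimum(step, cur[:, b - 1], out=step)
                    cur[:, b] = ca[:, b] + step
            prev = cur
        m = n - i - 1
        D[i, i + 1 :] = prev[np.arange(m), lens[i + 1 :] - 1]
    D = D + D.T
    return DistanceMatrix(ids=[r.participant_id for r in recalls], values=D)
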
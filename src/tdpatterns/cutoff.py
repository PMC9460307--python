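"""Energy/time cut-off classification of temporal dietary patterns.

A descriptive, rule-based counterpart to the data-driven clusters:

1. if every eating event is below the energy threshold (800 kcal),
   the participant belongs to cluster 1 (moderate, even intake);
2. otherwise the unique maximum-energy event decides the cluster by its
   clock time — [05:00, 15:00) -> cluster 4, [15:00, 19:00) -> cluster 2,
   19:00 onward -> cluster 3;
3. if the maximum energy is attained by more than one event, the
   participant falls back to cluster 1.

Two genuinely ambiguous corners are config-exposed rather than silently
fixed: the threshold comparison is strict (an event of exactly 800 kcal
disqualifies cluster 1), and a maximum event before 05:00 is assigned to
cluster 3 as a continuation of late-night eating across midnight.
Energies are compared after merging simultaneous events, with exact
float equality for ties (recall energies are sums of coded food
energies, so exact ties are meaningful).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import yaml

from .recall import RecallDay, merge_simultaneous_events

__all__ = ["CutoffRule", "classify", "classify_cohort", "read_rule", "write_rule"]


@dataclass(frozen=True)
class CutoffRule:
    """Published cut-off rule; all boundaries in minutes of day."""

    energy_threshold_kcal: float = 800.0
    window_c4: tuple[int, int] = (300, 900)     # [05:00, 15:00)
    window_c2: tuple[int, int] = (900, 1140)    # [15:00, 19:00)
    night_start: int = 1140                     # 19:00; >= here (or < 05:00) -> cluster 3
    tie_label: int = 1
    strict_threshold: bool = True               # events == threshold leave cluster 1

    def __post_init__(self) -> None:
        if self.window_c4[1] != self.window_c2[0] or self.window_c2[1] != self.night_start:
            raise ValueError("windows must be contiguous: c4 end = c2 start, c2 end = night start")
        if not 0 < self.window_c4[0] < self.window_c4[1] < self.window_c2[1] <= 1440:
            raise ValueError("window boundaries out of order")


def classify(events, rule: CutoffRule = CutoffRule()) -> int:
    """Label one participant's eating events with a cluster in {1, 2, 3, 4}."""
    if isinstance(events, RecallDay):
        events = events.events
    merged = merge_simultaneous_events(events)
    if not merged:
        raise ValueError("cannot classify an empty event list")
    energies = np.array([ev.energy_kcal for ev in merged])
    thr = rule.energy_threshold_kcal
    below = energies < thr if rule.strict_threshold else energies <= thr
    if below.all():
        return 1
    emax = energies.max()
    at_max = np.flatnonzero(energies == emax)
    if at_max.size > 1:
        return rule.tie_label
    t = merged[int(at_max[0])].time_min
    if rule.window_c4[0] <= t < rule.window_c4[1]:
        return 4
    if rule.window_c2[0] <= t < rule.window_c2[1]:
        return 2
    return 3  # >= night_start, or before 05:00 (overnight continuation)


def classify_cohort(
    recalls: Sequence[RecallDay], rule: CutoffRule = CutoffRule()
) -> tuple[np.ndarray, dict[int, int]]:
    """Apply :func:`classify` per participant; labels plus per-label counts."""
    if not recalls:
        raise ValueError("empty cohort")
    labels = np.array([classify(r, rule) for r in recalls])
    return labels, dict(sorted(Counter(labels.tolist()).items()))


def write_rule(rule: CutoffRule, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(rule), fh, sort_keys=False)


def read_rule(path) -> CutoffRule:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("window_c4", "window_c2"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return CutoffRule(**raw)
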
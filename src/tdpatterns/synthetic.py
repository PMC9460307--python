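"""Synthetic dietary-recall cohorts with planted temporal patterns.

Generates cohorts whose eating-event structure mirrors the four
temporal-dietary-pattern archetypes the analysis targets:

* archetype 1 — three moderate, evenly spaced occasions (about 08:00,
  13:00 and 18:00), every event strictly below 800 kcal;
* archetypes 2, 3, 4 — one dominant occasion (> 800 kcal) whose time
  falls in the afternoon (15:00-19:00), night (19:00 onward) or midday
  (05:00-15:00) window respectively, plus one or two minor occasions
  under 500 kcal.

Each participant also receives demographically plausible covariates
(survey cycle, sex, age group, race/ethnicity, income category),
anthropometrics for the energy-requirement calculation, a stratified
two-PSU-per-stratum survey design with lognormal weights, and BMI and
waist-circumference outcomes drawn from an additive linear model:
baseline + archetype shift + covariate shifts + misreporting slope +
Gaussian noise.  The default archetype shifts (about +3 kg/m2 BMI and
+8 cm WC for the single-peak archetypes relative to archetype 1) and
baselines (29.1 kg/m2, 97.7 cm) reproduce the effect magnitudes the
method is meant to detect.

Body weight and height are drawn independently of the BMI outcome and
are used only for the IOM energy requirement; generating weight from
the simulated BMI would make the misreporting ratio a descendant of the
outcome noise and bias adjusted cluster contrasts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .association import compute_eer
from .recall import RecallDay

__all__ = [
    "ArchetypeSpec",
    "CohortConfig",
    "default_archetypes",
    "generate_cohort",
    "generate_separability_variants",
    "write_cohort",
]

SEPARATION_LEVELS = ("well_separated", "moderate", "overlapping")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Event template for one archetype.

    The first entry of ``event_time_means``/``event_energy_means`` is
    the dominant occasion when ``peak_window`` is set; remaining entries
    are minor occasions included in order up to the drawn event count.
    ``energy_cap`` bounds every event strictly below the given kcal
    (archetype 1); ``dominant_energy_bounds`` bound the dominant event.
    """

    archetype_id: int
    event_count_distribution: dict[int, float]
    event_time_means: tuple[float, ...]
    event_time_sd: float
    event_energy_means: tuple[float, ...]
    event_energy_sds: tuple[float, ...]
    energy_cap: float | None = None
    peak_window: tuple[int, int] | None = None
    dominant_energy_bounds: tuple[float, float] = (801.0, 4000.0)
    minor_energy_bounds: tuple[float, float] = (50.0, 500.0)

    def __post_init__(self) -> None:
        probs = np.array(list(self.event_count_distribution.values()))
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("event_count_distribution must be a probability distribution")
        if max(self.event_count_distribution) > len(self.event_time_means):
            raise ValueError("more events requested than template slots")
        if len(self.event_time_means) != len(self.event_energy_means):
            raise ValueError("time and energy templates must align")


def default_archetypes(
    time_sd: float = 45.0,
    minor_energy_sd: float = 80.0,
    dominant_energy_sd: float = 300.0,
    cap_energy_sd: float = 100.0,
    dominant_low: float = 801.0,
    minor_high: float = 500.0,
    peak_count_probs: dict[int, float] | None = None,
) -> tuple[ArchetypeSpec, ...]:
    """The four archetype templates with adjustable dispersion.

    ``peak_count_probs`` is the event-count distribution of the
    single-peak archetypes (dominant occasion plus minors); event-count
    variability is itself a dispersion source for the alignment distance,
    so the well-separated regime pins it at three events.
    """
    if peak_count_probs is None:
        peak_count_probs = {2: 0.5, 3: 0.5}
    peak = (dominant_low, 4000.0)
    minor = (50.0, minor_high)
    return (
        ArchetypeSpec(
            archetype_id=1,
            event_count_distribution={3: 1.0},
            event_time_means=(480.0, 780.0, 1080.0),
            event_time_sd=time_sd,
            event_energy_means=(500.0, 500.0, 500.0),
            event_energy_sds=(cap_energy_sd,) * 3,
            energy_cap=800.0,
        ),
        ArchetypeSpec(
            archetype_id=2,
            event_count_distribution=dict(peak_count_probs),
            event_time_means=(1080.0, 480.0, 740.0),
            event_time_sd=time_sd,
            event_energy_means=(1500.0, 300.0, 300.0),
            event_energy_sds=(dominant_energy_sd, minor_energy_sd, minor_energy_sd),
            peak_window=(900, 1140),
            dominant_energy_bounds=peak,
            minor_energy_bounds=minor,
        ),
        ArchetypeSpec(
            archetype_id=3,
            event_count_distribution=dict(peak_count_probs),
            event_time_means=(1200.0, 480.0, 780.0),
            event_time_sd=time_sd,
            event_energy_means=(1500.0, 300.0, 300.0),
            event_energy_sds=(dominant_energy_sd, minor_energy_sd, minor_energy_sd),
            peak_window=(1140, 1440),
            dominant_energy_bounds=peak,
            minor_energy_bounds=minor,
        ),
        ArchetypeSpec(
            archetype_id=4,
            event_count_distribution=dict(peak_count_probs),
            event_time_means=(780.0, 480.0, 1110.0),
            event_time_sd=time_sd,
            event_energy_means=(1500.0, 300.0, 300.0),
            event_energy_sds=(dominant_energy_sd, minor_energy_sd, minor_energy_sd),
            peak_window=(300, 900),
            dominant_energy_bounds=peak,
            minor_energy_bounds=minor,
        ),
    )


# Table-style marginal frequencies keeping synthetic cohorts demographically
# plausible for US adults 20-65 y.
COVARIATE_LEVELS: dict[str, dict[str, float]] = {
    "survey_year": {
        "2007-2008": 0.200,
        "2009-2010": 0.217,
        "2011-2012": 0.192,
        "2013-2014": 0.200,
        "2015-2016": 0.191,
    },
    "sex": {"Male": 0.493, "Female": 0.507},
    "race_ethnicity": {
        "Mexican American": 0.170,
        "Other Hispanic": 0.100,
        "Non-Hispanic white": 0.403,
        "Non-Hispanic black": 0.220,
        "Other": 0.107,
    },
    "age_group": {"20-34": 0.322, "35-49": 0.330, "50-65": 0.348},
    "pir_category": {
        "0-0.99": 0.232,
        "1-1.99": 0.253,
        "2-2.99": 0.143,
        "3-3.99": 0.109,
        "4-4.99": 0.080,
        ">=5": 0.183,
    },
}

AGE_RANGES = {"20-34": (20, 34), "35-49": (35, 49), "50-65": (50, 65)}

# roughly centred additive covariate shifts on the outcomes
DEFAULT_COVARIATE_EFFECTS: dict[str, dict] = {
    "bmi": {
        "sex": {"Male": -0.4, "Female": 0.4},
        "age_group": {"20-34": -0.6, "35-49": 0.0, "50-65": 0.6},
        "race_ethnicity": {"Non-Hispanic black": 0.5, "Non-Hispanic white": -0.2},
        "pir_category": {"0-0.99": 0.5, ">=5": -0.5},
        "survey_year": {},
        "misreporting_ratio": -1.0,
    },
    "wc": {
        "sex": {"Male": 4.0, "Female": -4.0},
        "age_group": {"20-34": -2.0, "35-49": 0.0, "50-65": 2.0},
        "race_ethnicity": {"Non-Hispanic black": 1.0, "Non-Hispanic white": -0.5},
        "pir_category": {"0-0.99": 1.0, ">=5": -1.0},
        "survey_year": {},
        "misreporting_ratio": -2.5,
    },
}


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one reproducible synthetic cohort."""

    n_participants: int = 1000
    mixing_proportions: tuple[float, float, float, float] = (0.481, 0.178, 0.168, 0.173)
    archetypes: tuple[ArchetypeSpec, ...] = field(default_factory=default_archetypes)
    outcome_baselines: dict[str, float] = field(
        default_factory=lambda: {"bmi": 29.1, "wc": 97.7}
    )
    outcome_effects: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {"bmi": (0.0, 3.0, 3.3, 3.3), "wc": (0.0, 7.4, 8.2, 8.2)}
    )
    covariate_effects: dict[str, dict] = field(
        default_factory=lambda: DEFAULT_COVARIATE_EFFECTS
    )
    noise_sd: dict[str, float] = field(default_factory=lambda: {"bmi": 6.0, "wc": 13.0})
    n_strata: int = 15
    psus_per_stratum: int = 2
    weight_lognorm_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.mixing_proportions, dtype=float)
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("mixing proportions must be nonnegative and sum to 1")
        if len(self.archetypes) != len(p):
            raise ValueError("one archetype spec per mixing proportion")
        if self.n_strata <= 0 or self.psus_per_stratum <= 1:
            raise ValueError("need positive strata with >=2 PSUs each")


def _truncnorm(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_events(spec: ArchetypeSpec, n: int, rng: np.random.Generator):
    """Times (int minutes) and energies for n participants of one archetype."""
    slots = len(spec.event_time_means)
    counts = rng.choice(
        list(spec.event_count_distribution),
        size=n,
        p=list(spec.event_count_distribution.values()),
    )
    times = np.zeros((n, slots), dtype=int)
    energies = np.zeros((n, slots))
    for s in range(slots):
        dominant = spec.peak_window is not None and s == 0
        if dominant:
            t_low, t_high = spec.peak_window
        else:
            t_low, t_high = 0, 1440
        t = _truncnorm(rng, spec.event_time_means[s], spec.event_time_sd, t_low, t_high - 1, n)
        times[:, s] = np.clip(np.rint(t).astype(int), t_low, t_high - 1)
        if spec.energy_cap is not None:
            e_low, e_high = 50.0, spec.energy_cap - 1.0
        elif dominant:
            e_low, e_high = spec.dominant_energy_bounds
        else:
            e_low, e_high = spec.minor_energy_bounds
        energies[:, s] = _truncnorm(
            rng, spec.event_energy_means[s], spec.event_energy_sds[s], e_low, e_high, n
        )
    # de-duplicate clock times within a participant so merging cannot
    # manufacture a spurious >800 kcal event or an energy tie
    for i in range(n):
        used = set()
        for s in range(slots):
            t = int(times[i, s])
            while t in used:
                t = (t + 1) % 1440
            times[i, s] = t
            used.add(t)
    return counts, times, energies


def generate_cohort(config: CohortConfig):
    """Generate (recalls, participants, true_labels) for one cohort.

    Deterministic given ``config.seed``.  ``participants`` is a frame
    with covariates, survey-design fields, anthropometrics, the
    misreporting ratio, outcomes, and the true archetype label.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    arch = rng.choice(len(config.archetypes), size=n, p=config.mixing_proportions) + 1

    ids = [f"P{i:06d}" for i in range(n)]
    recalls: list[RecallDay | None] = [None] * n
    intake = np.zeros(n)
    for spec in config.archetypes:
        idx = np.flatnonzero(arch == spec.archetype_id)
        if idx.size == 0:
            continue
        counts, times, energies = _draw_events(spec, idx.size, rng)
        for row, i in enumerate(idx):
            evs = [
                (int(times[row, s]), float(energies[row, s]))
                for s in range(counts[row])
            ]
            recalls[i] = RecallDay(ids[i], evs)
            intake[i] = sum(e for _, e in evs)

    cov = {}
    for name, levels in COVARIATE_LEVELS.items():
        cov[name] = rng.choice(list(levels), size=n, p=list(levels.values()))
    lo = np.array([AGE_RANGES[g][0] for g in cov["age_group"]])
    hi = np.array([AGE_RANGES[g][1] for g in cov["age_group"]])
    age_years = rng.uniform(lo, hi + 1.0).clip(20.0, 65.0)

    male = cov["sex"] == "Male"
    height = np.where(male, rng.normal(1.757, 0.074, n), rng.normal(1.621, 0.069, n))
    height = height.clip(1.40, 2.10)
    body_weight = np.where(male, rng.normal(88.8, 16.0, n), rng.normal(76.4, 18.0, n))
    body_weight = body_weight.clip(40.0, 180.0)
    eer = np.array(
        [
            compute_eer(s, a, w, h)
            for s, a, w, h in zip(cov["sex"], age_years, body_weight, height)
        ]
    )
    mis = intake / eer

    # balanced round-robin survey design: every stratum gets both PSUs
    order = np.arange(n)
    stratum = order % config.n_strata
    psu = (order // config.n_strata) % config.psus_per_stratum
    weights = rng.lognormal(0.0, config.weight_lognorm_sigma, n)
    weights = weights / weights.sum() * n

    outcomes = {}
    for out in ("bmi", "wc"):
        y = np.full(n, config.outcome_baselines[out])
        y += np.asarray(config.outcome_effects[out])[arch - 1]
        eff = config.covariate_effects[out]
        for name in COVARIATE_LEVELS:
            shifts = eff.get(name, {})
            if shifts:
                y += np.array([shifts.get(v, 0.0) for v in cov[name]])
        y += eff.get("misreporting_ratio", 0.0) * (mis - 1.0)
        y += rng.normal(0.0, config.noise_sd[out], n)
        outcomes[out] = y

    participants = pd.DataFrame(
        {
            "participant_id": ids,
            **cov,
            "age_years": age_years,
            "height_m": height,
            "body_weight_kg": body_weight,
            "energy_intake_kcal": intake,
            "eer_kcal": eer,
            "misreporting_ratio": mis,
            "weight": weights,
            "stratum": stratum,
            "psu": psu,
            "bmi": outcomes["bmi"],
            "wc": outcomes["wc"],
            "true_label": arch,
        }
    )
    return recalls, participants, arch.copy()


def generate_separability_variants(config: CohortConfig, separation_level: str) -> CohortConfig:
    """Rescale archetype dispersions to a named separability regime.

    ``well_separated``: tight times (SD 25 min) and a dominant peak at
    least twice any minor event; ``moderate``: default-like dispersion
    (SD 60 min); ``overlapping``: time SDs of 150 min and energy
    distributions that blur the 800-kcal boundary.
    """
    if separation_level == "well_separated":
        archetypes = default_archetypes(
            time_sd=25.0,
            minor_energy_sd=60.0,
            dominant_energy_sd=200.0,
            cap_energy_sd=80.0,
            dominant_low=1000.0,
            minor_high=500.0,
            peak_count_probs={3: 1.0},
        )
    elif separation_level == "moderate":
        archetypes = default_archetypes(time_sd=60.0)
    elif separation_level == "overlapping":
        archetypes = default_archetypes(
            time_sd=150.0,
            minor_energy_sd=200.0,
            dominant_energy_sd=500.0,
            cap_energy_sd=250.0,
            dominant_low=801.0,
            minor_high=790.0,
        )
    else:
        raise ValueError(
            f"unknown separation level {separation_level!r}; choose from {SEPARATION_LEVELS}"
        )
    return dataclasses.replace(config, archetypes=archetypes)


def write_cohort(recalls, participants: pd.DataFrame, config: CohortConfig, outdir) -> None:
    """Persist events/participants as CSV and the config as YAML."""
    from pathlib import Path

    from .recall import events_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events_frame(recalls).to_csv(outdir / "events.csv", index=False)
    participants.to_csv(outdir / "participants.csv", index=False)
    cfg = dataclasses.asdict(config)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False, default_flow_style=None)
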
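"""Synthetic emergency-department-style encounter data.

Real shared-patient collaboration data comes from protected EHR extracts,
so the generator emulates the statistical structure the analysis needs at
desk scale:

* providers are organised into pools (shifts/teams); each encounter draws
  its team mostly from one pool, with a mixing fraction drawn from the
  whole roster.  Pooling makes some pairs share many encounters, which is
  what lets thresholded networks be non-trivial at this scale;
* team sizes follow a negative binomial (mean ≈ 9.2, SD ≈ 4.3, min 1),
  matching the provider-count profile of a large academic ED;
* each encounter gets an acuity level 1–5 (1 = resuscitation, rare in
  surveyed encounters; 3 = urgent, the median) and a binary outcome drawn
  from a logistic model on acuity, calibrated to ≈ 60% positive overall;
* optional *enriched* provider pairs: whenever both members are on an
  encounter's team, the positive-outcome probability is raised by δ
  (clipped to [0, 1]).  These planted effects are the ground truth for
  power/recovery tests; the null configuration has none, so outcomes are
  independent of provider identity.

Everything is reproducible: one seed drives a single generator stream, and
the emitted truth record stores every parameter and enriched-pair
identity.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from .types import EncounterRecord, ProviderEvent, ProviderRecord, canonical_pair

ACTIVITY_CATEGORIES = ("orders", "notes", "intake-output")
ACTION_TYPES = {
    "orders": ("order", "complete", "discontinued", "modified"),
    "notes": ("performed", "modified", "verified"),
    "intake-output": ("performed", "complete"),
}
PROVIDER_CATEGORIES = ("physician", "resident", "student", "nurse", "pharmacist", "other")
PROVIDER_CATEGORY_PROBS = (0.12, 0.18, 0.05, 0.50, 0.05, 0.10)


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class TeamSizeSpec:
    """Providers-per-encounter distribution.

    Negative binomial with the given mean and SD (truncated below at
    ``minimum``); ``sd = 0`` gives a constant team size.
    """

    mean: float = 9.2
    sd: float = 4.3
    minimum: int = 1

    def nb_params(self) -> tuple[float, float]:
        var = self.sd**2
        if var <= self.mean:
            raise ValueError("team-size variance must exceed the mean")
        n = self.mean**2 / (var - self.mean)
        p = n / (n + self.mean)
        return n, p


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic outcome model used for simulation.

    ``intercept`` is the log-odds at the reference acuity (level 3) and
    ``acuity_effects`` the per-level log-odds offsets.  The defaults give
    a marginal positive rate of ≈ 0.60 under the default acuity mix, with
    sicker patients (lower acuity number) less likely to report a top-box
    outcome.
    """

    intercept: float = logit(0.6)
    acuity_effects: tuple[tuple[int, float], ...] = (
        (1, -0.8),
        (2, -0.3),
        (3, 0.0),
        (4, 0.2),
        (5, 0.4),
    )

    def log_odds(self, acuity: int) -> float:
        return self.intercept + dict(self.acuity_effects).get(acuity, 0.0)

    def probability(self, acuity: int) -> float:
        return 1.0 / (1.0 + math.exp(-self.log_odds(acuity)))


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of one synthetic data set.

    ``mixing_rate`` is the expected fraction of each team drawn from the
    whole roster instead of the encounter's home pool.
    ``acuity_team_coupling`` (0 = off) scales mean team size by
    ``1 + coupling * (3 - acuity) / 2`` so sicker patients involve more
    providers.  ``enriched_pairs`` is a tuple of ((provider_a, provider_b),
    delta) entries; deltas are added on the probability scale for
    encounters whose team contains both members, then clipped.
    """

    n_providers: int = 150
    n_encounters: int = 3000
    team_size: TeamSizeSpec = TeamSizeSpec()
    n_pools: int = 8
    mixing_rate: float = 0.2
    acuity_levels: tuple[int, ...] = (1, 2, 3, 4, 5)
    acuity_probs: tuple[float, ...] = (0.01, 0.20, 0.50, 0.25, 0.04)
    acuity_team_coupling: float = 0.0
    outcome: OutcomeModel = OutcomeModel()
    enriched_pairs: tuple[tuple[tuple[str, str], float], ...] = ()
    actions_per_involvement_mean: float = 2.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_providers < 1 or self.n_encounters < 1:
            raise ValueError("n_providers and n_encounters must be >= 1")
        if not math.isclose(sum(self.acuity_probs), 1.0, abs_tol=1e-9):
            raise ValueError("acuity_probs must sum to 1")
        if not 0.0 <= self.mixing_rate <= 1.0:
            raise ValueError("mixing_rate must lie in [0, 1]")
        if self.n_pools < 1 or self.n_pools > self.n_providers:
            raise ValueError("n_pools must lie in [1, n_providers]")
        if self.team_size.sd == 0 and round(self.team_size.mean) > self.n_providers:
            raise ValueError("team size exceeds the provider roster")
        if self.team_size.minimum > self.n_providers:
            raise ValueError("minimum team size exceeds the provider roster")
        for (a, b), delta in self.enriched_pairs:
            canonical_pair(a, b)
            if not -1.0 <= delta <= 1.0:
                raise ValueError(f"delta {delta} out of range for pair ({a}, {b})")


@dataclass
class SyntheticData:
    """Generated tables plus the ground-truth record."""

    encounters: list[EncounterRecord]
    events: list[ProviderEvent]
    providers: list[ProviderRecord]
    truth: dict


def provider_id(i: int) -> str:
    return f"P{i:04d}"


def pool_assignment(config: GeneratorConfig) -> dict[str, int]:
    """Deterministic round-robin provider → pool map (independent of seed)."""
    return {provider_id(i): i % config.n_pools for i in range(config.n_providers)}


def null_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Default configuration with no enriched pairs (the calibration null)."""
    return GeneratorConfig(seed=seed, **overrides)


def enriched_config(
    n_pairs: int = 60,
    delta: float = 0.25,
    seed: int = 0,
    **overrides,
) -> GeneratorConfig:
    """Configuration with ``n_pairs`` disjoint within-pool enriched pairs.

    Pairs are chosen deterministically (consecutive members of each pool,
    cycling over pools) so they co-occur often enough to appear in
    thresholded networks; disjointness keeps the planted effects from
    interacting.
    """
    base = GeneratorConfig(seed=seed, **overrides)
    pools: list[list[str]] = [[] for _ in range(base.n_pools)]
    for pid, pool in pool_assignment(base).items():
        pools[pool].append(pid)
    capacity = sum(len(p) // 2 for p in pools)
    if n_pairs > capacity:
        raise ValueError(f"cannot place {n_pairs} disjoint within-pool pairs (max {capacity})")
    pairs: list[tuple[tuple[str, str], float]] = []
    depth = 0
    while len(pairs) < n_pairs:
        for pool in pools:
            if len(pairs) >= n_pairs:
                break
            if 2 * depth + 1 < len(pool):
                pairs.append((canonical_pair(pool[2 * depth], pool[2 * depth + 1]), delta))
        depth += 1
    return replace(base, enriched_pairs=tuple(pairs))


def _draw_team(
    rng: np.random.Generator,
    size: int,
    pool_members: Sequence[Sequence[int]],
    all_providers: np.ndarray,
    mixing_rate: float,
) -> np.ndarray:
    pool = int(rng.integers(len(pool_members)))
    home = np.asarray(pool_members[pool])
    size = min(size, len(all_providers))
    n_out = int(rng.binomial(size, mixing_rate))
    n_in = min(size - n_out, len(home))
    n_out = size - n_in
    team = list(rng.choice(home, size=n_in, replace=False))
    if n_out:
        outside = np.setdiff1d(all_providers, team, assume_unique=False)
        team.extend(rng.choice(outside, size=n_out, replace=False))
    return np.asarray(team)


def generate(config: GeneratorConfig) -> SyntheticData:
    """Generate encounters, provider events and provider records.

    The procedure per encounter: draw a home pool, a team size, team
    members (mostly from the pool), an acuity level, and an outcome from
    the logistic model, with enrichment applied when an enriched pair is
    fully on the team.  Each (provider, encounter) involvement then emits
    ``1 + Poisson(mean - 1)`` action rows with activity/action labels.
    """
    rng = np.random.default_rng(config.seed)
    pools_of = pool_assignment(config)
    pool_members: list[list[int]] = [[] for _ in range(config.n_pools)]
    for i in range(config.n_providers):
        pool_members[pools_of[provider_id(i)]].append(i)
    all_providers = np.arange(config.n_providers)
    constant_size = config.team_size.sd == 0
    nb_n = nb_p = 0.0
    if not constant_size:
        nb_n, nb_p = config.team_size.nb_params()
    enriched = [
        ((int(a[1:]), int(b[1:])), delta) for (a, b), delta in config.enriched_pairs
    ]

    cats = rng.choice(len(PROVIDER_CATEGORIES), size=config.n_providers, p=PROVIDER_CATEGORY_PROBS)
    providers = [
        ProviderRecord(
            provider_id(i),
            category=PROVIDER_CATEGORIES[cats[i]],
            position=PROVIDER_CATEGORIES[cats[i]].capitalize(),
        )
        for i in range(config.n_providers)
    ]

    encounters: list[EncounterRecord] = []
    events: list[ProviderEvent] = []
    n_positive = 0
    for j in range(config.n_encounters):
        eid = f"E{j:06d}"
        acuity = int(rng.choice(config.acuity_levels, p=config.acuity_probs))
        scale = 1.0 + config.acuity_team_coupling * (3 - acuity) / 2.0
        base_size = (
            round(config.team_size.mean)
            if constant_size
            else int(rng.negative_binomial(nb_n, nb_p))
        )
        size = max(config.team_size.minimum, round(base_size * scale))
        team = _draw_team(rng, size, pool_members, all_providers, config.mixing_rate)
        team_set = set(int(t) for t in team)

        p = config.outcome.probability(acuity)
        for (a, b), delta in enriched:
            if a in team_set and b in team_set:
                p += delta
        p = min(max(p, 0.0), 1.0)
        y = int(rng.random() < p)
        n_positive += y
        encounters.append(EncounterRecord(eid, y, {"acuity": acuity}))

        n_actions = 1 + rng.poisson(
            max(config.actions_per_involvement_mean - 1.0, 0.0), size=len(team)
        )
        for t, k in zip(team, n_actions):
            pid = provider_id(int(t))
            for _ in range(int(k)):
                cat = ACTIVITY_CATEGORIES[int(rng.integers(len(ACTIVITY_CATEGORIES)))]
                typ = ACTION_TYPES[cat][int(rng.integers(len(ACTION_TYPES[cat])))]
                events.append(ProviderEvent(pid, eid, cat, typ))

    truth = {
        "config": asdict(config),
        "pool_of": pools_of,
        "enriched_pairs": [
            {"pair": list(pair), "delta": delta} for pair, delta in config.enriched_pairs
        ],
        "n_positive": n_positive,
        "positive_rate": n_positive / config.n_encounters,
    }
    return SyntheticData(encounters, events, providers, truth)


def write_tables(data: SyntheticData, out_dir) -> dict[str, str]:
    """Write the generated tables in the CSV schemas the readers expect."""
    import csv
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "encounters": out / "encounters.csv",
        "events": out / "events.csv",
        "providers": out / "providers.csv",
        "truth": out / "truth.json",
    }
    with open(paths["encounters"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["encounter_id", "outcome", "acuity"])
        for enc in data.encounters:
            w.writerow([
                enc.encounter_id,
                "" if enc.outcome is None else enc.outcome,
                enc.covariates.get("acuity", ""),
            ])
    with open(paths["events"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["provider_id", "encounter_id", "activity_category", "action_type"])
        for ev in data.events:
            w.writerow([ev.provider_id, ev.encounter_id, ev.activity_category, ev.action_type])
    with open(paths["providers"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["provider_id", "category", "position"])
        for pr in data.providers:
            w.writerow([pr.provider_id, pr.category, pr.position])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(data.truth, fh, indent=2, default=str)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
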
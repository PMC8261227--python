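"""Synthetic colonies, competitive events and cooperation networks with
known ground truth.

The generator emulates the structure of a captive vampire-bat colony
study: a roster of adult females plus their captive-born young, a stream
of ~1000 dyadic competitive events at feeders of five behavioural types,
and dyadic kinship / grooming / food-sharing / co-observation matrices.

Ground truth is a latent dominance score per individual, by default
equally spaced on [0, 1].  Event winners follow a logistic model,
P(i beats j) = 1 / (1 + exp(-beta * (s_i - s_j))), so ``beta`` tunes the
hierarchy from none (0) to near-deterministic; the default beta = 2 gives
the weakly structured hierarchy typical of this system.  Cooperation
rates are log-normal seconds-per-trial with configurable kinship effect,
give/receive reciprocity correlation, and an optional rank bias, so both
null and structured regimes of the downstream network tests can be
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .events import EventTable, make_event_table, NIGHT_MINUTES
from .network import DyadicMatrix

# event-type mix observed at study scale: ci/ni/cd/nd/wait
DEFAULT_TYPE_COUNTS = (224, 250, 214, 109, 219)
EVENT_TYPE_ORDER = ("ci", "ni", "cd", "nd", "wait")


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults mirror the study conditions."""

    # colony composition
    n_adult_females: int = 24
    n_young_females: int = 5
    n_young_males: int = 4
    # latent hierarchy
    score_spacing: float | None = None  # None -> equally spaced on [0, 1]
    beta: float = 2.0
    # event stream
    n_events: int = 1023
    n_ambiguous: int = 0
    type_probs: tuple = tuple(
        c / sum(DEFAULT_TYPE_COUNTS) for c in DEFAULT_TYPE_COUNTS
    )
    dyad_dispersion: float | None = None  # None -> uniform dyad choice
    n_nights: int = 70
    # cooperation networks
    kinship_mean: float = 0.075
    kinship_shape: float = 0.5
    groom_scale: float = 10.0  # median seconds per trial
    share_scale: float = 5.0
    kinship_slope: float = 0.0  # effect of kinship on log helping rate
    reciprocity_rho: float = 0.0  # corr of give/receive noise within a dyad
    rank_bias: float = 0.0  # effect of (receiver - actor) score on log rate
    affinity_sd: float = 0.8  # dyad-level symmetric heterogeneity
    noise_sd: float = 0.5  # directed residual noise
    co_obs_mean: float = 20.0

    def __post_init__(self) -> None:
        if abs(sum(self.type_probs) - 1.0) > 1e-9:
            raise ValueError("event-type probabilities must sum to 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_adult_females + self.n_young_females + self.n_young_males


@dataclass
class GroundTruth:
    """Latent generating state, recoverable from (config, seed)."""

    scores: dict[str, float]
    order: list[str]  # highest to lowest latent score
    config: SyntheticConfig

    def score_array(self, ids: list[str]) -> np.ndarray:
        return np.array([self.scores[i] for i in ids])


def generate_colony(
    config: SyntheticConfig | None = None, seed=None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Roster with metadata plus latent dominance scores.

    Adult females are split between two source populations (~7:17); young
    are captive-born, one adult female flagged as mother per young.
    Forearm and mass are drawn from age-class-specific normal
    distributions.  Latent scores are equally spaced and assigned in
    random order, so roster position carries no rank information.
    """
    config = config or SyntheticConfig()
    n = config.n_total
    if n < 3:
        raise ValueError("colony must have at least 3 individuals")
    rng = np.random.default_rng(seed)
    ids, sex, age = [], [], []
    for k in range(config.n_adult_females):
        ids.append(f"F{k + 1:02d}")
        sex.append("F")
        age.append("adult")
    for k in range(config.n_young_females):
        ids.append(f"YF{k + 1:02d}")
        sex.append("F")
        age.append("young")
    for k in range(config.n_young_males):
        ids.append(f"YM{k + 1:02d}")
        sex.append("M")
        age.append("young")
    adult = np.array(age) == "adult"
    forearm = np.where(
        adult, rng.normal(53.5, 1.2, n), rng.normal(50.5, 1.5, n)
    ).round(1)
    mass = np.where(adult, rng.normal(37.0, 3.0, n), rng.normal(30.0, 3.0, n)).round(1)
    n_lp = round(config.n_adult_females * 7 / 24)
    population = []
    for k in range(n):
        if not adult[k]:
            population.append("captive_born")
        else:
            population.append("las_pavas" if k < n_lp else "tole")
    n_young = config.n_young_females + config.n_young_males
    mothers = set(
        rng.choice(
            config.n_adult_females,
            size=min(n_young, config.n_adult_females),
            replace=False,
        )
    )
    is_mother = [bool(k in mothers) if adult[k] else False for k in range(n)]
    roster = pd.DataFrame(
        {
            "id": ids,
            "sex": sex,
            "age_class": age,
            "forearm_mm": forearm,
            "mass_g": mass,
            "population": population,
            "is_mother": is_mother,
        }
    )
    spacing = (
        config.score_spacing
        if config.score_spacing is not None
        else (1.0 / (n - 1) if n > 1 else 1.0)
    )
    levels = np.arange(n) * spacing
    assignment = rng.permutation(n)
    scores = {ids[k]: float(levels[assignment[k]]) for k in range(n)}
    order = sorted(ids, key=lambda i: -scores[i])
    return roster, GroundTruth(scores, order, config)


def generate_events(
    roster: pd.DataFrame,
    truth: GroundTruth,
    config: SyntheticConfig | None = None,
    seed=None,
) -> EventTable:
    """Event stream under the logistic win model.

    Dyads are drawn uniformly (or with Gamma-distributed dyad weights when
    ``dyad_dispersion`` is set, mimicking heterogeneous encounter rates);
    each event gets a type from the five-type mix, a night, and a time
    uniform on the 900-minute recording window.  Optional ambiguous
    events (unidentified actors) are appended with type ``ambig``.
    """
    config = config or truth.config
    rng = np.random.default_rng(seed)
    ids = list(roster["id"])
    n = len(ids)
    s = truth.score_array(ids)
    iu, ju = np.triu_indices(n, k=1)
    n_dyads = len(iu)
    if config.dyad_dispersion is None:
        weights = np.full(n_dyads, 1.0 / n_dyads)
    else:
        w = rng.gamma(config.dyad_dispersion, 1.0, n_dyads)
        weights = w / w.sum()
    dyads = rng.choice(n_dyads, size=config.n_events, p=weights)
    i_arr, j_arr = iu[dyads], ju[dyads]
    p_i = 1.0 / (1.0 + np.exp(-config.beta * (s[i_arr] - s[j_arr])))
    i_wins = rng.random(config.n_events) < p_i
    winners = np.where(i_wins, i_arr, j_arr)
    losers = np.where(i_wins, j_arr, i_arr)
    types = rng.choice(EVENT_TYPE_ORDER, size=config.n_events, p=config.type_probs)
    nights = rng.integers(1, config.n_nights + 1, config.n_events)
    times = rng.uniform(0, NIGHT_MINUTES, config.n_events).round(1)
    df = pd.DataFrame(
        {
            "night": nights,
            "time_min": times,
            "winner": [ids[k] for k in winners],
            "loser": [ids[k] for k in losers],
            "type": types,
        }
    )
    if config.n_ambiguous:
        amb = pd.DataFrame(
            {
                "night": rng.integers(1, config.n_nights + 1, config.n_ambiguous),
                "time_min": rng.uniform(0, NIGHT_MINUTES, config.n_ambiguous).round(1),
                "winner": "?",
                "loser": "?",
                "type": "ambig",
            }
        )
        df = pd.concat([df, amb], ignore_index=True)
    df = df.sort_values(["night", "time_min"], kind="stable").reset_index(drop=True)
    return make_event_table(df, roster)


def generate_networks(
    roster: pd.DataFrame,
    truth: GroundTruth,
    config: SyntheticConfig | None = None,
    seed=None,
) -> dict[str, DyadicMatrix]:
    """Kinship, grooming, sharing and co-observation matrices.

    Kinship is symmetric Gamma-distributed (low mean, heavy tail —
    populations where most dyads are non-kin but some are close kin).
    Helping rates (seconds per fasting trial) are log-normal:
    log rate = log(scale) + kinship_slope * kin + rank_bias * (s_recv -
    s_actor) + dyad affinity + noise, with give/receive noise correlated
    by ``reciprocity_rho``.  Co-observation counts are Poisson.
    """
    config = config or truth.config
    rng = np.random.default_rng(seed)
    ids = list(roster["id"])
    n = len(ids)
    s = truth.score_array(ids)
    span = max(s.max() - s.min(), 1e-12)
    s_norm = (s - s.min()) / span
    iu, ju = np.triu_indices(n, k=1)

    kin_vals = rng.gamma(
        config.kinship_shape, config.kinship_mean / config.kinship_shape, len(iu)
    )
    kin_vals = np.clip(kin_vals, 0.0, 0.5)
    K = np.zeros((n, n))
    K[iu, ju] = kin_vals
    K += K.T

    def helping(scale: float) -> np.ndarray:
        affinity = np.zeros((n, n))
        affinity[iu, ju] = rng.normal(0.0, config.affinity_sd, len(iu))
        affinity += affinity.T
        cov = config.noise_sd**2 * np.array(
            [[1.0, config.reciprocity_rho], [config.reciprocity_rho, 1.0]]
        )
        eps_pairs = rng.multivariate_normal([0.0, 0.0], cov, len(iu))
        E = np.zeros((n, n))
        E[iu, ju] = eps_pairs[:, 0]
        E[ju, iu] = eps_pairs[:, 1]
        rank_term = config.rank_bias * (s_norm[None, :] - s_norm[:, None])
        R = np.exp(
            np.log(scale) + config.kinship_slope * K + rank_term + affinity + E
        )
        np.fill_diagonal(R, 0.0)
        return R

    grooming = helping(config.groom_scale)
    sharing = helping(config.share_scale)

    co = np.zeros((n, n))
    co[iu, ju] = rng.poisson(config.co_obs_mean, len(iu))
    co += co.T

    return {
        "kinship": DyadicMatrix(ids, K, "kinship", symmetric=True),
        "grooming": DyadicMatrix(ids, grooming, "grooming", symmetric=False),
        "sharing": DyadicMatrix(ids, sharing, "sharing", symmetric=False),
        "co_observation": DyadicMatrix(ids, co, "co_observation", symmetric=True),
    }


@dataclass
class SyntheticDataset:
    roster: pd.DataFrame
    truth: GroundTruth
    events: EventTable
    networks: dict[str, DyadicMatrix]
    seed: int | None = None


def generate_dataset(
    config: SyntheticConfig | None = None, seed=None
) -> SyntheticDataset:
    """Full colony + events + networks from one master seed (stage seeds
    are spawned deterministically)."""
    config = config or SyntheticConfig()
    ss = np.random.SeedSequence(seed)
    s_colony, s_events, s_networks = ss.spawn(3)
    roster, truth = generate_colony(config, seed=s_colony)
    events = generate_events(roster, truth, config, seed=s_events)
    networks = generate_networks(roster, truth, config, seed=s_networks)
    return SyntheticDataset(roster, truth, events, networks, seed)


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["type_probs"] = list(d["type_probs"])
    return d
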
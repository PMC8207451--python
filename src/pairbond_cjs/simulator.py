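"""Generator of correlated pair-bond mark-recapture datasets.

A population of ``n`` animals is given i.i.d. fair-coin sexes, males and
females are mated into as many monogamous pairs as possible, and everyone
is marked and released at the first of ``T`` sampling occasions (a single
cohort).  Each interval, an intact pair stays together with probability
``delta``; while together its survival and recapture fates are drawn from
the correlated bivariate-Bernoulli distributions of
:mod:`pairbond_cjs.joint_fates`, and while separated (or once widowed) its
members behave as independent CJS animals.  Death/permanent emigration is
absorbing and widows never re-pair.

With ``gamma = rho = 0`` (or ``delta = 0``) the generator reduces exactly
to the standard Cormack-Jolly-Seber data-generating process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .joint_fates import correlation_bounds, joint_fate_distribution

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "Entity",
    "CaptureDataset",
    "build_population",
    "mate_maximally",
    "simulate_dataset",
    "simulate_replicates",
    "empirical_history_frequencies",
    "derive_seed",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def derive_seed(base_seed: int, *key: int) -> int:
    """Deterministically derive a sub-seed below 2**31 from a base seed."""
    ss = np.random.SeedSequence((int(base_seed),) + tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the data-generating process.

    Defaults are the reference study conditions: 200 animals, 4 occasions,
    pairs always together, survival 0.7 and recapture 0.8 for both sexes,
    independence (gamma = rho = 0), 1000 replicates.
    """

    n: int = 200
    n_occasions: int = 4
    delta: float = 1.0
    phi_f: float = 0.7
    phi_m: float = 0.7
    p_f: float = 0.8
    p_m: float = 0.8
    gamma: float = 0.0
    rho: float = 0.0
    n_replicates: int = 1000
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n < 2:
            raise ConfigurationError(f"n must be >= 2, got {self.n}")
        if self.n_occasions < 2:
            raise ConfigurationError(
                f"n_occasions must be >= 2, got {self.n_occasions}"
            )
        if self.n_replicates < 1:
            raise ConfigurationError(
                f"n_replicates must be >= 1, got {self.n_replicates}"
            )
        for name in ("delta", "phi_f", "phi_m", "p_f", "p_m"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} must lie in [0, 1]")
        for corr, pair, label in (
            (self.gamma, (self.phi_f, self.phi_m), "gamma"),
            (self.rho, (self.p_f, self.p_m), "rho"),
        ):
            if 0.0 < pair[0] < 1.0 and 0.0 < pair[1] < 1.0:
                bounds = correlation_bounds(pair)
                if not bounds.contains(corr):
                    raise ConfigurationError(
                        f"{label}={corr} outside admissible interval "
                        f"[{bounds.lower:.6g}, {bounds.upper:.6g}] "
                        f"for marginals {pair}"
                    )
        return self

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (and re-validated)."""
        return replace(self, **kwargs).validate()


@dataclass(frozen=True)
class Entity:
    """A mated pair or an unmated single animal."""

    entity_id: int
    member_ids: tuple[int, ...]
    sexes: tuple[str, ...]

    @property
    def kind(self) -> str:
        return "pair" if len(self.member_ids) == 2 else "single"


@dataclass
class CaptureDataset:
    """Single-cohort encounter histories with sex and pair labels.

    ``histories`` is the n x T binary capture matrix (1 = captured),
    ``sex`` holds 'M'/'F' labels, ``entity_index`` maps each individual to
    its entity (pair members share an index), and ``first_capture`` is the
    0-based occasion of first release.
    """

    histories: np.ndarray
    sex: np.ndarray
    entity_index: np.ndarray
    first_capture: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.histories = np.asarray(self.histories, dtype=np.int8)
        self.sex = np.asarray(self.sex)
        self.entity_index = np.asarray(self.entity_index, dtype=np.int64)
        if self.first_capture is None:
            self.first_capture = np.argmax(self.histories == 1, axis=1)
        self.first_capture = np.asarray(self.first_capture, dtype=np.int64)
        if not (self.histories.sum(axis=1) > 0).all():
            raise ValueError("every individual must be captured at least once")

    @property
    def n_individuals(self) -> int:
        return self.histories.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.histories.shape[1]

    def history_strings(self) -> list[str]:
        return ["".join(map(str, row)) for row in self.histories]


def mate_maximally(sexes: Sequence[str], rng: np.random.Generator) -> list[Entity]:
    """Mate males and females into as many pairs as possible.

    With #M males and #F females there are min(#M, #F) pairs and the
    leftover majority-sex animals remain single, for m = n - min(#M, #F)
    entities.  Pair assignment is randomized within the given RNG stream
    (distribution-neutral here because all pairs share parameters).
    """
    sexes = np.asarray(sexes)
    males = rng.permutation(np.flatnonzero(sexes == "M"))
    females = rng.permutation(np.flatnonzero(sexes == "F"))
    n_pairs = min(len(males), len(females))
    entities: list[Entity] = []
    for j in range(n_pairs):
        f, m = int(females[j]), int(males[j])
        entities.append(Entity(len(entities), (f, m), ("F", "M")))
    for i in males[n_pairs:]:
        entities.append(Entity(len(entities), (int(i),), ("M",)))
    for i in females[n_pairs:]:
        entities.append(Entity(len(entities), (int(i),), ("F",)))
    return entities


def build_population(config: SimulationConfig, rng: np.random.Generator) -> list[Entity]:
    """Draw fair-coin sexes and mate males and females maximally."""
    config.validate()
    sexes = np.where(rng.integers(0, 2, size=config.n) == 1, "M", "F")
    return mate_maximally(sexes, rng)


def _categorical(rng: np.random.Generator, cum_rows: np.ndarray) -> np.ndarray:
    """Draw one outcome per row from rows of cumulative probabilities."""
    u = rng.random(cum_rows.shape[0])
    return (u[:, None] >= cum_rows[:, :-1]).sum(axis=1)


def simulate_dataset(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    keep_latent: bool = False,
) -> CaptureDataset:
    """Simulate one single-cohort dataset from the correlated-pair model.

    Per interval t-1 -> t each intact pair draws a togetherness indicator
    d ~ Bernoulli(delta) which conditions both its joint survival draw and
    the joint recapture draw at occasion t; a pair that loses a member (or
    an animal that never had one) survives and is recaptured through
    independent Bernoulli draws.  Everyone is captured at occasion 1.

    Latent alive states are internal to the simulation; ``keep_latent``
    attaches them to the returned dataset as an ``alive`` attribute
    (n x T boolean matrix) for diagnostics and testing.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, T = config.n, config.n_occasions

    entities = build_population(config, rng)
    pair_f = np.array(
        [e.member_ids[0] for e in entities if e.kind == "pair"], dtype=np.int64
    )
    pair_m = np.array(
        [e.member_ids[1] for e in entities if e.kind == "pair"], dtype=np.int64
    )

    entity_index = np.empty(n, dtype=np.int64)
    for e in entities:
        for i in e.member_ids:
            entity_index[i] = e.entity_id
    sex = np.full(n, "F")
    for e in entities:
        for i, s in zip(e.member_ids, e.sexes):
            sex[i] = s
    is_female = sex == "F"

    # Outcome distributions are state-homogeneous, so precompute the
    # cumulative 4-vectors for together/separated pairs once.
    surv = {
        t: np.cumsum(
            joint_fate_distribution(
                (config.phi_f, config.phi_m), config.gamma, together=t
            ).as_array()
        )
        for t in (True, False)
    }
    recap = {
        t: np.cumsum(
            joint_fate_distribution(
                (config.p_f, config.p_m), config.rho, together=t
            ).as_array()
        )
        for t in (True, False)
    }

    alive = np.ones(n, dtype=bool)
    histories = np.zeros((n, T), dtype=np.int8)
    histories[:, 0] = 1
    alive_trace = np.ones((n, T), dtype=bool) if keep_latent else None

    phi = np.where(is_female, config.phi_f, config.phi_m)
    p = np.where(is_female, config.p_f, config.p_m)

    for t in range(1, T):
        intact = alive[pair_f] & alive[pair_m]
        f_idx, m_idx = pair_f[intact], pair_m[intact]
        together = rng.random(f_idx.size) < config.delta

        # Joint survival draw for intact pairs.
        cum = np.where(together[:, None], surv[True], surv[False])
        outcome = _categorical(rng, cum)
        alive[m_idx[(outcome == 1) | (outcome == 3)]] = False
        alive[f_idx[(outcome == 2) | (outcome == 3)]] = False

        # Widows, singles, and members of already-broken pairs survive
        # independently.
        solo = alive.copy()
        solo[f_idx] = False
        solo[m_idx] = False
        solo_idx = np.flatnonzero(solo)
        survives = rng.random(solo_idx.size) < phi[solo_idx]
        alive[solo_idx[~survives]] = False

        # Joint recapture draw for pairs still intact after survival,
        # conditioned on the same togetherness indicator.
        still = alive[f_idx] & alive[m_idx]
        sf, sm = f_idx[still], m_idx[still]
        cum = np.where(together[still][:, None], recap[True], recap[False])
        outcome = _categorical(rng, cum)
        histories[sf[(outcome == 0) | (outcome == 1)], t] = 1
        histories[sm[(outcome == 0) | (outcome == 2)], t] = 1

        # Everyone else alive is captured independently.
        other = alive.copy()
        other[sf] = False
        other[sm] = False
        other_idx = np.flatnonzero(other)
        caught = rng.random(other_idx.size) < p[other_idx]
        histories[other_idx[caught], t] = 1

        if alive_trace is not None:
            alive_trace[:, t] = alive

    dataset = CaptureDataset(histories, sex, entity_index)
    if alive_trace is not None:
        dataset.alive = alive_trace
    return dataset


def simulate_replicates(
    config: SimulationConfig, n_replicates: int | None = None
) -> Iterator[CaptureDataset]:
    """Yield independent replicate datasets from reproducible substreams.

    Replicate k uses the RNG stream spawned as child k of the
    configuration seed, so identical seeds give bit-identical output and
    replicates are mutually independent.
    """
    config.validate()
    K = config.n_replicates if n_replicates is None else int(n_replicates)
    if K < 1:
        raise ConfigurationError(f"replicate count must be >= 1, got {K}")
    children = np.random.SeedSequence(config.seed).spawn(K)
    for child in children:
        yield simulate_dataset(config, np.random.default_rng(child))


def empirical_history_frequencies(data: CaptureDataset) -> dict[str, float]:
    """Relative frequency of each observed encounter history."""
    if data.n_individuals == 0:
        raise ValueError("dataset is empty")
    strings, counts = np.unique(data.history_strings(), return_counts=True)
    total = counts.sum()
    return {str(s): float(c / total) for s, c in zip(strings, counts)}
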
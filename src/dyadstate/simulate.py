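"""Ground-truth-known synthetic studies of foraging dyads.

Generates boldness populations, assembles pairs into the four
boldness-ratio categories, builds per-pair transition-intensity models via
a documented boldness link, and simulates pre/post-satiation sessions by
exact (Gillespie) simulation of the same continuous-time Markov chain that
the inference module fits -- so parameter recovery is well-specified by
construction.

Boldness link (an implementation choice, not an empirical claim):

    log q_leave  = a_leave  + b_leave  * boldness   (of the fish that moves)
    log q_return = a_return - b_return * boldness

Leaving rates therefore increase, and returning rates decrease, with the
mover's boldness.  Satiation acts multiplicatively (log-linearly) on the
configured edges of the satiated (focal) fish's session.

Reproducibility: one root seed; every stream is a child generator derived
with ``SeedSequence(seed, spawn_key=(stream_id,))`` where stream id 0 draws
the boldness population, 1 drives pair assembly, and pair ``i`` session
``s`` (0 = control, 1 = satiated) uses ``10 + 2*i + s`` -- independent of
generation order.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ctmc import Edge, IntensityModel
from .eventlog import (
    PERMITTED_EDGES,
    PairTrajectory,
    SessionMeta,
    TransitionEvent,
    write_event_log,
    write_sessions,
)
from .metrics import categorize_pair

__all__ = [
    "StudyConfig",
    "StudyData",
    "generate_boldness_population",
    "assemble_pairs",
    "build_pair_model",
    "simulate_trajectory",
    "generate_study",
    "write_study",
]

#: ratio bands (lo, hi) on focal/partner boldness; None = unbounded
_CATEGORY_BANDS: dict[str, tuple[float | None, float | None]] = {
    "SM": (0.70, 0.85),
    "SL": (None, 0.50),
    "BM": (1.15, 1.40),
    "BL": (2.00, None),
}

#: follow edges (a fish joining its already-out partner)
FOLLOW_EDGES: tuple[Edge, Edge] = ((2, 4), (3, 4))

_FOCAL_LEAVE: tuple[Edge, Edge] = ((1, 2), (3, 4))
_FOCAL_RETURN: tuple[Edge, Edge] = ((2, 1), (4, 3))
_PARTNER_LEAVE: tuple[Edge, Edge] = ((1, 3), (2, 4))
_PARTNER_RETURN: tuple[Edge, Edge] = ((3, 1), (4, 2))


def _edge_key(e: Edge) -> str:
    return f"{e[0]}->{e[1]}"


def _parse_edge(text: str) -> Edge:
    a, b = text.split("->")
    return (int(a), int(b))


@dataclass(frozen=True)
class StudyConfig:
    """Full description of a synthetic study; every field has a default.

    The default quotas (14/11/25/10) and two 2-hour sessions per pair match
    the emulated study design; the default boldness distribution is a Beta
    with mean 0.31 whose 2.5th-97.5th percentiles span roughly 0.02-0.81.
    """

    n_pairs_per_category: Mapping[str, int] = field(
        default_factory=lambda: {"SM": 14, "SL": 11, "BM": 25, "BL": 10}
    )
    session_duration: float = 7200.0
    population_size: int = 360
    boldness_mean: float = 0.31
    boldness_shape_a: float = 1.2
    a_leave: float = -5.4
    b_leave: float = 3.2
    a_return: float = -3.2
    b_return: float = 1.6
    satiation_effects: Mapping[Edge, float] = field(
        default_factory=lambda: {(1, 2): -1.0, (3, 4): -1.0}
    )
    responsiveness: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        if not 0 < self.boldness_mean < 1:
            raise ValueError("boldness_mean must lie in (0, 1)")
        if self.boldness_shape_a <= 0:
            raise ValueError("boldness_shape_a must be positive")
        if self.responsiveness <= 0:
            raise ValueError("responsiveness must be positive")
        for cat in self.n_pairs_per_category:
            if cat not in _CATEGORY_BANDS:
                raise ValueError(f"unknown category {cat!r}")
        for e in self.satiation_effects:
            if e not in PERMITTED_EDGES:
                raise ValueError(f"satiation effect on forbidden edge {e}")

    @property
    def boldness_shape_b(self) -> float:
        return self.boldness_shape_a * (1.0 - self.boldness_mean) / self.boldness_mean

    def to_dict(self) -> dict:
        return {
            "n_pairs_per_category": dict(self.n_pairs_per_category),
            "session_duration": self.session_duration,
            "population_size": self.population_size,
            "boldness_mean": self.boldness_mean,
            "boldness_shape_a": self.boldness_shape_a,
            "a_leave": self.a_leave,
            "b_leave": self.b_leave,
            "a_return": self.a_return,
            "b_return": self.b_return,
            "satiation_effects": {
                _edge_key(e): v for e, v in self.satiation_effects.items()
            },
            "responsiveness": self.responsiveness,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "StudyConfig":
        data = dict(data)
        unknown = set(data) - set(cls().to_dict())
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "satiation_effects" in data:
            data["satiation_effects"] = {
                _parse_edge(k) if isinstance(k, str) else tuple(k): float(v)
                for k, v in data["satiation_effects"].items()
            }
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _session_stream(pair_index: int, session_index: int) -> int:
    return 10 + 2 * pair_index + session_index


def generate_boldness_population(
    n: int, config: StudyConfig | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` boldness scores from the configured Beta distribution.

    Scores are clipped away from exactly 0/1 so every implied intensity is
    positive and finite.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or StudyConfig()
    if rng is None:
        rng = _child_rng(config.seed, 0)
    scores = rng.beta(config.boldness_shape_a, config.boldness_shape_b, size=n)
    return np.clip(scores, 1e-4, 1.0 - 1e-4)


def assemble_pairs(
    population: Sequence[float],
    config: StudyConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float, str]]:
    """Fill the category quotas with (focal, partner) pairs from a population.

    Each fish is used at most once.  Pairs are found by randomized greedy
    search; a quota that cannot be filled raises with the deficient category
    named.  Every returned pair re-checks against :func:`categorize_pair`.
    """
    config = config or StudyConfig()
    if rng is None:
        rng = _child_rng(config.seed, 1)
    scores = np.asarray(population, dtype=float)
    order = rng.permutation(len(scores))
    used = np.zeros(len(scores), dtype=bool)
    out: list[tuple[float, float, str]] = []
    # harder (narrow/extreme) bands first so easy bands do not starve them
    for cat in ("BL", "SL", "SM", "BM"):
        quota = int(config.n_pairs_per_category.get(cat, 0))
        for _ in range(quota):
            found = False
            for i in order:
                if used[i]:
                    continue
                for j in order:
                    if used[j] or i == j:
                        continue
                    if categorize_pair(scores[i], scores[j]) == cat:
                        used[i] = used[j] = True
                        out.append((float(scores[i]), float(scores[j]), cat))
                        found = True
                        break
                if found:
                    break
            if not found:
                raise ValueError(
                    f"cannot fill quota for category {cat} from population of "
                    f"{len(scores)} (got {sum(1 for p in out if p[2] == cat)})"
                )
    # restore requested category order
    cat_rank = {c: k for k, c in enumerate(config.n_pairs_per_category)}
    out.sort(key=lambda p: cat_rank.get(p[2], 99))
    return out


def build_pair_model(
    focal_boldness: float, partner_boldness: float, config: StudyConfig | None = None
) -> IntensityModel:
    """Intensity model for one pair under the boldness link.

    The focal fish moves on edges 1->2, 2->1, 3->4, 4->3; the partner on
    1->3, 3->1, 2->4, 4->2.  Leave rates are log-linear increasing in the
    mover's boldness, return rates log-linear decreasing; the optional
    ``responsiveness`` multiplier scales the two follow edges (2->4, 3->4).
    """
    config = config or StudyConfig()
    for b, who in ((focal_boldness, "focal"), (partner_boldness, "partner")):
        if not 0.0 < b <= 1.0:
            raise ValueError(f"{who} boldness {b} outside (0, 1]")
    q_leave = lambda b: math.exp(config.a_leave + config.b_leave * b)
    q_return = lambda b: math.exp(config.a_return - config.b_return * b)
    baseline: dict[Edge, float] = {}
    for e in _FOCAL_LEAVE:
        baseline[e] = q_leave(focal_boldness)
    for e in _FOCAL_RETURN:
        baseline[e] = q_return(focal_boldness)
    for e in _PARTNER_LEAVE:
        baseline[e] = q_leave(partner_boldness)
    for e in _PARTNER_RETURN:
        baseline[e] = q_return(partner_boldness)
    for e in FOLLOW_EDGES:
        baseline[e] *= config.responsiveness
    return IntensityModel(
        baseline=baseline, effects={"satiated": dict(config.satiation_effects)}
    )


def simulate_trajectory(
    model: IntensityModel,
    covariates: Mapping[str, float] | None = None,
    duration: float = 7200.0,
    initial_state: int = 1,
    seed: int | np.random.Generator = 0,
    pair_id: str = "sim",
    session: str = "control",
) -> PairTrajectory:
    """Exact stochastic simulation of the dyad chain over ``[0, duration)``.

    Holding times are exponential with the current state's exit rate; the
    next state is chosen with probability proportional to its intensity.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = {e: model.intensity(e, covariates) for e in model.baseline}
    # per-state exit rate, destinations and cumulative choice probabilities
    lam = np.zeros(5)
    dests: list[list[int]] = [[] for _ in range(5)]
    cum: list[np.ndarray] = [np.array([]) for _ in range(5)]
    for s in (1, 2, 3, 4):
        out = [(j, rates.get((s, j), 0.0)) for (i, j) in PERMITTED_EDGES if i == s]
        total = sum(r for _, r in out)
        lam[s] = total
        dests[s] = [j for j, _ in out]
        if total > 0:
            cum[s] = np.cumsum([r for _, r in out]) / total

    events: list[TransitionEvent] = []
    t = 0.0
    state = initial_state
    while True:
        if lam[state] <= 0.0:
            break
        t += rng.exponential(1.0 / lam[state])
        if t >= duration:
            break
        u = rng.random()
        nxt = dests[state][int(np.searchsorted(cum[state], u, side="right"))]
        events.append(TransitionEvent(time=t, from_state=state, to_state=nxt))
        state = nxt
    return PairTrajectory(
        pair_id=pair_id,
        session=session,
        duration=duration,
        initial_state=initial_state,
        events=events,
    )


@dataclass
class StudyData:
    """A complete simulated study plus its generating ground truth."""

    trajectories: list[PairTrajectory]
    sessions: list[SessionMeta]
    ground_truth: dict


def generate_study(config: StudyConfig | None = None) -> StudyData:
    """Simulate the full two-session study for every configured pair.

    Each pair gets a control session (``satiated = 0``) and a satiated
    session (``satiated = 1``, satiation effects applied to the configured
    edges).  The ground-truth record echoes the config and lists every
    pair's boldness and true intensities.
    """
    config = config or StudyConfig()
    population = generate_boldness_population(config.population_size, config)
    pairs = assemble_pairs(population, config)

    trajectories: list[PairTrajectory] = []
    sessions: list[SessionMeta] = []
    truth_pairs: list[dict] = []
    serial: dict[str, int] = {}
    for idx, (focal_b, partner_b, cat) in enumerate(pairs):
        serial[cat] = serial.get(cat, 0) + 1
        pair_id = f"{cat}{serial[cat]:02d}"
        model = build_pair_model(focal_b, partner_b, config)
        for s_idx, (label, satiated) in enumerate((("control", 0), ("satiated", 1))):
            rng = _child_rng(config.seed, _session_stream(idx, s_idx))
            traj = simulate_trajectory(
                model,
                covariates={"satiated": satiated},
                duration=config.session_duration,
                initial_state=1,
                seed=rng,
                pair_id=pair_id,
                session=label,
            )
            trajectories.append(traj)
            sessions.append(
                SessionMeta(
                    pair_id=pair_id,
                    session=label,
                    duration=config.session_duration,
                    initial_state=1,
                    focal_boldness=focal_b,
                    partner_boldness=partner_b,
                    focal_satiated=satiated,
                    category=cat,
                )
            )
        truth_pairs.append(
            {
                "pair_id": pair_id,
                "category": cat,
                "focal_boldness": focal_b,
                "partner_boldness": partner_b,
                "baseline": {_edge_key(e): q for e, q in model.baseline.items()},
            }
        )
    ground_truth = {
        "config": config.to_dict(),
        "satiation_effects": {
            _edge_key(e): v for e, v in config.satiation_effects.items()
        },
        "pairs": truth_pairs,
    }
    return StudyData(trajectories=trajectories, sessions=sessions, ground_truth=ground_truth)


def write_study(study: StudyData, out_dir: str | Path) -> dict[str, Path]:
    """Write events.csv, sessions.csv and ground_truth.json under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out / "events.csv",
        "sessions": out / "sessions.csv",
        "ground_truth": out / "ground_truth.json",
    }
    write_event_log(study.trajectories, paths["events"])
    write_sessions(study.sessions, paths["sessions"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(study.ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
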
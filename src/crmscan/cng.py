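"""Neuroevolutionary categorization of CRE pairs by their positional features.

Small two-class feedforward networks (three numeric inputs: Bowley skewness,
distance-test p, order-test p; one sigmoid hidden layer; one Heaviside output
neuron) are evolved — weights and biases only, never the structure — to carve
out categories of positive pairs. A network's fitness is the ratio of
positive to random points it includes, with a hard veto if it includes any of
the three fixed negative-control points, and ties broken toward larger
categories. Training proceeds in cycles; each cycle must cover at least one
previously uncovered positive, and training ends when every positive is
covered by some network.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

logger = logging.getLogger(__name__)

#: Input order fed to the networks.
INPUT_NAMES = ("bowley", "distance_p", "order_p")

#: The three fixed negative-control points: p-values of 1 and Bowley
#: skewness of -1, 0 and 1.
NEGATIVE_CONTROLS = np.array(
    [[-1.0, 1.0, 1.0], [0.0, 1.0, 1.0], [1.0, 1.0, 1.0]]
)

#: Neutral point substituted for pairs whose statistics cannot be computed.
NEUTRAL_POINT = (0.0, 1.0, 1.0)


def _sigmoid(t: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-t))


@dataclass
class NeuralNet:
    """3-input, sigmoid-hidden, Heaviside-output two-class network."""

    w: np.ndarray  # (n_hidden, 3) hidden weights
    b_h: np.ndarray  # (n_hidden,) hidden biases
    v: np.ndarray  # (n_hidden,) output weights
    b_out: float  # output bias

    @property
    def n_hidden(self) -> int:
        return self.w.shape[0]

    def forward(self, inputs: Sequence[float]) -> int:
        """Classify one (bowley, distance_p, order_p) triple into {0, 1}.

        hidden_j = s(bias_j + sum_k w_jk * input_k), s(t) = 1/(1 + e^-t);
        output = h(b + sum_j v_j * hidden_j) with Heaviside h(x) = 1 iff x >= 0.
        """
        x = np.asarray(inputs, dtype=float)
        hidden = _sigmoid(self.b_h + self.w @ x)
        return int(self.b_out + self.v @ hidden >= 0)

    def includes(self, points: np.ndarray) -> np.ndarray:
        """Vectorized forward pass over an (N, 3) array -> boolean mask."""
        hidden = _sigmoid(self.b_h[None, :] + points @ self.w.T)
        return (self.b_out + hidden @ self.v) >= 0

    # -- flat parameter view used by the mutation operators ------------------

    def flat(self) -> np.ndarray:
        return np.concatenate([self.w.ravel(), self.b_h, self.v, [self.b_out]])

    @classmethod
    def from_flat(cls, params: np.ndarray, n_hidden: int) -> "NeuralNet":
        nw = n_hidden * 3
        return cls(
            w=params[:nw].reshape(n_hidden, 3).copy(),
            b_h=params[nw : nw + n_hidden].copy(),
            v=params[nw + n_hidden : nw + 2 * n_hidden].copy(),
            b_out=float(params[-1]),
        )

    def to_dict(self) -> dict:
        return {
            "n_hidden": self.n_hidden,
            "w": self.w.tolist(),
            "b_h": self.b_h.tolist(),
            "v": self.v.tolist(),
            "b_out": self.b_out,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuralNet":
        return cls(
            np.array(d["w"], dtype=float),
            np.array(d["b_h"], dtype=float),
            np.array(d["v"], dtype=float),
            float(d["b_out"]),
        )


@dataclass
class CngParams:
    """Tunable training settings (all user-overridable)."""

    n_hidden: int = 3
    population: int = 50
    top_k: int = 10
    fresh_per_round: int = 10
    patience: int = 15
    init_low: float = -5.0
    init_high: float = 5.0
    step: float = 0.1
    cycle_cap: int = 50


@dataclass
class TrainingSet:
    """Positives (candidate pairs' statistics), the three negative controls, and
    random pairs' statistics on the same promoter set."""

    positives: np.ndarray  # (N, 3) in INPUT_NAMES order
    positive_keys: list[str]
    randoms: np.ndarray  # (M, 3)
    random_keys: list[str] = field(default_factory=list)
    negatives: np.ndarray = field(default_factory=lambda: NEGATIVE_CONTROLS.copy())

    def __post_init__(self) -> None:
        self.positives = np.atleast_2d(np.asarray(self.positives, dtype=float))
        self.randoms = np.atleast_2d(np.asarray(self.randoms, dtype=float))
        if self.positives.shape[1] != 3:
            raise ValueError("positives must be (N, 3)")
        if len(self.positive_keys) != len(self.positives):
            raise ValueError("one key per positive required")
        for p in self.positives:
            if any(np.allclose(p, neg) for neg in self.negatives):
                raise ValueError(
                    f"positive {p.tolist()} coincides with a negative control; "
                    "coverage is impossible"
                )


def stats_to_point(stat) -> tuple[float, float, float]:
    """(bowley, distance_p, order_p) with not-computed fields at neutral."""
    return (
        NEUTRAL_POINT[0] if stat.bowley is None else float(stat.bowley),
        NEUTRAL_POINT[1] if stat.distance_p is None else float(stat.distance_p),
        NEUTRAL_POINT[2] if stat.order_p is None else float(stat.order_p),
    )


VETO_SCORE = (0, 0.0, 0)


def score(
    net: NeuralNet, training_set: TrainingSet, uncovered: np.ndarray | None = None
) -> tuple[int, float, int]:
    """Ordered fitness: (gate, positives/randoms ratio, total included).

    gate = 0 (the lowest possible score) if the network includes any negative
    control — or, when an ``uncovered`` mask is given, if it covers no
    previously uncovered positive. Larger tuples rank higher.
    """
    if net.includes(training_set.negatives).any():
        return VETO_SCORE
    pos_in = net.includes(training_set.positives)
    if uncovered is not None and not pos_in[uncovered].any():
        return VETO_SCORE
    n_pos = int(pos_in.sum())
    n_rand = int(net.includes(training_set.randoms).sum()) if len(training_set.randoms) else 0
    return (1, n_pos / max(n_rand, 1), n_pos + n_rand)


def random_net(params: CngParams, rng: np.random.Generator) -> NeuralNet:
    n_params = params.n_hidden * 5 + 1
    return NeuralNet.from_flat(
        rng.uniform(params.init_low, params.init_high, size=n_params), params.n_hidden
    )


def mutate(
    net: NeuralNet,
    rng: np.random.Generator,
    params: CngParams,
    partner: NeuralNet | None = None,
) -> NeuralNet:
    """One variation step: incremental (+-step on one parameter), disruptive
    (resample one parameter from the init range), or crossover (per-parameter
    coin flip between two parents). Structure never changes."""
    modes = ["incremental", "disruptive"] + (["crossover"] if partner is not None else [])
    mode = modes[int(rng.integers(0, len(modes)))]
    flat = net.flat()
    if mode == "crossover":
        other = partner.flat()
        pick = rng.integers(0, 2, size=flat.size).astype(bool)
        child = np.where(pick, flat, other)
        return NeuralNet.from_flat(child, net.n_hidden)
    i = int(rng.integers(0, flat.size))
    if mode == "incremental":
        flat[i] += params.step if rng.integers(0, 2) else -params.step
    else:
        flat[i] = rng.uniform(params.init_low, params.init_high)
    return NeuralNet.from_flat(flat, net.n_hidden)


def train_cycle(
    training_set: TrainingSet,
    params: CngParams,
    rng: np.random.Generator,
    uncovered: np.ndarray | None = None,
) -> tuple[NeuralNet, tuple[int, float, int]]:
    """Run rounds of score/select/vary until the best score stagnates for
    ``patience`` rounds; return the best network of the cycle."""
    population = [random_net(params, rng) for _ in range(params.population)]
    best_score = VETO_SCORE
    stagnant = 0
    while True:
        scored = sorted(
            ((score(net, training_set, uncovered), j, net) for j, net in enumerate(population)),
            key=lambda t: (t[0], -t[1]),
            reverse=True,
        )
        top = [net for _, _, net in scored[: params.top_k]]
        round_best = scored[0][0]
        if round_best > best_score:
            best_score = round_best
            stagnant = 0
        else:
            stagnant += 1
        if stagnant >= params.patience:
            return top[0], best_score
        n_mutants = max(0, params.population - params.top_k - params.fresh_per_round)
        mutants = []
        for _ in range(n_mutants):
            parent = top[int(rng.integers(0, len(top)))]
            partner = top[int(rng.integers(0, len(top)))]
            mutants.append(mutate(parent, rng, params, partner))
        fresh = [random_net(params, rng) for _ in range(params.fresh_per_round)]
        population = top + mutants + fresh


@dataclass
class EnsembleEntry:
    net: NeuralNet
    members: list[str]  # keys of included positives
    score: tuple[int, float, int]
    cycle: int


@dataclass
class TrainedEnsemble:
    networks: list[EnsembleEntry]
    coverage: dict[str, list[int]]  # positive key -> indices of covering nets
    complete: bool


def run_training(
    training_set: TrainingSet,
    params: CngParams | None = None,
    rng: np.random.Generator | None = None,
) -> TrainedEnsemble:
    """Repeat training cycles, each forced to cover at least one previously
    uncovered positive, until every positive is categorized by some network
    (or the cycle cap aborts with a partial ensemble and a warning)."""
    if params is None:
        params = CngParams()
    if rng is None:
        rng = np.random.default_rng()
    n_pos = len(training_set.positives)
    covered = np.zeros(n_pos, dtype=bool)
    entries: list[EnsembleEntry] = []
    for cycle in range(params.cycle_cap):
        if covered.all():
            break
        net, sc = train_cycle(training_set, params, rng, uncovered=~covered)
        if sc == VETO_SCORE:
            logger.info("cycle %d produced no admissible network", cycle)
            continue
        pos_in = net.includes(training_set.positives)
        covered |= pos_in
        members = [training_set.positive_keys[i] for i in np.flatnonzero(pos_in)]
        entries.append(EnsembleEntry(net, members, sc, cycle))
    complete = bool(covered.all())
    if not complete:
        warnings.warn(
            f"cycle cap reached with {int((~covered).sum())} of {n_pos} "
            "positives uncovered; returning partial ensemble"
        )
    coverage: dict[str, list[int]] = {k: [] for k in training_set.positive_keys}
    for j, e in enumerate(entries):
        for k in e.members:
            coverage[k].append(j)
    return TrainedEnsemble(entries, coverage, complete)


def category_distance(members_a: Sequence[str], members_b: Sequence[str]) -> float | None:
    """1 - |A ∩ B| / min(|A|, |B|): 1 for disjoint categories, 0 when the
    smaller is contained in the larger. ``None`` if either is empty."""
    a, b = set(members_a), set(members_b)
    if not a or not b:
        return None
    return 1.0 - len(a & b) / min(len(a), len(b))


def ensemble_report(
    ensemble: TrainedEnsemble, training_set: TrainingSet
) -> dict:
    """Member tables, pairwise category-distance matrix, and per-network
    Spearman rank correlations among the three inputs of its members."""
    key_pos = {k: i for i, k in enumerate(training_set.positive_keys)}
    member_tables = []
    correlations = []
    for e in ensemble.networks:
        rows = training_set.positives[[key_pos[k] for k in e.members]]
        member_tables.append(
            pd.DataFrame(rows, columns=list(INPUT_NAMES), index=e.members)
        )
        if len(e.members) < 2:
            correlations.append(None)
        else:
            cors = {}
            with warnings.catch_warnings():
                # constant member columns yield an undefined (NaN) rho
                warnings.simplefilter("ignore", sstats.ConstantInputWarning)
                for i in range(3):
                    for j in range(i + 1, 3):
                        rho = sstats.spearmanr(rows[:, i], rows[:, j]).statistic
                        cors[f"{INPUT_NAMES[i]}~{INPUT_NAMES[j]}"] = float(rho)
            correlations.append(cors)
    n = len(ensemble.networks)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = category_distance(
                ensemble.networks[i].members, ensemble.networks[j].members
            )
            dist[i, j] = dist[j, i] = np.nan if d is None else d
    return {
        "members": member_tables,
        "distance_matrix": pd.DataFrame(dist),
        "spearman": correlations,
    }


def save_ensemble(ensemble: TrainedEnsemble, path: str | Path) -> None:
    """Serialize an ensemble as human-readable JSON text."""
    payload = {
        "complete": ensemble.complete,
        "networks": [
            {
                "net": e.net.to_dict(),
                "members": e.members,
                "score": list(e.score),
                "cycle": e.cycle,
            }
            for e in ensemble.networks
        ],
        "coverage": ensemble.coverage,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_ensemble(path: str | Path) -> TrainedEnsemble:
    d = json.loads(Path(path).read_text())
    entries = [
        EnsembleEntry(
            NeuralNet.from_dict(e["net"]), list(e["members"]),
            (int(e["score"][0]), float(e["score"][1]), int(e["score"][2])),
            int(e["cycle"]),
        )
        for e in d["networks"]
    ]
    return TrainedEnsemble(entries, {k: list(v) for k, v in d["coverage"].items()}, d["complete"])


def random_training_points(
    promoters,
    rng: np.random.Generator,
    n: int = 200,
    len_min: int = 5,
    len_max: int = 8,
    mode: str = "all",
    iters: int = 10_000,
) -> tuple[np.ndarray, list[str]]:
    """Positional statistics of random CRE pairs on a promoter set, the
    "random sequences" leg of the training data. Pairs with too few
    co-occurrences contribute the neutral point."""
    from .edcc import random_query
    from .matching import find_matches
    from .positional import pair_positional_stats

    points = np.empty((n, 3))
    keys = []
    for i in range(n):
        q = random_query(rng, arity=2, len_min=len_min, len_max=len_max)
        ma = find_matches(q.members[0], promoters, mode)
        mb = find_matches(q.members[1], promoters, mode)
        stat = pair_positional_stats(ma, mb, promoters, rng, iters=iters)
        points[i] = stats_to_point(stat)
        keys.append(q.label)
    return points, keys
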
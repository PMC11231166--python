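"""Directed spread graphs, hidden-state spaces and transition matrices.

The anatomy is abstracted as a directed acyclic graph: a primary-tumor node
with an arc to every lymph node level (LNL), plus optional LNL-to-LNL arcs
along lymphatic drainage pathways.  Each LNL is a binary hidden variable
(healthy / harbors metastases), and each arc carries a per-time-step
probability of metastatic seeding given disease at its source.  The joint
state of all ``V`` levels evolves as a Markov chain on the ``2**V`` binary
state vectors, with involved levels never reverting to healthy
("no self-healing"), so the all-involved state is absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml


class GraphError(ValueError):
    """Invalid spread-graph specification."""


class ModelParamError(ValueError):
    """Parameter set inconsistent with the graph or outside [0, 1]."""


DEFAULT_LNLS = ("I", "II", "III", "IV", "V", "VII")


@dataclass(frozen=True)
class SpreadGraph:
    """Tumor + LNL spread topology.

    Parameters
    ----------
    lnl_names
        Ordered level labels, e.g. ``("I", "II", "III", "IV", "V", "VII")``.
        The order fixes the hidden-state bit order (first label = most
        significant bit) and the parameter-vector layout.
    lnl_arcs
        Ordered ``(parent, child)`` pairs of LNL-to-LNL drainage arcs.

    Every level receives a direct tumor arc: levels are observed metastatic
    in isolation, which forces ``b_v > 0`` for all ``v``.
    """

    lnl_names: tuple[str, ...] = DEFAULT_LNLS
    lnl_arcs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        names = tuple(self.lnl_names)
        object.__setattr__(self, "lnl_names", names)
        arcs = tuple((str(p), str(c)) for p, c in self.lnl_arcs)
        object.__setattr__(self, "lnl_arcs", arcs)
        if len(set(names)) != len(names) or not names:
            raise GraphError(f"duplicate or empty LNL names: {names}")
        if len(set(arcs)) != len(arcs):
            raise GraphError(f"duplicate arcs: {arcs}")
        for p, c in arcs:
            if p not in names or c not in names:
                raise GraphError(f"arc {p}->{c} references unknown level")
            if p == c:
                raise GraphError(f"self-loop on level {p}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        children: dict[str, list[str]] = {n: [] for n in self.lnl_names}
        for p, c in self.lnl_arcs:
            children[p].append(c)
        # Kahn's algorithm
        indeg = {n: 0 for n in self.lnl_names}
        for p, c in self.lnl_arcs:
            indeg[c] += 1
        queue = [n for n, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            n = queue.pop()
            seen += 1
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(self.lnl_names):
            raise GraphError(f"LNL arcs contain a cycle: {self.lnl_arcs}")

    @property
    def n_lnls(self) -> int:
        return len(self.lnl_names)

    @property
    def n_params(self) -> int:
        """Sampled dimensionality k: one b per level, one t per arc, p_late."""
        return self.n_lnls + len(self.lnl_arcs) + 1

    def parents(self, level: str) -> tuple[str, ...]:
        return tuple(p for p, c in self.lnl_arcs if c == level)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        b = tuple(f"b_{v}" for v in self.lnl_names)
        t = tuple(f"t_{p}->{c}" for p, c in self.lnl_arcs)
        return b + t + ("p_late",)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        mapping: dict[str, list[str]] = {"tumor": list(self.lnl_names)}
        for name in self.lnl_names:
            mapping[name] = [c for p, c in self.lnl_arcs if p == name]
        return mapping

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Sequence[str]]) -> "SpreadGraph":
        """Build from a node -> children mapping; tumor keyed ``"tumor"``.

        LNL order is taken from the tumor node's child list (every level must
        have a tumor arc), falling back to key order for levels missing there.
        """
        if "tumor" not in mapping:
            raise GraphError('graph mapping needs a "tumor" key')
        names = list(mapping["tumor"])
        extra = [k for k in mapping if k != "tumor" and k not in names]
        if extra:
            raise GraphError(
                f"levels {extra} lack a tumor arc; every level needs one"
            )
        arcs = []
        for parent, kids in mapping.items():
            if parent == "tumor":
                continue
            for child in kids:
                arcs.append((parent, child))
        return cls(tuple(names), tuple(arcs))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpreadGraph":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def base_graph() -> SpreadGraph:
    """Minimal graph: tumor to every level, plus II->III and III->IV
    (the main lymphatic drainage pathway)."""
    return SpreadGraph(DEFAULT_LNLS, (("II", "III"), ("III", "IV")))


def winning_graph() -> SpreadGraph:
    """Evidence-maximizing graph: base graph plus I->II and IV->V."""
    return SpreadGraph(
        DEFAULT_LNLS,
        (("I", "II"), ("II", "III"), ("III", "IV"), ("IV", "V")),
    )


@dataclass
class ModelParams:
    """Spread probabilities and diagnose-time parameters for a graph.

    ``b[v]`` is the per-time-step probability of direct tumor seeding of
    level ``v``; ``t[(r, v)]`` the probability of spread from an involved
    parent ``r`` into ``v``.  ``p_early`` and ``p_late`` parameterize the
    binomial diagnose-time priors for the two T-categories; ``p_early`` is
    conventionally fixed at 0.3 and not sampled.
    """

    b: dict[str, float]
    t: dict[tuple[str, str], float] = field(default_factory=dict)
    p_late: float = 0.5
    p_early: float = 0.3
    t_max: int = 10

    def validate(self, graph: SpreadGraph) -> None:
        if set(self.b) != set(graph.lnl_names):
            raise ModelParamError(
                f"b keys {sorted(self.b)} != levels {sorted(graph.lnl_names)}"
            )
        if set(self.t) != set(graph.lnl_arcs):
            raise ModelParamError(
                f"t keys {sorted(self.t)} != arcs {sorted(graph.lnl_arcs)}"
            )
        probs = [*self.b.values(), *self.t.values(), self.p_late, self.p_early]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ModelParamError("all spread/time probabilities must be in [0, 1]")
        if self.t_max < 1:
            raise ModelParamError("t_max must be >= 1")

    def to_vector(self, graph: SpreadGraph) -> np.ndarray:
        """Flatten to the sampling layout: b (level order), t (arc order), p_late."""
        self.validate(graph)
        return np.array(
            [self.b[v] for v in graph.lnl_names]
            + [self.t[a] for a in graph.lnl_arcs]
            + [self.p_late]
        )

    @classmethod
    def from_vector(
        cls,
        theta: np.ndarray,
        graph: SpreadGraph,
        p_early: float = 0.3,
        t_max: int = 10,
    ) -> "ModelParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (graph.n_params,):
            raise ModelParamError(
                f"expected vector of length {graph.n_params}, got {theta.shape}"
            )
        nv = graph.n_lnls
        b = dict(zip(graph.lnl_names, theta[:nv]))
        t = dict(zip(graph.lnl_arcs, theta[nv:-1]))
        return cls(b=b, t=t, p_late=float(theta[-1]), p_early=p_early, t_max=t_max)


class StateSpace:
    """Enumeration of the ``2**V`` binary involvement states.

    State ``i`` is the V-digit binary representation of ``i`` with the first
    listed level as the most significant bit, so index 0 is all-healthy and
    index ``2**V - 1`` all-involved.
    """

    MAX_LEVELS = 12

    def __init__(self, lnl_names: Sequence[str]):
        V = len(lnl_names)
        if not 1 <= V <= self.MAX_LEVELS:
            raise GraphError(f"need 1 <= V <= {self.MAX_LEVELS}, got {V}")
        self.lnl_names = tuple(lnl_names)
        self.V = V
        self.n_states = 2**V
        i = np.arange(self.n_states)
        # bits[i, v] = involvement of the v-th listed level in state i
        self.bits = ((i[:, None] >> (V - 1 - np.arange(V))) & 1).astype(np.int8)
        self._level_index = {name: v for v, name in enumerate(self.lnl_names)}

    def level_index(self, level: str) -> int:
        try:
            return self._level_index[level]
        except KeyError:
            raise GraphError(f"unknown level {level!r}") from None

    def index_of(self, state: Sequence[int]) -> int:
        state = tuple(int(s) for s in state)
        if len(state) != self.V or any(s not in (0, 1) for s in state):
            raise GraphError(f"not a binary state of length {self.V}: {state}")
        return int(sum(s << (self.V - 1 - v) for v, s in enumerate(state)))

    def state_of(self, index: int) -> tuple[int, ...]:
        return tuple(int(x) for x in self.bits[index])

    @property
    def states(self) -> list[tuple[int, ...]]:
        return [tuple(int(x) for x in row) for row in self.bits]

    def involvement_mask(self, level: str) -> np.ndarray:
        """Boolean mask over states where ``level`` is involved."""
        return self.bits[:, self.level_index(level)] == 1


def enumerate_states(V: int, lnl_names: Sequence[str] | None = None) -> StateSpace:
    """State space over ``V`` levels (labelled 1..V unless names are given)."""
    if lnl_names is None:
        lnl_names = tuple(str(v + 1) for v in range(V))
    if len(lnl_names) != V:
        raise GraphError("lnl_names length must equal V")
    return StateSpace(lnl_names)


def node_transition_prob(
    graph: SpreadGraph,
    params: ModelParams,
    level: str,
    parent_states: Sequence[int],
    current: int,
    new: int,
) -> float:
    """Single-level transition probability P(X_v[t+1]=new | X_v[t]=current).

    An involved level stays involved (no self-healing).  A healthy level
    becomes involved with probability ``1 - (1-b_v) * prod(1-t_rv)`` over its
    involved parents ``r``.
    """
    if level not in graph.lnl_names:
        raise ModelParamError(f"unknown level {level!r}")
    parents = graph.parents(level)
    if len(parent_states) != len(parents):
        raise ModelParamError(
            f"level {level} has parents {parents}; got {len(parent_states)} states"
        )
    if current == 1:
        return 1.0 if new == 1 else 0.0
    stay = 1.0 - params.b[level]
    for r, inv in zip(parents, parent_states):
        if inv:
            stay *= 1.0 - params.t[(r, level)]
    return 1.0 - stay if new == 1 else stay


class TransitionMatrix:
    """Column-stochastic transition matrix over the hidden-state space.

    ``A[i, j] = P(X[t+1] = state_i | X[t] = state_j)``: columns index the
    source state, so a column distribution propagates as ``A @ pi``.
    """

    def __init__(self, A: np.ndarray, state_space: StateSpace):
        self.A = A
        self.state_space = state_space

    def __getitem__(self, key):
        return self.A[key]

    def propagate(self, pi: np.ndarray, steps: int = 1) -> np.ndarray:
        out = np.asarray(pi, dtype=float)
        for _ in range(steps):
            out = self.A @ out
        return out


def _involvement_probs(
    bits: np.ndarray,
    b: np.ndarray,
    arc_parent_idx: np.ndarray,
    arc_child_idx: np.ndarray,
    arc_t: np.ndarray,
) -> np.ndarray:
    """p[j, v]: probability that healthy level v becomes involved from state j."""
    stay = np.repeat((1.0 - b)[None, :], bits.shape[0], axis=0)
    for r, c, t in zip(arc_parent_idx, arc_child_idx, arc_t):
        np.multiply(
            stay[:, c], np.where(bits[:, r] == 1, 1.0 - t, 1.0), out=stay[:, c]
        )
    return 1.0 - stay


def build_transition_matrix(
    graph: SpreadGraph, params: ModelParams, state_space: StateSpace | None = None
) -> TransitionMatrix:
    """Assemble A as the product over levels of single-level factors."""
    params.validate(graph)
    ss = state_space or StateSpace(graph.lnl_names)
    if ss.lnl_names != graph.lnl_names:
        raise GraphError("state space levels do not match graph levels")
    bits = ss.bits
    b = np.array([params.b[v] for v in graph.lnl_names])
    pidx = np.array([ss.level_index(p) for p, _ in graph.lnl_arcs], dtype=int)
    cidx = np.array([ss.level_index(c) for _, c in graph.lnl_arcs], dtype=int)
    tval = np.array([params.t[a] for a in graph.lnl_arcs])
    p_inv = _involvement_probs(bits, b, pidx, cidx, tval)

    A = np.ones((ss.n_states, ss.n_states))
    for v in range(ss.V):
        src = bits[:, v][None, :]
        dst = bits[:, v][:, None]
        p = p_inv[:, v][None, :]
        factor = np.where(
            src == 1,
            np.where(dst == 1, 1.0, 0.0),
            np.where(dst == 1, p, 1.0 - p),
        )
        A *= factor
    if np.any(A < -1e-12) or np.any(A > 1 + 1e-12):
        raise ModelParamError("transition probabilities escaped [0, 1]")
    return TransitionMatrix(A, ss)
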
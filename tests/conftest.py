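import itertools

import numpy as np
import pytest

import lyspread as ly


@pytest.fixture(scope="session")
def winning():
    return ly.winning_graph()


@pytest.fixture(scope="session")
def ref_params():
    return ly.reference_params()


@pytest.fixture(scope="session")
def toy_graph():
    """Two-level chain: tumor -> A, tumor -> B, A -> B."""
    return ly.SpreadGraph(("A", "B"), (("A", "B"),))


@pytest.fixture(scope="session")
def toy_params():
    return ly.ModelParams(
        b={"A": 0.2, "B": 0.1}, t={("A", "B"): 0.5}, p_late=0.4, t_max=3
    )


# ---------------------------------------------------------------------------
# Independent naive oracles (deliberately slow, enumeration-based).
# ---------------------------------------------------------------------------

def naive_transition_matrix(graph, params):
    """Direct per-entry evaluation of the product of single-level factors."""
    names = graph.lnl_names
    V = len(names)
    states = list(itertools.product([0, 1], repeat=V))
    n = len(states)
    A = np.zeros((n, n))
    for j, src in enumerate(states):
        for i, dst in enumerate(states):
            prob = 1.0
            for v, name in enumerate(names):
                cur, new = src[v], dst[v]
                if cur == 1:
                    prob *= 1.0 if new == 1 else 0.0
                else:
                    stay = 1.0 - params.b[name]
                    for p in graph.parents(name):
                        if src[names.index(p)] == 1:
                            stay *= 1.0 - params.t[(p, name)]
                    prob *= (1.0 - stay) if new == 1 else stay
            A[i, j] = prob
    return A, states


def naive_diagnosis_prob(graph, params, pattern, t_category, modality):
    """P(observe ternary pattern) by exhaustive sum over hidden-state *paths*,
    diagnosis completions and diagnose times."""
    import math

    names = graph.lnl_names
    V = len(names)
    states = list(itertools.product([0, 1], repeat=V))
    A, _ = naive_transition_matrix(graph, params)
    t_max = params.t_max
    p = params.p_early if t_category == "early" else params.p_late
    pmf = [
        math.comb(t_max, t) * p**t * (1 - p) ** (t_max - t) for t in range(t_max + 1)
    ]
    total = 0.0
    for t_d in range(t_max + 1):
        # enumerate state paths of length t_d starting all-healthy
        for path in itertools.product(range(len(states)), repeat=t_d):
            seq = [0] + list(path)
            path_prob = 1.0
            for a, bidx in zip(seq[:-1], seq[1:]):
                path_prob *= A[bidx, a]
            if path_prob == 0.0:
                continue
            final = states[seq[-1]]
            obs_prob = 1.0
            for v, name in enumerate(names):
                z = pattern.get(name)
                if z is None:
                    continue
                x = final[v]
                if x == 1:
                    obs_prob *= modality.sensitivity if z == 1 else 1 - modality.sensitivity
                else:
                    obs_prob *= 1 - modality.specificity if z == 1 else modality.specificity
            total += pmf[t_d] * path_prob * obs_prob
    return total


def random_params(graph, rng, t_max=10):
    b = {v: rng.uniform() for v in graph.lnl_names}
    t = {a: rng.uniform() for a in graph.lnl_arcs}
    return ly.ModelParams(b=b, t=t, p_late=rng.uniform(), t_max=t_max)
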
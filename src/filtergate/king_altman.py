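"""King-Altman spanning-tree expansion (exhaustive test oracle).

The stationary probability of state m in a kinetic diagram equals
D_m / sum_n D_n, where D_m is the sum over all spanning trees of the
underlying graph, directed toward m, of the product of the rate constants
along the directed edges.  This module enumerates those trees exhaustively
and is intentionally limited to small graphs (<= 8 states): it exists as an
independent oracle for the linear-solve steady state, not as the production
path.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np

from .constants import E_CHARGE, PA_PER_A
from .kinetics import OccupationVector, _rate_table
from .models import Condition, ModelSpec, RateParameterSet

__all__ = ["spanning_tree_weights", "spanning_tree_oracle", "closed_form_current"]

_MAX_STATES = 8


def spanning_tree_weights(
    states: list[str],
    rates: Mapping[tuple[str, str], float],
) -> dict[str, float]:
    """Per-state King-Altman weights D_m by exhaustive tree enumeration.

    ``rates`` maps directed edges (source, target) -> rate constant.  Every
    undirected spanning tree of the connection graph is enumerated; for each
    root m the tree edges are oriented toward m and the corresponding rate
    products summed.  Refuses graphs with more than 8 states.
    """
    n = len(states)
    if n > _MAX_STATES:
        raise ValueError(f"oracle limited to {_MAX_STATES} states, got {n}")
    idx = {s: i for i, s in enumerate(states)}
    undirected = sorted({tuple(sorted((idx[s], idx[t]))) for s, t in rates})
    D = {s: 0.0 for s in states}
    for subset in combinations(undirected, n - 1):
        # spanning tree iff acyclic and connected (union-find)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if not ok:
            continue
        adj: dict[int, list[int]] = {i: [] for i in range(n)}
        for a, b in subset:
            adj[a].append(b)
            adj[b].append(a)
        for root_label in states:
            root = idx[root_label]
            # orient each tree edge toward the root: BFS from root, every
            # edge points from child to parent
            prod = 1.0
            stack = [root]
            seen = {root}
            while stack and prod:
                node = stack.pop()
                for nb in adj[node]:
                    if nb in seen:
                        continue
                    seen.add(nb)
                    stack.append(nb)
                    k = rates.get((states[nb], states[node]), 0.0)
                    prod *= k
            D[root_label] += prod
    if all(v == 0.0 for v in D.values()):
        raise ValueError("graph has no spanning tree with nonzero weight")
    return D


def spanning_tree_oracle(
    model: ModelSpec,
    params: RateParameterSet,
    cond: Condition,
) -> OccupationVector:
    """Stationary occupation by King-Altman enumeration (oracle path)."""
    V = np.array([cond.V])
    rates_arr = _rate_table(model, params, V, np.array([cond.a_in]), np.array([cond.a_out]))
    rates = {pair: float(r[0]) for pair, r in rates_arr.items()}
    D = spanning_tree_weights(model.states, rates)
    total = sum(D.values())
    P = np.array([D[s] / total for s in model.states])
    return OccupationVector(states=list(model.states), P=P, D=np.array([D[s] for s in model.states]))


def closed_form_current(
    model: ModelSpec,
    params: RateParameterSet,
    cond: Condition,
) -> float:
    """Current (pA) from the explicit cycle formula, for pure-cycle models.

    I = e * (product of forward cycle rates - product of backward cycle
    rates) / sum_m D_m.  Valid when every edge of the model lies on the
    transport cycle, so that the net flux has the single-cycle closed form.
    """
    cycle_pairs = set(model.cycle_pairs())
    on_cycle = cycle_pairs | {(t, s) for s, t in cycle_pairs}
    if {(e.source, e.target) for e in model.edges} != on_cycle:
        raise ValueError("closed-form current requires a pure cycle model")
    V = np.array([cond.V])
    rates_arr = _rate_table(model, params, V, np.array([cond.a_in]), np.array([cond.a_out]))
    rates = {pair: float(r[0]) for pair, r in rates_arr.items()}
    fwd = np.prod([rates[(s, t)] for s, t in model.cycle_pairs()])
    bwd = np.prod([rates[(t, s)] for s, t in model.cycle_pairs()])
    D = spanning_tree_weights(model.states, rates)
    flux = (fwd - bwd) / sum(D.values())
    return E_CHARGE * flux * PA_PER_A
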
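"""Exact Markov-chain analysis of PEW Boolean models.

A PEW model induces a discrete Markov chain on its 2^N state space: the
state transition graph (STG) of the deterministic model becomes weighted by
the exact PEW branch probabilities.  This module builds that chain for each
update scheme, enumerates attractors of noise-free models, finds ergodic
subsets (closed communicating classes) of noisy ones, and solves for
stationary distributions.  It is the brute-force oracle against which the
stochastic engine is cross-checked.

State indexing convention: bit i of the integer state index corresponds to
``model.nodes[i]`` (bit 0 = first declared node).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .grammar import NetworkModel
from .noise import expression_probability

__all__ = [
    "TransitionMatrix",
    "Attractor",
    "transition_matrix",
    "find_attractors",
    "ergodic_subsets",
    "stationary_distribution",
    "export_stg",
]

STATE_SPACE_CAP = 16  # default N cap for exact 2^N enumeration
_SPARSE_ABOVE = 12  # store the matrix sparsely for N > 12
_RANDOM_ORDER_CAP = 6  # N! permutation enumeration cap


from .dynamics import UpdateScheme, index_to_state  # noqa: E402  (cycle-free)


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix over the 2^N state space."""

    matrix: np.ndarray | sp.spmatrix
    scheme: UpdateScheme
    nodes: tuple[str, ...]

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    def row(self, state_index: int) -> np.ndarray:
        row = self.matrix[state_index]
        if sp.issparse(row):
            return np.asarray(row.todense()).ravel()
        return np.asarray(row).ravel()

    def dense(self) -> np.ndarray:
        if sp.issparse(self.matrix):
            return np.asarray(self.matrix.todense())
        return self.matrix

    def node_marginal(self, distribution: np.ndarray) -> dict[str, float]:
        """Per-node ON-probabilities under a distribution over states."""
        marginals = {}
        idx = np.arange(self.n_states)
        for i, name in enumerate(self.nodes):
            on = (idx >> i) & 1
            marginals[name] = float(distribution[on == 1].sum())
        return marginals


def _node_probabilities(model: NetworkModel, state_index: int) -> list[float]:
    """Exact Pr(node_i' = 1) for each node, given the source state."""
    state = index_to_state(model, state_index)
    return [
        expression_probability(model.expression_for(name), state)
        for name in model.nodes
    ]


def _check_cap(model: NetworkModel, cap: int) -> None:
    if model.n > cap:
        raise ValueError(
            f"model has {model.n} nodes; exact 2^N analysis is capped at "
            f"N = {cap} (pass a larger cap explicitly to override)"
        )


def _sync_row(probs: Sequence[float]) -> dict[int, float]:
    """Joint successor distribution = product of independent per-node coins."""
    targets = {0: 1.0}
    for i, p in enumerate(probs):
        new: dict[int, float] = {}
        bit = 1 << i
        for idx, pr in targets.items():
            if p > 0.0:
                new[idx | bit] = new.get(idx | bit, 0.0) + pr * p
            if p < 1.0:
                new[idx] = new.get(idx, 0.0) + pr * (1.0 - p)
        targets = new
    return targets


def _single_node_update_matrix(model: NetworkModel, node_i: int) -> np.ndarray:
    """Dense operator: update only node i, exact branch probabilities."""
    size = 1 << model.n
    bit = 1 << node_i
    name = model.nodes[node_i]
    expr = model.expression_for(name)
    U = np.zeros((size, size))
    for s in range(size):
        p = expression_probability(expr, index_to_state(model, s))
        U[s, s | bit] += p
        U[s, s & ~bit] += 1.0 - p
    return U


def transition_matrix(
    model: NetworkModel,
    scheme: UpdateScheme = UpdateScheme.SYNCHRONOUS,
    cap: int = STATE_SPACE_CAP,
) -> TransitionMatrix:
    """Exact transition matrix of the chain induced by ``model`` and scheme.

    * synchronous: product measure of per-node update probabilities;
    * general asynchronous: uniform mixture of single-node updates;
    * random-order asynchronous: uniform mixture over all N! sweep orders
      (capped at N = 6; the factorial enumeration is an oracle, not a
      production path).
    """
    scheme = UpdateScheme(scheme)
    _check_cap(model, cap)
    size = 1 << model.n

    if scheme is UpdateScheme.RANDOM_ORDER_ASYNC:
        if model.n > _RANDOM_ORDER_CAP:
            raise ValueError(
                f"random-order exact matrix requires N <= {_RANDOM_ORDER_CAP} "
                f"(N! sweep orders); got N = {model.n}"
            )
        U = [_single_node_update_matrix(model, i) for i in range(model.n)]
        P = np.zeros((size, size))
        perms = list(itertools.permutations(range(model.n)))
        for perm in perms:
            M = U[perm[0]]
            for i in perm[1:]:
                M = M @ U[i]
            P += M
        P /= len(perms)
        return TransitionMatrix(P, scheme, model.nodes)

    if scheme is UpdateScheme.GENERAL_ASYNC:
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        inv_n = 1.0 / model.n
        for s in range(size):
            probs = _node_probabilities(model, s)
            acc: dict[int, float] = {}
            for i, p in enumerate(probs):
                bit = 1 << i
                acc[s | bit] = acc.get(s | bit, 0.0) + inv_n * p
                acc[s & ~bit] = acc.get(s & ~bit, 0.0) + inv_n * (1.0 - p)
            for t, v in acc.items():
                if v > 0.0:
                    rows.append(s)
                    cols.append(t)
                    vals.append(v)
        return TransitionMatrix(
            _assemble(rows, cols, vals, size, model.n), scheme, model.nodes
        )

    # synchronous
    rows, cols, vals = [], [], []
    for s in range(size):
        for t, v in _sync_row(_node_probabilities(model, s)).items():
            rows.append(s)
            cols.append(t)
            vals.append(v)
    return TransitionMatrix(
        _assemble(rows, cols, vals, size, model.n), scheme, model.nodes
    )


def _assemble(rows, cols, vals, size: int, n: int):
    coo = sp.coo_matrix((vals, (rows, cols)), shape=(size, size))
    if n > _SPARSE_ABOVE:
        return coo.tocsr()
    return np.asarray(coo.todense())


# ---------------------------------------------------------------------------
# Attractors of noise-free models (synchronous dynamics)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Attractor:
    """A closed orbit of the noise-free synchronous dynamics.

    ``states`` lists the orbit in visiting order starting from its smallest
    state index.
    """

    states: tuple[int, ...]
    kind: str  # "fixed_point" | "limit_cycle"

    def __len__(self) -> int:
        return len(self.states)


def _deterministic_successor(model: NetworkModel, s: int) -> int:
    t = 0
    for i, p in enumerate(_node_probabilities(model, s)):
        if p not in (0.0, 1.0):  # pragma: no cover - guarded by is_noise_free
            raise ValueError("model is not deterministic")
        if p == 1.0:
            t |= 1 << i
    return t


def find_attractors(model: NetworkModel, cap: int = STATE_SPACE_CAP) -> list[Attractor]:
    """Exhaustive synchronous attractor enumeration for noise-free models.

    Fixed points satisfy f_i(state) = state_i for every node.  For a noisy
    model the long-run structure is not a set of deterministic orbits; use
    :func:`ergodic_subsets` on its transition matrix instead.
    """
    if not model.is_noise_free:
        raise ValueError(
            "find_attractors requires a noise-free model (all PEW specs [1,0] "
            "or absent); for noisy models use ergodic_subsets(transition_matrix(...))"
        )
    _check_cap(model, cap)
    size = 1 << model.n
    succ = [_deterministic_successor(model, s) for s in range(size)]

    color = [0] * size  # 0 = unvisited, -1 = on current path, >0 = attractor id + 1 resolved
    resolved = [False] * size
    attractors: list[Attractor] = []
    for s0 in range(size):
        if resolved[s0]:
            continue
        path = []
        s = s0
        while not resolved[s] and color[s] == 0:
            color[s] = -1
            path.append(s)
            s = succ[s]
        if not resolved[s]:  # closed a new cycle within the current path
            start = path.index(s)
            cycle = path[start:]
            # canonical rotation: start at the smallest state index
            k = cycle.index(min(cycle))
            cycle = cycle[k:] + cycle[:k]
            attractors.append(
                Attractor(tuple(cycle), "fixed_point" if len(cycle) == 1 else "limit_cycle")
            )
        for s in path:
            resolved[s] = True
    return attractors


# ---------------------------------------------------------------------------
# Ergodic subsets and stationary distributions
# ---------------------------------------------------------------------------


def ergodic_subsets(tm: TransitionMatrix | np.ndarray) -> list[tuple[int, ...]]:
    """Closed communicating classes of the chain (its ergodic subsets).

    These are the strongly connected components of the positive-probability
    transition graph with no outgoing edges; the chain keeps visiting such a
    set forever once it enters it.
    """
    P = tm.matrix if isinstance(tm, TransitionMatrix) else tm
    if sp.issparse(P):
        G = nx.from_scipy_sparse_array(sp.csr_matrix(P), create_using=nx.DiGraph)
    else:
        G = nx.from_numpy_array(np.asarray(P), create_using=nx.DiGraph)
    cond = nx.condensation(G)
    closed = []
    for comp_id, data in cond.nodes(data=True):
        if cond.out_degree(comp_id) == 0:
            closed.append(tuple(sorted(data["members"])))
    return sorted(closed)


def stationary_distribution(
    tm: TransitionMatrix | np.ndarray,
    states: Sequence[int] | None = None,
    tol: float = 1e-10,
) -> np.ndarray:
    """Solve pi P = pi, pi >= 0, sum(pi) = 1 on a closed class.

    ``states`` restricts the chain to one closed class (as returned by
    :func:`ergodic_subsets`); omit it for an irreducible chain.  The linear
    system is solved directly, so periodic chains are handled as well.
    Returns pi indexed like ``states`` (or like the full space).
    """
    P = tm.matrix if isinstance(tm, TransitionMatrix) else tm
    if sp.issparse(P):
        P = np.asarray(P.todense())
    P = np.asarray(P, dtype=float)
    if states is not None:
        idx = np.asarray(list(states), dtype=int)
        P = P[np.ix_(idx, idx)]
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("the given state set is not closed under the chain")
    m = P.shape[0]
    A = np.vstack([P.T - np.eye(m), np.ones((1, m))])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    residual = np.abs(pi @ P - pi).max()
    if residual > tol:
        raise ArithmeticError(
            f"stationary solve residual {residual:.2e} exceeds tolerance {tol:.0e}"
        )
    return pi


def export_stg(tm: TransitionMatrix, path) -> None:
    """Write the weighted STG as a TSV edge list: source, target, probability."""
    P = tm.matrix
    with open(path, "w") as fh:
        fh.write("source_index\ttarget_index\tprobability\n")
        if sp.issparse(P):
            coo = sp.coo_matrix(P)
            for s, t, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{s}\t{t}\t{v!r}\n")
        else:
            for s in range(P.shape[0]):
                for t in np.nonzero(P[s])[0]:
                    fh.write(f"{s}\t{t}\t{P[s, t]!r}\n")
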
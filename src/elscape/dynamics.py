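"""Metropolis–Hastings random walks on the landscape and their attractor summaries.

The walk moves on the hypercube of activity patterns: from pattern V_i one of
the N Hamming-1 neighbors V_j is proposed uniformly at random and accepted
with probability min(1, exp(E(V_i) − E(V_j))) — downhill moves are always
accepted, uphill moves sometimes, so the chain cannot be trapped forever.
Its stationary law is the Boltzmann distribution of the fitted model.

After a burn-in, every visited state is mapped to its attractor (basin), and
the label sequence is summarized as per-attractor dwelling times
(consecutive-run lengths) and pairwise transition counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import BasinMap, neighbor_indices
from .mem import StateTable

DEFAULT_N_STEPS = 100_000
DEFAULT_BURN_IN = 100


@dataclass
class WalkTrajectory:
    states: np.ndarray  # visited state indices after burn-in
    labels: np.ndarray  # attractor (minimum state-index) per visited state
    seed: int
    n_steps: int
    burn_in: int

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class DynamicsSummary:
    """Run-length summary of an attractor label sequence.

    ``dwell_mean`` is the mean consecutive-run length per attractor (steps);
    ``occupancy`` the total number of steps spent in each attractor;
    ``transitions`` the switch count for each unordered attractor pair.
    ``run_lengths`` keeps the raw per-attractor run-length lists so either
    the per-attractor means or the pooled run-length distribution can be
    inspected.
    """

    dwell_mean: dict[int, float]
    occupancy: dict[int, int]
    transitions: dict[tuple[int, int], int]
    run_lengths: dict[int, list[int]] = field(default_factory=dict)
    length: int = 0


def random_walk(
    table: StateTable,
    basins: BasinMap | None,
    n_steps: int = DEFAULT_N_STEPS,
    burn_in: int = DEFAULT_BURN_IN,
    seed: int = 0,
) -> WalkTrajectory:
    """Metropolis–Hastings walk of ``n_steps`` from a uniformly random pattern.

    The first ``burn_in`` visited states are discarded to wash out the
    initial condition; the rest are mapped through ``basins`` to attractor
    labels (with ``basins=None`` — e.g. on a degenerate landscape without
    strict minima — the raw state indices serve as labels).
    """
    if burn_in >= n_steps:
        raise ValueError("burn_in must be smaller than n_steps")
    E = table.energies
    nb = neighbor_indices(table.n_nodes)
    n = table.n_nodes

    # all acceptance probabilities are precomputed: A[k, i] for flipping node i of state k
    A = np.minimum(1.0, np.exp(E[:, None] - E[nb]))

    rng = np.random.default_rng(seed)
    state = int(rng.integers(table.n_states))
    proposals = rng.integers(0, n, size=n_steps)
    uniforms = rng.random(n_steps)

    visited = np.empty(n_steps, dtype=np.int64)
    nb_list = nb  # local alias for the loop
    for t in range(n_steps):
        i = proposals[t]
        if uniforms[t] < A[state, i]:
            state = int(nb_list[state, i])
        visited[t] = state

    kept = visited[burn_in:]
    labels = basins.basin[kept] if basins is not None else kept.copy()
    return WalkTrajectory(states=kept, labels=labels, seed=seed, n_steps=n_steps, burn_in=burn_in)


def summarize_dynamics(traj: WalkTrajectory | np.ndarray) -> DynamicsSummary:
    """Run-length encode an attractor label sequence.

    Dwelling time of an attractor = mean length of its consecutive runs;
    occupancy = total steps; transitions = counts of adjacent distinct label
    pairs, unordered (self-transitions are not counted).
    """
    labels = np.asarray(traj.labels if isinstance(traj, WalkTrajectory) else traj)
    if labels.size == 0:
        raise ValueError("empty trajectory")

    change = np.flatnonzero(labels[1:] != labels[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(labels)]))
    run_labels = labels[starts]
    run_lens = ends - starts

    run_lengths: dict[int, list[int]] = {}
    for lab, ln in zip(run_labels, run_lens):
        run_lengths.setdefault(int(lab), []).append(int(ln))

    dwell_mean = {lab: float(np.mean(lens)) for lab, lens in run_lengths.items()}
    occupancy = {lab: int(np.sum(lens)) for lab, lens in run_lengths.items()}

    transitions: dict[tuple[int, int], int] = {}
    for a, b in zip(run_labels[:-1], run_labels[1:]):
        key = (int(min(a, b)), int(max(a, b)))
        transitions[key] = transitions.get(key, 0) + 1

    return DynamicsSummary(
        dwell_mean=dwell_mean,
        occupancy=occupancy,
        transitions=transitions,
        run_lengths=run_lengths,
        length=int(labels.size),
    )
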
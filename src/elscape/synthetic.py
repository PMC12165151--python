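"""Synthetic recordings with known ground truth for the full analysis chain.

Latent ±1 dynamics are drawn from a pairwise maximum-entropy model with known
parameters, then optionally emitted as noisy continuous observations:

* fMRI-like inputs: N = 9 channels, one observed column per latent channel;
* LLM-like inputs: each latent channel duplicated over many observed columns
  (``nodes_per_cluster``) with per-column random gain/offset and Gaussian
  noise, emulating a high-dimensional hidden-state recording whose nodes must
  be re-clustered into nine channels.

Two landscape regimes can be constructed: ``uniform_shallow`` (weak
homogeneous couplings, many minima of similar depth) and ``polarized`` (a
tight ferromagnetic block plus weakly coupled nodes, producing coexisting
deep and shallow minima).  All generators are pure functions of their
arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import build_disconnectivity, find_local_minima
from .mem import MAX_ENUM_NODES, EnumerationError, MEMParameters, exact_distribution

#: depth-heterogeneity threshold separating the two regimes: a polarized
#: landscape has (max basin depth)/(min basin depth) >= this ratio among its
#: minima, a uniform_shallow landscape stays below it.
REGIME_DEPTH_RATIO = 2.0

REGIMES = ("uniform_shallow", "polarized")


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic recording."""

    n_nodes: int = 9
    n_timepoints: int = 100_000
    seed: int = 0
    noise_sd: float = 0.1
    nodes_per_cluster: int = 1
    regime: str = "uniform_shallow"

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nodes_per_cluster < 1:
            raise ValueError("nodes_per_cluster must be >= 1")
        if self.regime not in REGIMES + ("custom",):
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass
class SyntheticObservations:
    """Continuous observations plus the truth metadata tests rely on."""

    data: np.ndarray  # (T, n_nodes * nodes_per_cluster)
    cluster_map: np.ndarray  # (n_columns,) true latent channel of each column
    gains: np.ndarray
    offsets: np.ndarray


def _check_enumerable(params: MEMParameters) -> None:
    if params.n_nodes > MAX_ENUM_NODES:
        raise EnumerationError(
            f"exact sampling requires N <= {MAX_ENUM_NODES}, got N = {params.n_nodes}"
        )


def sample_mem_series(params: MEMParameters, n_timepoints: int, seed: int) -> np.ndarray:
    """I.i.d. rows from the exact Boltzmann distribution of ``params``.

    Each time point is drawn independently from P(V_k), so empirical moments
    converge to the exact model moments with no autocorrelation — the
    cleanest input for parameter-recovery checks.
    """
    _check_enumerable(params)
    table = exact_distribution(params)
    rng = np.random.default_rng(seed)
    idx = rng.choice(table.n_states, size=n_timepoints, p=table.probabilities)
    return table.patterns[idx].copy()


def sample_glauber_series(
    params: MEMParameters,
    n_timepoints: int,
    seed: int,
    burn_in: int = 1_000,
    thin: int = 1,
) -> np.ndarray:
    """Temporally correlated series from single-site Glauber dynamics.

    One node is resampled per step from its conditional under the model, so
    (at ``thin=1``) consecutive rows differ in at most one node while the
    stationary law is still the Boltzmann distribution of ``params``.
    """
    _check_enumerable(params)
    if thin < 1:
        raise ValueError("thin must be >= 1")
    n = params.n_nodes
    rng = np.random.default_rng(seed)
    state = rng.choice((-1, 1), size=n).astype(np.int8)
    h, J = params.h, params.J

    total = burn_in + n_timepoints * thin
    sites = rng.integers(0, n, size=total)
    us = rng.random(total)
    out = np.empty((n_timepoints, n), dtype=np.int8)
    kept = 0
    for t in range(total):
        i = sites[t]
        a = h[i] + J[i] @ state
        p_plus = 1.0 / (1.0 + np.exp(-2.0 * a))
        state[i] = 1 if us[t] < p_plus else -1
        if t >= burn_in and (t - burn_in) % thin == thin - 1:
            out[kept] = state
            kept += 1
            if kept == n_timepoints:
                break
    return out


def _partition_blocks(n: int, n_blocks: int = 3) -> list[np.ndarray]:
    n_blocks = min(n_blocks, n // 2)
    sizes = np.full(n_blocks, n // n_blocks)
    sizes[: n % n_blocks] += 1
    bounds = np.concatenate(([0], np.cumsum(sizes)))
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(n_blocks)]


def _block_landscape(
    rng: np.random.Generator, n: int, block_strengths: np.ndarray
) -> MEMParameters:
    """Ferromagnetic blocks with near-zero fields.

    With fields close to zero the landscape is nearly spin-flip symmetric, so
    every combination of block alignments is a local minimum and a block's
    escape barrier — hence its basin depth — is set by its coupling strength.
    Per-edge jitter and weak inter-block couplings break exact energy ties.
    """
    blocks = _partition_blocks(n, len(block_strengths))
    h = rng.uniform(-0.02, 0.02, size=n)
    J = rng.uniform(-0.05, 0.05, size=(n, n))
    for block, j in zip(blocks, block_strengths):
        for a in block:
            for b in block:
                if a < b:
                    J[a, b] = J[b, a] = j * rng.uniform(0.95, 1.05)
    J = 0.5 * (J + J.T)
    np.fill_diagonal(J, 0.0)
    return MEMParameters(h=h, J=J)


def _draw_uniform_shallow(rng: np.random.Generator, n: int) -> MEMParameters:
    # three equally weak blocks -> many minima of similar depth
    base = rng.uniform(0.30, 0.40)
    return _block_landscape(rng, n, np.full(3, base))


def _draw_polarized(rng: np.random.Generator, n: int) -> MEMParameters:
    # one strongly ferromagnetic block plus weak blocks -> deep and shallow minima
    strong = rng.uniform(0.75, 0.95)
    weak = rng.uniform(0.25, 0.35)
    return _block_landscape(rng, n, np.array([strong, weak, weak]))


def landscape_depths(params: MEMParameters) -> dict[int, float]:
    """Basin depth of every local minimum, from the exhaustive landscape."""
    table = exact_distribution(params)
    minima = find_local_minima(table)
    tree = build_disconnectivity(table, minima)
    return tree.basin_depths()


def make_regime_params(
    regime: str,
    n_nodes: int = 9,
    seed: int = 0,
    max_retries: int = 100,
) -> MEMParameters:
    """Draw model parameters whose exhaustive landscape realizes a regime.

    ``uniform_shallow``: weak homogeneous couplings; the landscape must have
    ≥ 2 local minima and max/min basin-depth ratio < ``REGIME_DEPTH_RATIO``.
    ``polarized``: a ferromagnetic block plus weak couplings; ≥ 2 minima and
    depth ratio ≥ ``REGIME_DEPTH_RATIO``.  Draws are repeated (up to
    ``max_retries``, advancing the stream deterministically) until the
    exhaustive check passes.
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}, got {regime!r}")
    rng = np.random.default_rng(seed)
    draw = _draw_uniform_shallow if regime == "uniform_shallow" else _draw_polarized

    for _ in range(max_retries):
        params = draw(rng, n_nodes)
        depths = landscape_depths(params)
        if len(depths) < 2:
            continue
        vals = np.array(list(depths.values()))
        if vals.min() <= 0:
            continue
        ratio = vals.max() / vals.min()
        ok = ratio >= REGIME_DEPTH_RATIO if regime == "polarized" else ratio < REGIME_DEPTH_RATIO
        if ok:
            params.meta["regime"] = regime
            params.meta["depth_ratio"] = float(ratio)
            return params
    raise RuntimeError(
        f"could not realize regime {regime!r} with >= 2 minima in {max_retries} draws"
    )


def emit_continuous_observations(
    latent: np.ndarray,
    nodes_per_cluster: int = 1,
    noise_sd: float = 0.1,
    seed: int = 0,
    gain_range: tuple[float, float] = (0.5, 1.5),
    offset_range: tuple[float, float] = (-1.0, 1.0),
) -> SyntheticObservations:
    """Emit noisy continuous columns tracking the latent ±1 channels.

    Column ``c`` follows latent channel ``c // nodes_per_cluster`` through an
    affine map (per-column gain and offset, drawn once) plus i.i.d. Gaussian
    noise of scale ``noise_sd``.  The default gain/offset ranges force the
    downstream normalization to do real work; pass ``(1, 1)`` and ``(0, 0)``
    for an identity emission.
    """
    if nodes_per_cluster < 1:
        raise ValueError("nodes_per_cluster must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    latent = np.asarray(latent)
    T, n = latent.shape
    n_cols = n * nodes_per_cluster
    cluster_map = np.repeat(np.arange(n), nodes_per_cluster)

    rng = np.random.default_rng(seed)
    gains = rng.uniform(*gain_range, size=n_cols)
    offsets = rng.uniform(*offset_range, size=n_cols)
    data = latent[:, cluster_map].astype(float) * gains + offsets
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=(T, n_cols))
    return SyntheticObservations(data=data, cluster_map=cluster_map, gains=gains, offsets=offsets)


def generate_subject(config: GeneratorConfig) -> tuple[MEMParameters, np.ndarray, SyntheticObservations]:
    """One synthetic subject: regime parameters, latent series, observations.

    Sub-seeds for the parameter draw, the latent sampling and the emission
    are derived deterministically from ``config.seed``.
    """
    if config.regime == "custom":
        raise ValueError("generate_subject needs a named regime; use the lower-level API for custom params")
    ss = np.random.SeedSequence(config.seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    params = make_regime_params(config.regime, config.n_nodes, seed=seeds[0])
    latent = sample_mem_series(params, config.n_timepoints, seed=seeds[1])
    obs = emit_continuous_observations(
        latent, config.nodes_per_cluster, config.noise_sd, seed=seeds[2]
    )
    return params, latent, obs
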
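"""Seeded generators for synthetic ground-truth inputs.

Everything the test surface needs is generated here as a pure function of
its arguments and a seed: directed validation networks with known edges,
flow matrices with a planted club or a planted hierarchy, random symmetric
structural matrices, independent null panels, and a planted-hub Hopf
parameter set for lesioning experiments.  Regenerating with the same seed
is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .ndte import FlowMatrix
from .signals import EmbeddingSpec, TimeSeriesPanel
from .hopf import HopfParams


@dataclass(frozen=True)
class GroundTruth:
    """What a generator planted, for later comparison with what was detected."""

    kind: str  # directed_network | planted_club | planted_hierarchy | null | planted_hub
    payload: Any
    rng_seed: int


def make_validation_network(n_nodes: int, topology: str = "chain", rng_seed: int = 0) -> GroundTruth:
    """Binary directed adjacency with known edges; entry (t, s) = 1 means s -> t.

    Topologies: ``chain`` (1 -> 2 -> ... -> n), ``fan_in`` (all drive node 0),
    ``fan_out`` (node 0 drives all), ``mixed`` (fan_out plus one reciprocal
    pair).  Chain and fan graphs are acyclic with no reciprocal edges.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    adj = np.zeros((n_nodes, n_nodes), dtype=int)
    if topology == "chain":
        for s in range(n_nodes - 1):
            adj[s + 1, s] = 1
    elif topology == "fan_in":
        for s in range(1, n_nodes):
            adj[0, s] = 1
    elif topology == "fan_out":
        for t in range(1, n_nodes):
            adj[t, 0] = 1
    elif topology == "mixed":
        for t in range(1, n_nodes):
            adj[t, 0] = 1
        adj[0, 1] = 1  # one reciprocal pair (0 <-> 1)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return GroundTruth(kind="directed_network", payload=adj, rng_seed=rng_seed)


def make_planted_club_matrix(
    n: int,
    club_size: int,
    within: float = 0.8,
    inward: float = 0.6,
    outward: float = 0.05,
    background: float = 0.05,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> tuple[FlowMatrix, GroundTruth]:
    """Flow matrix with a planted club: strong within/incoming, weak outgoing.

    Club members (indices ``0..club_size-1``) exchange ``within`` flow among
    themselves, receive ``inward`` from outside, send only ``outward``; all
    remaining entries sit at ``background``.  Jitter is truncated-normal
    (clipped to [0, 1]).  Requires within > inward > outward >= background.
    """
    if not (club_size < n):
        raise ValueError("club must be smaller than the network")
    if not (within > inward > outward >= background >= 0):
        raise ValueError("need within > inward > outward >= background >= 0")
    rng = np.random.default_rng(rng_seed)
    members = list(range(club_size))
    values = np.full((n, n), background)
    inside = np.zeros(n, dtype=bool)
    inside[members] = True
    values[np.ix_(inside, inside)] = within
    values[np.ix_(inside, ~inside)] = inward  # rows=targets: club receives
    values[np.ix_(~inside, inside)] = outward  # club sends little
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=(n, n))
    values = np.clip(values, 0.0, 1.0)
    np.fill_diagonal(values, 0.0)
    flow = FlowMatrix(
        values=values,
        region_labels=[f"R{i:03d}" for i in range(n)],
        embedding=EmbeddingSpec(T=10),
    )
    return flow, GroundTruth(kind="planted_club", payload=members, rng_seed=rng_seed)


def make_random_sc(
    n: int, density: float = 0.5, rng_seed: int = 0, max_retries: int = 100
) -> np.ndarray:
    """Random connected symmetric structural matrix, maximum entry exactly 0.2."""
    if not (0.0 < density <= 1.0):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    iu = np.triu_indices(n, k=1)
    for _ in range(max_retries):
        present = rng.random(iu[0].size) < density
        if not present.any():
            continue
        weights = np.where(present, rng.random(iu[0].size), 0.0)
        sc = np.zeros((n, n))
        sc[iu] = weights
        sc = sc + sc.T
        # connectivity via breadth-first reachability
        seen = {0}
        frontier = [0]
        adj = sc > 0
        while frontier:
            node = frontier.pop()
            for nb in np.nonzero(adj[node])[0]:
                if int(nb) not in seen:
                    seen.add(int(nb))
                    frontier.append(int(nb))
        if len(seen) == n:
            return sc * (0.2 / sc.max())
    raise RuntimeError(f"could not draw a connected graph at density {density}")


def make_null_panels(
    m: int,
    n_regions: int,
    n_time: int,
    model: str = "white",
    ar_coef: float = 0.5,
    tr: float = 0.72,
    rng_seed: int = 0,
) -> list[TimeSeriesPanel]:
    """Independent region series per subject: white noise or unit-variance AR(1)."""
    if model not in ("white", "ar1"):
        raise ValueError(f"unknown model {model!r}")
    if model == "ar1" and not (abs(ar_coef) < 1):
        raise ValueError("|ar_coef| must be < 1 for stationarity")
    rng = np.random.default_rng(rng_seed)
    panels = []
    for s in range(m):
        if model == "white":
            data = rng.standard_normal((n_regions, n_time))
        else:
            innov_sd = np.sqrt(1.0 - ar_coef**2)  # stationary unit variance
            data = np.empty((n_regions, n_time))
            data[:, 0] = rng.standard_normal(n_regions)
            eps = rng.standard_normal((n_regions, n_time)) * innov_sd
            for t in range(1, n_time):
                data[:, t] = ar_coef * data[:, t - 1] + eps[:, t]
        panels.append(
            TimeSeriesPanel(data=data, tr=tr, subject_id=f"null{s:03d}", condition="null")
        )
    return panels


def make_planted_hierarchy(
    n: int, h_values: np.ndarray, scale: float = 0.2, rng_seed: int = 0
) -> tuple[FlowMatrix, GroundTruth]:
    """Flow matrix whose feedforward fractions follow logistic(h_i - h_j) exactly.

    For each unordered pair, ``flow[i, j] = scale * logistic(h_i - h_j)`` and
    the reverse entry is the complement — the exact inverse of the
    feedforward-hierarchy GLM, so recovery should be near-perfect.
    """
    h = np.asarray(h_values, dtype=float)
    if h.size != n:
        raise ValueError("h_values length must equal n")
    diff = h[:, None] - h[None, :]
    values = scale / (1.0 + np.exp(-diff))
    np.fill_diagonal(values, 0.0)
    flow = FlowMatrix(
        values=values,
        region_labels=[f"R{i:03d}" for i in range(n)],
        embedding=EmbeddingSpec(T=10),
    )
    return flow, GroundTruth(kind="planted_hierarchy", payload=h.copy(), rng_seed=rng_seed)


def make_planted_hub_params(
    n: int,
    hub_size: int,
    hub_weight: float = 0.2,
    background_weight: float = 0.02,
    f_hz: float = 0.05,
    a: float = -0.02,
    beta: float = 0.02,
    g: float = 1.0,
    rng_seed: int = 0,
) -> tuple[HopfParams, GroundTruth]:
    """Hopf parameter set with a planted hub club.

    Hub regions (indices ``0..hub_size-1``) receive strong coupling from
    everywhere and from each other; all remaining directed couplings are
    weak.  Simulating this model yields a flow matrix whose club is the
    planted hub set, which is the ground truth for lesioning experiments.
    """
    if not (0 < hub_size < n):
        raise ValueError("hub_size must be in (0, n)")
    rng = np.random.default_rng(rng_seed)
    hubs = list(range(hub_size))
    inside = np.zeros(n, dtype=bool)
    inside[hubs] = True
    coupling = np.full((n, n), background_weight)
    coupling[inside, :] = hub_weight  # rows receive: hubs get strong input
    coupling *= rng.uniform(0.8, 1.2, size=(n, n))  # mild heterogeneity
    np.fill_diagonal(coupling, 0.0)
    params = HopfParams(
        a=np.full(n, a),
        omega=np.full(n, 2 * np.pi * f_hz),
        beta=np.full(n, beta),
        g=g,
        coupling=coupling,
    )
    return params, GroundTruth(kind="planted_hub", payload=hubs, rng_seed=rng_seed)
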
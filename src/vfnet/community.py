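"""Weighted modularity, stochastic Louvain optimisation, consensus co-assignment,
and the affinity of a region to a cortex.

The affinity statistic summarises, for a region i and a cortex X (the set
of left frontal or left temporal regions), how consistently i is assigned
to the same functional community as the members of X:

    A_iX = (1 / n_Xi) * sum_{j in X, j != i} P_ij,

where P_ij is the probability that regions i and j share a community
across repeated stochastic modularity optimisations (100 by default) and
n_Xi is the number of regions of X other than i.

Modularity is the Newman-Girvan weighted form with resolution gamma:

    Q = (1/2m) * sum_ij [W_ij - gamma * k_i k_j / (2m)] * delta(c_i, c_j),

with k the node strengths and m half the total weight; the i = j null
terms are included, so a single all-node community has Q = 0 at gamma = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Partition",
    "modularity",
    "louvain",
    "consensus_coassignment",
    "CoAssignmentMatrix",
    "affinity",
    "AffinityScore",
]


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    if (W < 0).any():
        raise ValueError(
            "negative weights are not supported; zero them before community detection"
        )
    if W.sum() <= 0:
        raise ValueError("total weight must be positive")
    return W


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel communities 0..C-1 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


@dataclass(frozen=True)
class Partition:
    """A community assignment together with its modularity Q."""

    labels: np.ndarray
    quality: float

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1


def modularity(W: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Newman-Girvan weighted modularity of a partition."""
    W = _check_weights(W)
    labels = np.asarray(labels)
    if labels.shape[0] != W.shape[0]:
        raise ValueError("one label per node required")
    two_m = W.sum()
    k = W.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        members = labels == c
        w_c = W[np.ix_(members, members)].sum()
        K_c = k[members].sum()
        q += w_c / two_m - gamma * (K_c / two_m) ** 2
    return float(q)


def _local_moves(
    W: np.ndarray, labels: np.ndarray, gamma: float, rng: np.random.Generator
) -> bool:
    """One-level Louvain: sweep nodes in random order until no move improves Q.

    The gain of placing node i in community c (i removed from its own) is
    w_{i,c}/m - gamma * k_i * K_c / (2 m^2); ties keep the current
    community. Returns whether any move happened.
    """
    n = W.shape[0]
    two_m = W.sum()
    m = two_m / 2.0
    k = W.sum(axis=1)
    # one spare slot keeps the "move to a fresh singleton community" option open
    n_slots = labels.max() + 2
    K = np.bincount(labels, weights=k, minlength=n_slots)
    moved_any = False
    improving = True
    while improving:
        improving = False
        for i in rng.permutation(n):
            a = labels[i]
            K[a] -= k[i]
            w_ic = np.bincount(labels, weights=W[i], minlength=n_slots)
            w_ic[a] -= W[i, i]
            gain = w_ic / m - gamma * k[i] * K / (2 * m * m)
            best = int(np.argmax(gain))
            # strict improvement required; ties keep the current community
            if gain[best] <= gain[a] + 1e-14:
                best = a
            labels[i] = best
            K[best] += k[i]
            if best != a:
                improving = True
                moved_any = True
                if K[-1] > 0:  # the spare slot was taken; open a new one
                    K = np.append(K, 0.0)
                    n_slots += 1
    return moved_any


def _aggregate(W: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n_comm = labels.max() + 1
    S = np.zeros((W.shape[0], n_comm))
    S[np.arange(W.shape[0]), labels] = 1.0
    return S.T @ W @ S


def louvain(W: np.ndarray, gamma: float = 1.0, seed: int | np.random.SeedSequence = 0) -> Partition:
    """Greedy two-phase modularity optimisation (local moves + aggregation).

    Node visit order is shuffled from the seed on every sweep, so repeated
    runs explore different local optima; a given seed is fully
    deterministic. Aggregation repeats until a full cycle improves Q by
    less than 1e-10.
    """
    W = _check_weights(W)
    rng = np.random.default_rng(seed)
    n = W.shape[0]
    node_labels = np.arange(n)
    q_prev = modularity(W, node_labels, gamma)
    # outer cycles restart node-level moves from the current partition, so a
    # single region can still switch community after coarse-level merging
    while True:
        labels = _canonical(node_labels.copy())
        _local_moves(W, labels, gamma, rng)
        node_labels = _canonical(labels)
        level_W = _aggregate(W, node_labels)
        mapping = node_labels
        while level_W.shape[0] > 1:
            lv_labels = np.arange(level_W.shape[0])
            moved = _local_moves(level_W, lv_labels, gamma, rng)
            if not moved:
                break
            lv_labels = _canonical(lv_labels)
            mapping = lv_labels[mapping]
            level_W = _aggregate(level_W, lv_labels)
        node_labels = _canonical(mapping)
        q_now = modularity(W, node_labels, gamma)
        if q_now - q_prev < 1e-10:
            break
        q_prev = q_now
    return Partition(labels=node_labels, quality=modularity(W, node_labels, gamma))


@dataclass
class CoAssignmentMatrix:
    """Probability that two nodes share a community across stochastic runs."""

    values: np.ndarray
    region_labels: list[str]
    runs: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T):
            raise ValueError("co-assignment matrix must be symmetric")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("co-assignment probabilities must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("diagonal must be 1")
        self.values = v


def consensus_coassignment(
    W: np.ndarray,
    runs: int = 100,
    master_seed: int | np.random.SeedSequence = 0,
    gamma: float = 1.0,
    region_labels: list[str] | None = None,
) -> CoAssignmentMatrix:
    """P_ij = fraction of ``runs`` independent Louvain runs assigning i and j together."""
    if runs < 1:
        raise ValueError("runs must be >= 1")
    W = _check_weights(W)
    n = W.shape[0]
    seeds = np.random.SeedSequence(
        master_seed.entropy if isinstance(master_seed, np.random.SeedSequence) else master_seed
    ).spawn(runs)
    counts = np.zeros((n, n))
    for s in seeds:
        labels = louvain(W, gamma=gamma, seed=s).labels
        counts += labels[:, None] == labels[None, :]
    P = counts / runs
    labels_out = region_labels or [f"node_{i}" for i in range(n)]
    return CoAssignmentMatrix(P, labels_out, runs)


@dataclass(frozen=True)
class AffinityScore:
    region: str
    cortex: str
    value: float
    n_members: int


def affinity(
    P: CoAssignmentMatrix, region: str, cortex_members: list[str], cortex: str = ""
) -> AffinityScore:
    """Mean co-assignment probability of ``region`` with a cortex's members.

    The region itself is excluded from the member set; an empty member set
    after exclusion is an error (the affinity is undefined).
    """
    idx = {name: i for i, name in enumerate(P.region_labels)}
    if region not in idx:
        raise ValueError(f"unknown region {region!r}")
    members = [m for m in cortex_members if m != region]
    if not members:
        raise ValueError(f"cortex has no members other than {region!r}")
    unknown = [m for m in members if m not in idx]
    if unknown:
        raise ValueError(f"unknown cortex member(s) {unknown}")
    i = idx[region]
    vals = [P.values[i, idx[j]] for j in members]
    return AffinityScore(
        region=region, cortex=cortex, value=float(np.mean(vals)), n_members=len(members)
    )
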
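"""Least-squares clustering of residue types into D chemical families.

The 20x20 contact-energy matrix is compressed to a DxD matrix of block
means; the assignment is chosen to minimize the squared reconstruction
error. Small alphabets are solved exhaustively, larger ones by seeded
multi-restart local search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy_model import (
    InteractionModel,
    ResidueAlphabet,
    _normalize_code,
)

__all__ = [
    "ClusterMap",
    "ClusteredModel",
    "fit_cluster_map",
    "clustered_energy",
    "clustered_sigma",
    "clustered_freq",
    "build_clustered_model",
    "cluster_loss",
]

#: exhaustive search is used when the number of set partitions into D
#: nonempty unlabeled families does not exceed this bound
EXHAUSTIVE_BOUND = 200_000


@dataclass(frozen=True)
class ClusterMap:
    """Assignment of each residue type to a family index in 0..D-1."""

    assignment: np.ndarray
    D: int
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        if not (2 <= self.D <= len(a)):
            raise ValueError(f"D={self.D} out of range for {len(a)} types")
        if a.min() < 0 or a.max() >= self.D:
            raise ValueError("family indices out of range")
        if len(np.unique(a)) != self.D:
            raise ValueError("every family must be nonempty")
        object.__setattr__(self, "assignment", a)

    @property
    def n_types(self) -> int:
        return len(self.assignment)

    def members(self, family: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == family)

    def family_of(self, code: str) -> int:
        if not self.labels:
            raise ValueError("cluster map carries no residue labels")
        code = _normalize_code(code)
        try:
            return int(self.assignment[self.labels.index(code)])
        except ValueError:
            raise KeyError(f"unknown residue type {code!r}") from None

    def to_text(self) -> str:
        if not self.labels:
            raise ValueError("cluster map carries no residue labels")
        return "\n".join(
            f"{c} {int(f)}" for c, f in zip(self.labels, self.assignment)
        ) + "\n"

    @classmethod
    def from_text(cls, text: str, D: int | None = None) -> "ClusterMap":
        labels, fams = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            c, f = line.split()
            labels.append(c)
            fams.append(int(f))
        fams = np.asarray(fams)
        return cls(fams, D=D if D is not None else fams.max() + 1,
                   labels=tuple(labels))


@dataclass(frozen=True)
class ClusteredModel:
    """Effective DxD interaction model plus the generating assignment."""

    eps_prime: np.ndarray
    sigma_prime: np.ndarray
    freq_prime: np.ndarray
    map: ClusterMap

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps_prime, dtype=float)
        if not np.allclose(eps, eps.T, atol=1e-9):
            raise ValueError("clustered energies must be symmetric")
        if abs(float(np.sum(self.freq_prime)) - 1.0) > 1e-9:
            raise ValueError("family frequencies must sum to 1")


def clustered_energy(e: np.ndarray, cmap: ClusterMap) -> np.ndarray:
    """Block-mean DxD matrix: e'_IJ = mean of e_kl over k in I, l in J.

    Diagonal blocks include the k = l pairs, so singleton families
    reproduce the original entries exactly.
    """
    e = np.asarray(e, dtype=float)
    if e.shape != (cmap.n_types, cmap.n_types):
        raise ValueError("matrix shape does not match cluster map")
    out = np.empty((cmap.D, cmap.D))
    for i in range(cmap.D):
        mi = cmap.members(i)
        for j in range(i, cmap.D):
            mj = cmap.members(j)
            out[i, j] = out[j, i] = e[np.ix_(mi, mj)].mean()
    return out


def clustered_sigma(alphabet: ResidueAlphabet, cmap: ClusterMap) -> np.ndarray:
    """Per-family diameter: unweighted mean over the family members."""
    return np.array(
        [alphabet.vdw_diameter[cmap.members(i)].mean() for i in range(cmap.D)]
    )


def clustered_freq(alphabet: ResidueAlphabet, cmap: ClusterMap) -> np.ndarray:
    # summed (not averaged) so family frequencies stay a distribution
    return np.array(
        [alphabet.surface_freq[cmap.members(i)].sum() for i in range(cmap.D)]
    )


def cluster_loss(e: np.ndarray, assignment: np.ndarray, D: int) -> float:
    """Squared reconstruction error of the block-mean compression."""
    e = np.asarray(e, dtype=float)
    ep = _block_means(e, assignment, D)
    return float(np.sum((e - ep[np.ix_(assignment, assignment)]) ** 2))


def _block_means(e: np.ndarray, assignment: np.ndarray, D: int) -> np.ndarray:
    n = len(assignment)
    onehot = np.zeros((n, D))
    onehot[np.arange(n), assignment] = 1.0
    counts = onehot.sum(axis=0)
    block_sum = onehot.T @ e @ onehot
    return block_sum / np.outer(counts, counts)


def _canonicalize(e: np.ndarray, assignment: np.ndarray, D: int) -> np.ndarray:
    """Relabel families by ascending mean self-energy e'_II."""
    ep = _block_means(e, assignment, D)
    order = np.argsort(np.diag(ep), kind="stable")
    relabel = np.empty(D, dtype=int)
    relabel[order] = np.arange(D)
    return relabel[assignment]


def _partition_count(n: int, d: int) -> int:
    # Stirling number of the second kind S(n, d)
    table = [[0] * (d + 1) for _ in range(n + 1)]
    table[0][0] = 1
    for i in range(1, n + 1):
        for j in range(1, min(i, d) + 1):
            table[i][j] = j * table[i - 1][j] + table[i - 1][j - 1]
    return table[n][d]


def _iter_partitions(n: int, d: int):
    """Restricted-growth strings with exactly d blocks."""
    a = np.zeros(n, dtype=int)

    def rec(i: int, maxused: int):
        if i == n:
            if maxused + 1 == d:
                yield a.copy()
            return
        # pruning: remaining positions must be able to open missing blocks
        remaining = n - i
        need = d - (maxused + 1)
        if need > remaining:
            return
        for v in range(min(maxused + 1, d - 1) + 1):
            a[i] = v
            yield from rec(i + 1, max(maxused, v))

    yield from rec(0, -1)


def fit_cluster_map(
    e: np.ndarray,
    D: int,
    labels: tuple[str, ...] = (),
    *,
    n_restarts: int = 50,
    n_sweeps: int = 400,
    seed: int | None = None,
    exhaustive_bound: int = EXHAUSTIVE_BOUND,
) -> tuple[ClusterMap, float]:
    """Find the family assignment minimizing the reconstruction loss.

    Exhaustive over set partitions when their count is within
    ``exhaustive_bound``; otherwise seeded annealed local search over
    single-type reassignments with multiple restarts. Family labels are
    canonicalized by ascending mean self-energy.
    """
    e = np.asarray(e, dtype=float)
    n = e.shape[0]
    if e.shape != (n, n):
        raise ValueError("energy matrix must be square")
    if not 2 <= D <= n:
        raise ValueError(f"D={D} must be in [2, {n}]")

    if D == n:
        best = np.arange(n)
    elif _partition_count(n, D) <= exhaustive_bound:
        best, best_loss = None, np.inf
        for a in _iter_partitions(n, D):
            loss = cluster_loss(e, a, D)
            if loss < best_loss - 1e-15:
                best_loss, best = loss, a
    else:
        rng = np.random.default_rng(seed)
        best, best_loss = None, np.inf
        for _ in range(n_restarts):
            a = _local_search(e, D, rng, n_sweeps)
            loss = cluster_loss(e, a, D)
            if loss < best_loss - 1e-15:
                best_loss, best = loss, a

    best = _canonicalize(e, best, D)
    final_loss = cluster_loss(e, best, D)
    return ClusterMap(best, D=D, labels=labels), final_loss


def _local_search(
    e: np.ndarray, D: int, rng: np.random.Generator, n_sweeps: int
) -> np.ndarray:
    n = e.shape[0]
    # random init with every family nonempty
    a = np.concatenate([np.arange(D), rng.integers(0, D, n - D)])
    rng.shuffle(a)
    cur = cluster_loss(e, a, D)
    temps = np.geomspace(1.0, 1e-3, n_sweeps) * max(cur, 1e-12) / n
    for t in temps:
        for i in rng.permutation(n):
            old = a[i]
            if np.count_nonzero(a == old) == 1:
                continue  # would empty the family
            new = int(rng.integers(0, D))
            if new == old:
                continue
            a[i] = new
            trial = cluster_loss(e, a, D)
            if trial <= cur or rng.random() < np.exp(-(trial - cur) / t):
                cur = trial
            else:
                a[i] = old
    # greedy polish to a local minimum
    improved = True
    while improved:
        improved = False
        for i in range(n):
            old = a[i]
            if np.count_nonzero(a == old) == 1:
                continue
            for new in range(D):
                if new == old:
                    continue
                a[i] = new
                trial = cluster_loss(e, a, D)
                if trial < cur - 1e-12:
                    cur, old = trial, new
                    improved = True
                else:
                    a[i] = old
            a[i] = old
    return a


def build_clustered_model(
    e: np.ndarray,
    alphabet: ResidueAlphabet,
    cmap: ClusterMap,
    lambda_scale: float,
    e0: float,
    cutoff: float = 8.5,
) -> tuple[ClusteredModel, InteractionModel]:
    """Effective clustered model and its pair-potential form.

    The clustered raw energies are rescaled with the same (lambda, e0)
    used for the full alphabet.
    """
    ep = clustered_energy(e, cmap)
    sp = clustered_sigma(alphabet, cmap)
    fp = clustered_freq(alphabet, cmap)
    clustered = ClusteredModel(ep, sp, fp, cmap)
    fam = {code: int(cmap.assignment[i]) for i, code in enumerate(alphabet.names)}
    model = InteractionModel(
        labels=tuple(f"F{i}" for i in range(cmap.D)),
        epsilon=lambda_scale * (ep - e0),
        sigma=sp,
        freq=fp,
        residue_family=fam,
        cutoff=cutoff,
    )
    return clustered, model
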
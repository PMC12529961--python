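"""Ground-state search for the design Hamiltonian.

Three routes: exhaustive enumeration (the correctness oracle on tiny
instances), native single-flip Metropolis simulated annealing, and a
pluggable external-backend protocol for commercial or quantum solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from .qubo_model import QuboModel

__all__ = [
    "SolveResult",
    "Spectrum",
    "SolverBackend",
    "brute_force",
    "simulated_annealing",
    "spectrum_stats",
    "BRUTE_FORCE_BOUND",
]

BRUTE_FORCE_BOUND = 22


@dataclass(frozen=True)
class SolveResult:
    """One solver run: the best bitstring found and its energy."""

    bits: np.ndarray
    energy: float
    solver: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "bits", np.asarray(self.bits, dtype=np.uint8)
        )


@dataclass
class Spectrum:
    """Minimum-energy values over repeated independent runs."""

    results: list[SolveResult]

    @property
    def energies(self) -> np.ndarray:
        return np.array([r.energy for r in self.results])

    def sorted_energies(self) -> np.ndarray:
        return np.sort(self.energies)

    def __len__(self) -> int:
        return len(self.results)


class SolverBackend(Protocol):
    """Contract for external optimizers (classical or quantum).

    Implementations receive the serialized QUBO (JSON, see
    :meth:`QuboModel.to_json`) and return one :class:`SolveResult` per
    independent run. Never required by the test suite.
    """

    def solve(self, qubo_json: str, n_runs: int, seed: int | None
              ) -> list[SolveResult]: ...


def brute_force(
    model: QuboModel, bound: int = BRUTE_FORCE_BOUND, tol: float = 1e-9
) -> tuple[list[np.ndarray], float]:
    """Exhaustively enumerate all bitstrings; exact ground states.

    Returns every optimal bitstring (in ascending integer order, LSB =
    variable 0) and the ground energy.
    """
    n = model.n_variables
    if n > bound:
        raise ValueError(
            f"{n} variables exceeds the brute-force bound ({bound}); "
            "use simulated_annealing or raise the bound explicitly"
        )
    total = 1 << n
    chunk = min(total, 1 << 16)
    best_e = np.inf
    best_codes: list[int] = []
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total), dtype=np.uint64)
        bits = (codes[:, None] >> np.arange(n, dtype=np.uint64)) & 1
        e = model.energies(bits)
        lo = float(e.min())
        if lo < best_e - tol:
            best_e = lo
            best_codes = [int(c) for c in codes[np.abs(e - lo) <= tol]]
        elif lo <= best_e + tol:
            best_codes.extend(int(c) for c in codes[np.abs(e - best_e) <= tol])
    states = [
        ((np.uint64(c) >> np.arange(n, dtype=np.uint64)) & 1).astype(np.uint8)
        for c in best_codes
    ]
    return states, best_e


def _adjacency(model: QuboModel) -> list[list[tuple[int, float]]]:
    adj: list[list[tuple[int, float]]] = [[] for _ in range(model.n_variables)]
    for (i, j), c in model.quadratic.items():
        adj[i].append((j, c))
        adj[j].append((i, c))
    return adj


def _flip_delta(
    bits: np.ndarray, i: int, lin: np.ndarray,
    adj: list[list[tuple[int, float]]],
) -> float:
    s = lin[i]
    for j, c in adj[i]:
        s += c * bits[j]
    return (1.0 - 2.0 * bits[i]) * s


def simulated_annealing(
    model: QuboModel,
    n_runs: int = 10,
    n_sweeps: int = 1000,
    seed: int | None = None,
    beta_range: tuple[float, float] | None = None,
    decoder: Callable[[np.ndarray], str] | None = None,
) -> Spectrum:
    """Single-flip Metropolis annealing with a geometric inverse-temperature
    schedule; returns the best-of-trajectory state per run.

    The schedule is auto-scaled from the coefficient magnitudes: hot enough
    that the largest single-flip move is accepted with probability ~0.8,
    cold enough that the smallest is accepted with probability ~0.01.
    """
    if n_runs < 1 or n_sweeps < 1:
        raise ValueError("n_runs and n_sweeps must be positive")
    n = model.n_variables
    lin = np.zeros(n)
    for i, c in model.linear.items():
        lin[i] = c
    adj = _adjacency(model)

    if beta_range is None:
        scale = [abs(c) for c in model.linear.values()]
        scale += [abs(c) for c in model.quadratic.values()]
        hi = max(scale, default=1.0) or 1.0
        lo = min((s for s in scale if s > 0), default=hi)
        beta_hot = -np.log(0.8) / hi
        beta_cold = -np.log(0.01) / lo
        if beta_cold <= beta_hot:
            beta_cold = beta_hot * 100.0
        beta_range = (beta_hot, beta_cold)
    betas = np.geomspace(beta_range[0], beta_range[1], n_sweeps)

    rng = np.random.default_rng(seed)
    results = []
    for run in range(n_runs):
        bits = rng.integers(0, 2, n).astype(np.float64)
        energy = model.energy(bits)
        best_bits, best_e = bits.copy(), energy
        for beta in betas:
            u = rng.random(n)
            for i in range(n):
                d = _flip_delta(bits, i, lin, adj)
                if d <= 0.0 or u[i] < np.exp(-beta * d):
                    bits[i] = 1.0 - bits[i]
                    energy += d
            if energy < best_e:
                best_e, best_bits = energy, bits.copy()
        best_e = model.energy(best_bits)  # guard against float drift
        meta = {"run": run, "seed": seed, "sweeps": n_sweeps}
        if decoder is not None:
            meta["sequence"] = decoder(best_bits.astype(np.uint8))
        results.append(
            SolveResult(best_bits, best_e, solver="sa", meta=meta)
        )
    return Spectrum(results)


def spectrum_stats(spectrum: Spectrum) -> dict:
    """Lowest / mean minimum-energy value and distinct-solution count."""
    if len(spectrum) == 0:
        raise ValueError("spectrum is empty")
    energies = spectrum.energies
    keys: Sequence = [
        r.meta.get("sequence", r.bits.tobytes()) for r in spectrum.results
    ]
    return {
        "lowest": float(energies.min()),
        "mean": float(energies.mean()),
        "n_runs": len(spectrum),
        "n_distinct": len(set(keys)),
    }
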
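"""Bitstring decoding and second-stage full-alphabet sequence refinement.

Decoding turns a solver bitstring back into a lattice peptide (ordered
site path plus per-position type), flags invalid topologies, and strips
disconnected rings. Refinement freezes the geometry and re-optimizes the
sequence over all 20 residues with a one-hot encoded QUBO.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy_model import InteractionModel, Receptor, pair_potential
from .pocket_lattice import ExternalField, PocketGrid, external_field
from .qubo_model import QuboModel, VariableRegistry

__all__ = [
    "ChainDecode",
    "RefinementProblem",
    "decode",
    "chain_physical_energy",
    "build_refinement",
    "decode_refinement",
    "random_sequences",
]


@dataclass(frozen=True)
class ChainDecode:
    """Decoded lattice peptide with validity diagnostics.

    ``path`` is ordered from anchor s to anchor t; ``sequence`` holds one
    type index per path position. ``length`` counts bonds (residues are
    ``length + 1`` when the path is valid).
    """

    path: tuple[int, ...]
    sequence: tuple[int, ...]
    valid_path: bool
    had_rings: bool = False
    ring_components: tuple[tuple[int, ...], ...] = ()
    diagnostic: str = ""

    @property
    def length(self) -> int:
        return max(len(self.path) - 1, 0)

    @property
    def n_residues(self) -> int:
        return len(self.path)


def decode(
    bits: np.ndarray, registry: VariableRegistry, grid: PocketGrid
) -> ChainDecode:
    """Interpret a bitstring as a lattice peptide.

    Walks the bond graph from anchor s; the s-t component must be a simple
    path with exactly one type per occupied site and consistent ancillas.
    Components disjoint from the chain are reported as rings and removed.
    """
    bits = np.asarray(bits).astype(np.uint8)
    if bits.shape != (registry.n_variables,):
        raise ValueError("bitstring length does not match registry")
    s, t = grid.s_index, grid.t_index
    if s is None or t is None:
        raise ValueError("grid has no anchors")

    D = registry.n_families
    occupancy: dict[int, list[int]] = {}
    for i in range(registry.n_sites):
        ks = [k for k in range(D) if bits[registry.site_var(i, k)]]
        if ks:
            occupancy[i] = ks

    adj: dict[int, list[int]] = {}
    bonded_edges = []
    for i, j in registry.edges:
        if bits[registry.bond_var(i, j)]:
            bonded_edges.append((i, j))
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)

    def fail(msg: str) -> ChainDecode:
        return ChainDecode((), (), valid_path=False, diagnostic=msg)

    if s not in occupancy:
        return fail("anchor s is unoccupied")
    if t not in occupancy:
        return fail("anchor t is unoccupied")

    # walk from s along the unique unvisited bonded neighbor
    path = [s]
    visited = {s}
    cur = s
    while cur != t:
        nxt = [j for j in adj.get(cur, []) if j not in visited]
        if len(nxt) != 1:
            back = [j for j in adj.get(cur, []) if j in visited]
            if not nxt and not back:
                return fail(f"chain dead-ends at site {cur}")
            if len(nxt) > 1 or len(adj.get(cur, [])) > 2:
                return fail(f"branching (degree > 2) at site {cur}")
            return fail(f"chain dead-ends at site {cur}")
        cur = nxt[0]
        if cur in visited:
            return fail("chain revisits a site")
        visited.add(cur)
        path.append(cur)
    if len(adj.get(t, [])) > 1:
        return fail("anchor t has more than one bond")
    if len(adj.get(s, [])) > 1:
        return fail("anchor s has more than one bond")

    # occupancy / ancilla consistency along the chain
    sequence = []
    for n, site in enumerate(path):
        ks = occupancy.get(site)
        if ks is None:
            return fail(f"bonded site {site} carries no type")
        if len(ks) != 1:
            return fail(f"site {site} carries {len(ks)} types")
        sequence.append(ks[0])
    for a, b in zip(path, path[1:]):
        lo, hi = min(a, b), max(a, b)
        k_lo = sequence[path.index(lo)]
        for k in range(D):
            expect = 1 if k == k_lo else 0
            if bits[registry.anc_var(lo, hi, k)] != expect:
                return fail(f"ancilla inconsistent on edge ({lo},{hi})")

    chain_sites = set(path)
    # anything bonded or occupied outside the chain forms rings/debris
    extra_sites = (set(occupancy) | set(adj)) - chain_sites
    rings: list[tuple[int, ...]] = []
    seen: set[int] = set()
    for start in sorted(extra_sites):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj.get(u, []):
                if v not in comp and v not in chain_sites:
                    comp.add(v)
                    stack.append(v)
        seen |= comp
        rings.append(tuple(sorted(comp)))

    return ChainDecode(
        tuple(path),
        tuple(sequence),
        valid_path=True,
        had_rings=bool(rings),
        ring_components=tuple(rings),
    )


def chain_physical_energy(
    chain: ChainDecode,
    grid: PocketGrid,
    fld: ExternalField,
    model: InteractionModel,
    ablate_E0: bool = False,
) -> float:
    """Independent re-evaluation of a decoded chain's design energy.

    Sum of per-residue external field minus offset, plus nonbonded
    intrachain pair energies (consecutive positions excluded).
    """
    if not chain.valid_path:
        raise ValueError("chain is not a valid path")
    e = 0.0
    for site, k in zip(chain.path, chain.sequence):
        e += fld.E[site, k] - (0.0 if ablate_E0 else fld.E0[k])
    params = model.params()
    for n in range(chain.n_residues):
        for m in range(n + 2, chain.n_residues):
            r = float(
                np.linalg.norm(
                    grid.sites[chain.path[n]] - grid.sites[chain.path[m]]
                )
            )
            if 0 < r < model.cutoff:
                e += pair_potential(
                    chain.sequence[n], chain.sequence[m], r, params
                )
    return e


@dataclass(frozen=True)
class RefinementProblem:
    """Stage-2 QUBO: one-hot residue choice per frozen chain position."""

    qubo: QuboModel
    n_positions: int
    n_types: int
    path: tuple[int, ...]
    fld: ExternalField = field(repr=False, default=None)

    def var(self, position: int, residue: int) -> int:
        return position * self.n_types + residue


def build_refinement(
    chain: ChainDecode,
    grid: PocketGrid,
    receptor: Receptor,
    model: InteractionModel,
    A: float = 20.0,
    n_contacts: float | None = None,
    fld: ExternalField | None = None,
    ablate_E0: bool = False,
) -> RefinementProblem:
    """Full-alphabet sequence optimization on the frozen geometry.

    Variables q_n^(a): position n along the chain holds residue a. Linear
    terms are the (field - offset) energies at the path sites; quadratic
    terms couple non-consecutive positions within the cutoff. One-hot is
    enforced with an exactly-one square plus pairwise occupancy penalties.
    """
    if not chain.valid_path:
        raise ValueError("cannot refine an invalid chain")
    nP, nT = chain.n_residues, model.n_types
    if fld is None:
        fld = external_field(grid, receptor, model, n_contacts=n_contacts)
    qubo = QuboModel(nP * nT)

    def var(n: int, a: int) -> int:
        return n * nT + a

    for n, site in enumerate(chain.path):
        for a in range(nT):
            coeff = fld.E[site, a] - (0.0 if ablate_E0 else fld.E0[a])
            qubo.add_linear(var(n, a), coeff)
        qubo.add_square(1.0, [(var(n, a), -1.0) for a in range(nT)], scale=A)
        for a in range(nT):
            for b in range(a + 1, nT):
                qubo.add_quadratic(var(n, a), var(n, b), A)

    params = model.params()
    for n in range(nP):
        for m in range(n + 2, nP):
            r = float(
                np.linalg.norm(
                    grid.sites[chain.path[n]] - grid.sites[chain.path[m]]
                )
            )
            if not 0 < r < model.cutoff:
                continue
            for a in range(nT):
                for b in range(nT):
                    u = pair_potential(a, b, r, params)
                    if u:
                        qubo.add_quadratic(var(n, a), var(m, b), float(u))
    qubo.params = {"A": A, "n_positions": nP, "n_types": nT}
    return RefinementProblem(qubo, nP, nT, chain.path, fld)


def decode_refinement(
    bits: np.ndarray, problem: RefinementProblem, labels: tuple[str, ...]
) -> str:
    """Read the one-hot refinement solution back into a sequence string."""
    bits = np.asarray(bits).astype(np.uint8)
    seq = []
    for n in range(problem.n_positions):
        chosen = [a for a in range(problem.n_types)
                  if bits[problem.var(n, a)]]
        if len(chosen) != 1:
            raise ValueError(f"position {n} holds {len(chosen)} residues")
        seq.append(labels[chosen[0]])
    return "".join(seq)


def random_sequences(
    length: int, n: int, seed: int | None = None,
    alphabet: tuple[str, ...] | None = None,
) -> list[str]:
    """Uniform i.i.d. random peptide sequences (reproducible by seed)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if alphabet is None:
        from .energy_model import CANONICAL_CODES
        alphabet = CANONICAL_CODES
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(alphabet), size=(n, length))
    return ["".join(alphabet[i] for i in row) for row in draws]
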
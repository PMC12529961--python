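"""Binary-quadratic encoding of the joint sequence/pose design problem.

Variables: site occupancies q_i^(k) (site i holds a type-k bead), bond
indicators q_ij on lattice edges, and ancillas q_ij^(k) that track the
product q_i^(k) * q_ij so bonded-pair interactions can be cancelled while
keeping the Hamiltonian quadratic. Terms:

* external field  — per-site type energies minus the mean-field offset
* intrachain      — nonbonded pair interactions within the peptide
* ancilla         — AND-penalty tying each ancilla to its product
* occupancy       — at most one type per site
* path            — end points bind once, internal sites twice (linear chain)
* chain length    — soft quadratic pull of the bond count toward L0
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .energy_model import InteractionModel, pair_potential_matrix
from .pocket_lattice import ExternalField, PocketGrid

__all__ = [
    "VariableRegistry",
    "QuboModel",
    "IsingModel",
    "QuboParams",
    "external_term",
    "intrachain_term",
    "ancilla_term",
    "occupancy_term",
    "path_term",
    "chain_length_term",
    "soft_coefficient_mass",
    "assemble",
    "to_ising",
    "variable_count",
    "w_from_tolerance",
    "admissible_length_bounds",
]


class RegistryMismatch(ValueError):
    pass


@dataclass(frozen=True)
class VariableRegistry:
    """Index bookkeeping for site, bond and ancilla binaries.

    Layout: site variables first (site-major, type-minor), then one bond
    variable per edge, then ancillas (edge-major, type-minor). Each
    ancilla is attached to the lower-indexed endpoint of its edge.
    """

    n_sites: int
    n_families: int
    edges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        edges = tuple((min(i, j), max(i, j)) for i, j in self.edges)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(
            self, "_edge_index", {e: n for n, e in enumerate(edges)}
        )

    @classmethod
    def from_grid(cls, grid: PocketGrid, n_families: int) -> "VariableRegistry":
        return cls(grid.n_sites, n_families, grid.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_variables(self) -> int:
        return self.n_sites * self.n_families + self.n_edges * (1 + self.n_families)

    def site_var(self, i: int, k: int) -> int:
        return i * self.n_families + k

    def bond_var(self, i: int, j: int) -> int:
        e = self._edge_index.get((min(i, j), max(i, j)))
        if e is None:
            raise RegistryMismatch(f"({i},{j}) is not a lattice edge")
        return self.n_sites * self.n_families + e

    def anc_var(self, i: int, j: int, k: int) -> int:
        e = self._edge_index.get((min(i, j), max(i, j)))
        if e is None:
            raise RegistryMismatch(f"({i},{j}) is not a lattice edge")
        base = self.n_sites * self.n_families + self.n_edges
        return base + e * self.n_families + k

    def name(self, idx: int) -> str:
        nS, D, nE = self.n_sites, self.n_families, self.n_edges
        if idx < nS * D:
            return f"q[{idx // D}]({idx % D})"
        idx -= nS * D
        if idx < nE:
            i, j = self.edges[idx]
            return f"q[{i},{j}]"
        idx -= nE
        i, j = self.edges[idx // D]
        return f"q[{i},{j}]({idx % D})"

    def names(self) -> list[str]:
        return [self.name(i) for i in range(self.n_variables)]


@dataclass
class QuboModel:
    """Sparse quadratic pseudo-Boolean polynomial over a registry."""

    n_variables: int
    linear: dict = field(default_factory=dict)
    quadratic: dict = field(default_factory=dict)
    offset: float = 0.0
    params: dict = field(default_factory=dict)
    registry: VariableRegistry | None = None
    components: dict = field(default_factory=dict)

    def add_linear(self, i: int, c: float) -> None:
        if c != 0.0:
            self.linear[i] = self.linear.get(i, 0.0) + c

    def add_quadratic(self, i: int, j: int, c: float) -> None:
        if i == j:
            raise ValueError("no self-pairs; fold q^2 = q into linear")
        if c != 0.0:
            key = (min(i, j), max(i, j))
            self.quadratic[key] = self.quadratic.get(key, 0.0) + c

    def add_square(self, constant: float, terms: list[tuple[int, float]],
                   scale: float = 1.0) -> None:
        """Add scale * (constant + sum c_i q_i)^2, using q^2 = q."""
        self.offset += scale * constant * constant
        for n, (i, ci) in enumerate(terms):
            self.add_linear(i, scale * (2.0 * constant * ci + ci * ci))
            for j, cj in terms[n + 1:]:
                if i == j:
                    self.add_linear(i, scale * 2.0 * ci * cj)
                else:
                    self.add_quadratic(i, j, scale * 2.0 * ci * cj)

    def energy(self, bits: np.ndarray) -> float:
        bits = np.asarray(bits)
        e = self.offset
        for i, c in self.linear.items():
            e += c * bits[i]
        for (i, j), c in self.quadratic.items():
            e += c * bits[i] * bits[j]
        return float(e)

    def energies(self, bitmatrix: np.ndarray) -> np.ndarray:
        """Vectorized evaluation over rows of a (M, n) bit matrix."""
        X = np.asarray(bitmatrix, dtype=float)
        out = np.full(len(X), self.offset)
        if self.linear:
            idx = np.fromiter(self.linear.keys(), dtype=int)
            c = np.fromiter(self.linear.values(), dtype=float)
            out += X[:, idx] @ c
        if self.quadratic:
            pairs = np.array(list(self.quadratic.keys()), dtype=int)
            c = np.fromiter(self.quadratic.values(), dtype=float)
            out += (X[:, pairs[:, 0]] * X[:, pairs[:, 1]]) @ c
        return out

    def __iadd__(self, other: "QuboModel") -> "QuboModel":
        if other.n_variables != self.n_variables:
            raise RegistryMismatch("models built on different registries")
        for i, c in other.linear.items():
            self.add_linear(i, c)
        for (i, j), c in other.quadratic.items():
            self.add_quadratic(i, j, c)
        self.offset += other.offset
        return self

    def copy(self) -> "QuboModel":
        return QuboModel(
            self.n_variables, dict(self.linear), dict(self.quadratic),
            self.offset, dict(self.params), self.registry,
        )

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        names = (
            self.registry.names()
            if self.registry is not None
            else [f"x{i}" for i in range(self.n_variables)]
        )
        return json.dumps(
            {
                "variables": names,
                "linear": {str(i): c for i, c in sorted(self.linear.items())},
                "quadratic": {
                    f"{i},{j}": c for (i, j), c in sorted(self.quadratic.items())
                },
                "offset": self.offset,
                "params": self.params,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "QuboModel":
        d = json.loads(text)
        lin = {int(k): v for k, v in d["linear"].items()}
        quad = {
            tuple(int(x) for x in k.split(",")): v
            for k, v in d["quadratic"].items()
        }
        return cls(len(d["variables"]), lin, quad, d["offset"], d.get("params", {}))

    def to_coordinate_text(self) -> str:
        """One term per line: `i i c` (linear) / `i j c` (quadratic)."""
        lines = [f"# offset {float(self.offset)!r}"]
        for i, c in sorted(self.linear.items()):
            lines.append(f"{i} {i} {float(c)!r}")
        for (i, j), c in sorted(self.quadratic.items()):
            lines.append(f"{i} {j} {float(c)!r}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class IsingModel:
    """Spin (+/-1) form: H = offset + sum h_l s_l + sum_{l<m} J_lm s_l s_m."""

    n_variables: int
    h: dict
    J: dict
    offset: float

    def energy(self, spins: np.ndarray) -> float:
        s = np.asarray(spins)
        e = self.offset
        for i, c in self.h.items():
            e += c * s[i]
        for (i, j), c in self.J.items():
            e += c * s[i] * s[j]
        return float(e)


@dataclass(frozen=True)
class QuboParams:
    """Weights of the assembled Hamiltonian."""

    A: float = 20.0
    L0: int = 10
    w: float | None = None  # defaults to A (stiff chain) when p is None
    p: float | None = None  # length-fluctuation fraction; sets w = A/(L0 p)^2
    ablate_E0: bool = False

    def resolved_w(self) -> float:
        if self.w is not None:
            return self.w
        if self.p is not None:
            return w_from_tolerance(self.A, self.L0, self.p)
        return self.A


def _new(registry: VariableRegistry) -> QuboModel:
    return QuboModel(registry.n_variables, registry=registry)


def external_term(
    fld: ExternalField, registry: VariableRegistry, ablate_E0: bool = False
) -> QuboModel:
    """Linear field (E_i^(k) - E0^(k)) on each site variable."""
    if fld.E.shape != (registry.n_sites, registry.n_families):
        raise RegistryMismatch(
            f"field shape {fld.E.shape} does not match registry "
            f"({registry.n_sites} sites x {registry.n_families} families)"
        )
    m = _new(registry)
    for i in range(registry.n_sites):
        for k in range(registry.n_families):
            coeff = fld.E[i, k] - (0.0 if ablate_E0 else fld.E0[k])
            m.add_linear(registry.site_var(i, k), coeff)
    return m


def intrachain_term(
    grid: PocketGrid, model: InteractionModel, registry: VariableRegistry
) -> QuboModel:
    """Nonbonded peptide self-interaction with bonded-pair cancellation.

    For every unordered site pair within the cutoff, the pair energy
    u_kl(r_ij) couples q_i^(k) q_j^(l). On lattice edges the matching
    ancilla subtracts the bonded contribution: (q_i^(k) - q_ij^(k)) q_j^(l).
    """
    m = _new(registry)
    cutoff = model.cutoff
    edge_set = set(registry.edges)
    D = registry.n_families
    for i in range(grid.n_sites):
        for j in range(i + 1, grid.n_sites):
            r = float(np.linalg.norm(grid.sites[i] - grid.sites[j]))
            if r >= cutoff:
                continue
            u = pair_potential_matrix(r, model.params())
            is_edge = (i, j) in edge_set
            for k in range(D):
                for l in range(D):
                    c = float(u[k, l])
                    if c == 0.0:
                        continue
                    m.add_quadratic(
                        registry.site_var(i, k), registry.site_var(j, l), c
                    )
                    if is_edge:
                        m.add_quadratic(
                            registry.anc_var(i, j, k),
                            registry.site_var(j, l),
                            -c,
                        )
    return m


def ancilla_term(registry: VariableRegistry, A: float) -> QuboModel:
    """AND-penalty: minimum 0 exactly when q_ij^(k) = q_i^(k) * q_ij."""
    if A <= 0:
        raise ValueError("A must be positive")
    m = _new(registry)
    for i, j in registry.edges:
        b = registry.bond_var(i, j)
        for k in range(registry.n_families):
            s = registry.site_var(i, k)
            a = registry.anc_var(i, j, k)
            m.add_linear(a, 3.0 * A)
            m.add_quadratic(s, b, A)
            m.add_quadratic(s, a, -2.0 * A)
            m.add_quadratic(b, a, -2.0 * A)
    return m


def occupancy_term(registry: VariableRegistry, A: float) -> QuboModel:
    """At most one type per site: A per violating unordered type pair."""
    if A <= 0:
        raise ValueError("A must be positive")
    m = _new(registry)
    for i in range(registry.n_sites):
        for k in range(registry.n_families):
            for l in range(k + 1, registry.n_families):
                m.add_quadratic(
                    registry.site_var(i, k), registry.site_var(i, l), A
                )
    return m


def path_term(
    registry: VariableRegistry, s: int, t: int, A: float
) -> QuboModel:
    """Linear-chain topology: anchors bind once, internal sites twice."""
    if A <= 0:
        raise ValueError("A must be positive")
    if s == t or not (0 <= s < registry.n_sites and 0 <= t < registry.n_sites):
        raise ValueError("invalid anchor sites")
    m = _new(registry)
    neighbors: dict[int, list[int]] = {i: [] for i in range(registry.n_sites)}
    for i, j in registry.edges:
        neighbors[i].append(j)
        neighbors[j].append(i)

    for anchor in (s, t):
        occ = [(registry.site_var(anchor, k), 1.0)
               for k in range(registry.n_families)]
        # exactly one bead at the anchor
        m.add_square(1.0, [(v, -c) for v, c in occ], scale=A)
        # anchor's bond count equals its occupancy
        bonds = [(registry.bond_var(anchor, j), -1.0) for j in neighbors[anchor]]
        m.add_square(0.0, occ + bonds, scale=A)

    for r in range(registry.n_sites):
        if r in (s, t):
            continue
        occ = [(registry.site_var(r, k), 2.0)
               for k in range(registry.n_families)]
        bonds = [(registry.bond_var(r, j), -1.0) for j in neighbors[r]]
        m.add_square(0.0, occ + bonds, scale=A)
    return m


def chain_length_term(
    registry: VariableRegistry, L0: int, w: float
) -> QuboModel:
    """Soft constraint w * (L0 - sum of bond variables)^2."""
    if L0 < 1:
        raise ValueError("L0 must be >= 1")
    if w <= 0:
        raise ValueError("w must be positive")
    m = _new(registry)
    terms = [(registry.bond_var(i, j), -1.0) for i, j in registry.edges]
    m.add_square(float(L0), terms, scale=w)
    return m


def assemble(
    grid: PocketGrid,
    fld: ExternalField,
    model: InteractionModel,
    params: QuboParams,
) -> QuboModel:
    """Merge all terms into the full design Hamiltonian."""
    if grid.s_index is None or grid.t_index is None:
        raise ValueError("grid has no anchor sites; call pick_anchors first")
    registry = VariableRegistry.from_grid(grid, model.n_types)
    parts = {
        "external": external_term(fld, registry, ablate_E0=params.ablate_E0),
        "intrachain": intrachain_term(grid, model, registry),
        "ancilla": ancilla_term(registry, params.A),
        "occupancy": occupancy_term(registry, params.A),
        "path": path_term(registry, grid.s_index, grid.t_index, params.A),
        "chain_length": chain_length_term(
            registry, params.L0, params.resolved_w()
        ),
    }
    total = _new(registry)
    for part in parts.values():
        total += part
    total.params = {
        "A": params.A,
        "w": params.resolved_w(),
        "L0": params.L0,
        "D": model.n_types,
        "ablate_E0": params.ablate_E0,
    }
    total.components = parts
    return total


def soft_coefficient_mass(
    grid: PocketGrid,
    fld: ExternalField,
    model: InteractionModel,
    params: QuboParams,
) -> float:
    """Sum of absolute soft-term coefficients (external + intrachain +
    chain length). An ``A`` strictly above this makes every A-weighted
    constraint hard: no violation can pay for itself."""
    registry = VariableRegistry.from_grid(grid, model.n_types)
    mass = 0.0
    parts = [
        external_term(fld, registry, ablate_E0=params.ablate_E0),
        intrachain_term(grid, model, registry),
        chain_length_term(registry, params.L0, params.resolved_w()),
    ]
    for part in parts:
        mass += sum(abs(c) for c in part.linear.values())
        mass += sum(abs(c) for c in part.quadratic.values())
    return mass


def to_ising(q: QuboModel) -> IsingModel:
    """Substitute q_l = (s_l + 1)/2; energies match on every bitstring."""
    h: dict[int, float] = {}
    J: dict[tuple[int, int], float] = {}
    offset = q.offset
    for i, c in q.linear.items():
        h[i] = h.get(i, 0.0) + c / 2.0
        offset += c / 2.0
    for (i, j), c in q.quadratic.items():
        J[(i, j)] = J.get((i, j), 0.0) + c / 4.0
        h[i] = h.get(i, 0.0) + c / 4.0
        h[j] = h.get(j, 0.0) + c / 4.0
        offset += c / 4.0
    return IsingModel(q.n_variables, h, J, offset)


def variable_count(
    Lx: int, Ly: int, Lz: int, D: int
) -> tuple[int, int]:
    """(exact, estimated) binary-variable counts for a full box grid.

    The estimate Lx*Ly*Lz*(4D+3) counts roughly 3 edges per site; the
    exact count uses the true edge total of the box.
    """
    if min(Lx, Ly, Lz, D) < 1:
        raise ValueError("dimensions must be positive")
    sites = Lx * Ly * Lz
    edges = (
        (Lx - 1) * Ly * Lz + Lx * (Ly - 1) * Lz + Lx * Ly * (Lz - 1)
    )
    exact = sites * D + edges * (1 + D)
    estimate = sites * (4 * D + 3)
    return exact, estimate


def w_from_tolerance(A: float, L0: int, p: float) -> float:
    """Chain-length weight admitting relative length fluctuations ~ p."""
    if p <= 0:
        raise ValueError("p must be positive")
    return A / (L0 ** 2 * p ** 2)


def admissible_length_bounds(L0: int, p: float) -> tuple[float, float]:
    """Bond-count interval [L0(1-p), L0(1+p)] admitted by the soft penalty."""
    if p < 0:
        raise ValueError("p must be non-negative")
    return L0 * (1.0 - p), L0 * (1.0 + p)
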
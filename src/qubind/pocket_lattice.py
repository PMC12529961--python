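"""Cubic pocket lattice, anchor selection and precomputed external field.

The grid fills the binding pocket with points on a cubic lattice whose
spacing matches the peptide-bond length, keeping points near a reference
pose and away from the receptor. Each retained site carries a precomputed
per-type interaction energy with the receptor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .energy_model import (
    InteractionModel,
    Receptor,
    mean_field_offset,
    pair_potential,
)

__all__ = [
    "PocketGrid",
    "ExternalField",
    "GridError",
    "build_grid",
    "pick_anchors",
    "external_field",
    "DEFAULT_SPACING",
    "DEFAULT_INCLUDE_RADIUS",
    "DEFAULT_EXCLUDE_RADIUS",
]

DEFAULT_SPACING = 3.8  # Angstrom, peptide-bond length
DEFAULT_INCLUDE_RADIUS = 7.6
DEFAULT_EXCLUDE_RADIUS = 1.5


class GridError(ValueError):
    pass


@dataclass(frozen=True)
class PocketGrid:
    """Cubic-lattice site set with axis-aligned neighbor edges and anchors."""

    sites: np.ndarray  # (N, 3) Angstrom
    edges: tuple[tuple[int, int], ...]  # unordered (i < j) neighbor pairs
    spacing: float = DEFAULT_SPACING
    s_index: int | None = None
    t_index: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sites = np.asarray(self.sites, dtype=float)
        if sites.ndim != 2 or sites.shape[1] != 3:
            raise GridError("sites must be an (N, 3) array")
        object.__setattr__(self, "sites", sites)
        edges = tuple(
            (min(i, j), max(i, j)) for i, j in self.edges
        )
        object.__setattr__(self, "edges", edges)
        for i, j in edges:
            d = np.linalg.norm(sites[i] - sites[j])
            if abs(d - self.spacing) > 1e-6:
                raise GridError(f"edge ({i},{j}) spans {d:.3f} != spacing")
        if self.s_index is not None and self.s_index == self.t_index:
            raise GridError("anchor sites s and t must differ")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def with_anchors(self, s: int, t: int) -> "PocketGrid":
        return PocketGrid(self.sites, self.edges, self.spacing, s, t,
                          dict(self.provenance))

    @classmethod
    def from_points(
        cls, sites: np.ndarray, spacing: float = DEFAULT_SPACING, **kw
    ) -> "PocketGrid":
        """Build a grid from explicit lattice points, deriving the edges."""
        sites = np.asarray(sites, dtype=float)
        edges = _derive_edges(sites, spacing)
        return cls(sites, edges, spacing, **kw)

    def to_json(self) -> str:
        return json.dumps(
            {
                "spacing": self.spacing,
                "sites": self.sites.tolist(),
                "edges": [list(e) for e in self.edges],
                "s_index": self.s_index,
                "t_index": self.t_index,
                "provenance": self.provenance,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PocketGrid":
        d = json.loads(text)
        return cls(
            np.asarray(d["sites"]),
            tuple(tuple(e) for e in d["edges"]),
            d["spacing"],
            d.get("s_index"),
            d.get("t_index"),
            d.get("provenance", {}),
        )


@dataclass(frozen=True)
class ExternalField:
    """Per-site, per-type receptor interaction energies plus offsets.

    ``E[i, k]`` is the energy of an isolated type-k bead at site i;
    ``E0[k]`` the mean-field average-surface interaction; ``Nc`` the mean
    receptor contact count per site used to scale E0.
    """

    E: np.ndarray
    E0: np.ndarray
    Nc: float

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        E0 = np.asarray(self.E0, dtype=float)
        if not (np.all(np.isfinite(E)) and np.all(np.isfinite(E0))):
            raise ValueError("field energies must be finite")
        if E.ndim != 2 or E0.shape != (E.shape[1],):
            raise ValueError("inconsistent field shapes")
        object.__setattr__(self, "E", E)
        object.__setattr__(self, "E0", E0)

    @property
    def n_types(self) -> int:
        return self.E.shape[1]


def _derive_edges(sites: np.ndarray, spacing: float) -> tuple[tuple[int, int], ...]:
    edges = []
    n = len(sites)
    for i in range(n):
        d = np.linalg.norm(sites[i + 1:] - sites[i], axis=1)
        for off in np.flatnonzero(np.abs(d - spacing) < 1e-6):
            edges.append((i, i + 1 + int(off)))
    return tuple(edges)


def build_grid(
    receptor: Receptor,
    reference: np.ndarray,
    spacing: float = DEFAULT_SPACING,
    include_radius: float = DEFAULT_INCLUDE_RADIUS,
    exclude_radius: float = DEFAULT_EXCLUDE_RADIUS,
) -> PocketGrid:
    """Clip a cubic lattice to the pocket around a reference pose.

    Lattice axes are aligned with the input frame and the origin sits at
    the reference-region centroid. A lattice point is kept when it lies
    within ``include_radius`` of at least one reference point and farther
    than ``exclude_radius`` from every receptor bead.
    """
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if reference.size == 0:
        raise GridError("reference region is empty")
    if len(receptor) == 0:
        raise GridError("receptor is empty")

    # lattice origin: reference centroid snapped onto the spacing grid of
    # the input frame, so lattice-aligned references reproduce their sites
    origin = spacing * np.round(reference.mean(axis=0) / spacing)
    lo = reference.min(axis=0) - include_radius - spacing
    hi = reference.max(axis=0) + include_radius + spacing
    ranges = []
    for d in range(3):
        kmin = int(np.floor((lo[d] - origin[d]) / spacing))
        kmax = int(np.ceil((hi[d] - origin[d]) / spacing))
        ranges.append(np.arange(kmin, kmax + 1))
    gx, gy, gz = np.meshgrid(*ranges, indexing="ij")
    pts = origin + spacing * np.stack(
        [gx.ravel(), gy.ravel(), gz.ravel()], axis=1
    )

    rec = receptor.coords
    d_ref = np.linalg.norm(pts[:, None, :] - reference[None], axis=2).min(axis=1)
    d_rec = np.linalg.norm(pts[:, None, :] - rec[None], axis=2).min(axis=1)
    keep = (d_ref <= include_radius) & (d_rec > exclude_radius)
    sites = pts[keep]
    if len(sites) == 0:
        raise GridError(
            "no lattice sites survive the radius filters; widen include_radius "
            "or shrink exclude_radius"
        )
    edges = _derive_edges(sites, spacing)
    prov = {
        "receptor": receptor.id,
        "spacing": spacing,
        "include_radius": include_radius,
        "exclude_radius": exclude_radius,
        "n_reference": int(len(reference)),
    }
    return PocketGrid(sites, edges, spacing, provenance=prov)


def pick_anchors(
    grid: PocketGrid, endpoint_a: np.ndarray, endpoint_b: np.ndarray
) -> tuple[int, int]:
    """Nearest grid sites to the two chain end points (ties: lowest index)."""
    if grid.n_sites == 0:
        raise GridError("grid is empty")
    s = _nearest_site(grid.sites, endpoint_a)
    t = _nearest_site(grid.sites, endpoint_b)
    if s == t:
        raise GridError("both end points map to the same grid site")
    return s, t


def _nearest_site(sites: np.ndarray, point: np.ndarray) -> int:
    d = np.linalg.norm(sites - np.asarray(point, dtype=float), axis=1)
    return int(np.argmin(d))  # argmin returns the first (lowest) index on ties


def external_field(
    grid: PocketGrid,
    receptor: Receptor,
    model: InteractionModel,
    n_contacts: float | None = None,
) -> ExternalField:
    """Precompute E_i^(k), the mean contact count Nc and the offsets E0^(k).

    E_i^(k) sums the pair potential between a type-k bead at site i and
    every receptor bead within the cutoff. Nc defaults to the mean number
    of receptor beads within the cutoff per grid site.
    """
    params = model.params()
    nK = model.n_types
    E = np.zeros((grid.n_sites, nK))
    rec = receptor.coords
    contact_counts = np.zeros(grid.n_sites)
    if len(receptor) > 0:
        fam = [model.family_of(code) for code in receptor.codes]
        for i, x in enumerate(grid.sites):
            d = np.linalg.norm(rec - x, axis=1)
            within = d < params.cutoff
            contact_counts[i] = int(np.count_nonzero(within))
            for m in np.flatnonzero(within):
                for k in range(nK):
                    E[i, k] += pair_potential(k, fam[m], float(d[m]), params)
    if n_contacts is None:
        n_contacts = float(contact_counts.mean()) if grid.n_sites else 0.0
    E0 = np.array([mean_field_offset(k, n_contacts, model) for k in range(nK)])
    return ExternalField(E=E, E0=E0, Nc=float(n_contacts))
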
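"""Seeded toy receptors, pockets and binder sets for tests and demos.

The workhorse is a groove-shaped receptor: a dense "floor" of one residue
composition sits one interaction-minimum below the pocket, and two sparse
"rim" columns of another composition flank it, so grid sites near the
floor see more receptor contacts (and, with a hydrophobic floor, a lower
hydrophobic field) than sites near the rim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy_model import Receptor
from .pocket_lattice import DEFAULT_SPACING

__all__ = [
    "FixtureSpec",
    "GrooveFixture",
    "make_groove_receptor",
    "make_ladder_pocket",
    "make_reference_binders",
]

#: radial offset from pocket sites to receptor beads; close to the
#: Lennard-Jones minimum for typical residue diameters, so adjacent
#: sites sit in the attractive well rather than the repulsive core
BEAD_OFFSET = 6.46


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible description of a synthetic groove pocket."""

    seed: int = 0
    dims: tuple[int, int, int] = (3, 3, 6)  # floor columns, depth, length
    floor_residue: str = "L"
    rim_residue: str = "S"
    spacing: float = DEFAULT_SPACING
    jitter: float = 0.0  # Gaussian coordinate noise (Angstrom)


@dataclass(frozen=True)
class GrooveFixture:
    receptor: Receptor
    reference: np.ndarray  # (nz, 3) reference pose coordinates
    endpoints: tuple[np.ndarray, np.ndarray]
    core_indices: tuple[int, ...]  # receptor beads forming the floor
    rim_indices: tuple[int, ...]
    spec: FixtureSpec = field(repr=False, default=None)


def make_groove_receptor(spec: FixtureSpec) -> GrooveFixture:
    """Build the groove receptor and its reference pose.

    The reference pose is a straight line of ``nz`` points along z through
    the groove center. Floor beads lie ``BEAD_OFFSET`` below the lowest
    retained lattice row (2 spacings under the reference line with default
    radii); rim beads flank the widest row at the same offset.
    """
    nx, ny, nz = spec.dims
    if nx < 1 or ny < 1 or nz < 2:
        raise ValueError(f"infeasible groove dims {spec.dims}")
    a = spec.spacing
    ref = np.array([[0.0, 0.0, k * a] for k in range(nz)])

    rng = np.random.default_rng(spec.seed)
    codes: list[str] = []
    coords: list[np.ndarray] = []
    core_idx: list[int] = []
    rim_idx: list[int] = []

    floor_y = -2.0 * a - BEAD_OFFSET
    xs = (np.arange(nx) - (nx - 1) / 2.0) * a
    for x in xs:
        for k in range(nz):
            core_idx.append(len(codes))
            codes.append(spec.floor_residue)
            coords.append(np.array([x, floor_y, k * a]))

    rim_x = 2.0 * a + BEAD_OFFSET
    for sx in (-rim_x, rim_x):
        for k in range(nz):
            rim_idx.append(len(codes))
            codes.append(spec.rim_residue)
            coords.append(np.array([sx, 0.0, k * a]))

    xyz = np.array(coords)
    if spec.jitter > 0:
        xyz = xyz + rng.normal(0.0, spec.jitter, xyz.shape)
    receptor = Receptor(
        tuple(zip(codes, xyz)), id=f"groove-{nx}x{ny}x{nz}-seed{spec.seed}"
    )
    return GrooveFixture(
        receptor=receptor,
        reference=ref,
        endpoints=(ref[0], ref[-1]),
        core_indices=tuple(core_idx),
        rim_indices=tuple(rim_idx),
        spec=spec,
    )


def make_ladder_pocket(
    n_rungs: int = 4,
    floor_residue: str = "L",
    rim_residue: str = "S",
    spacing: float = DEFAULT_SPACING,
) -> tuple[Receptor, np.ndarray]:
    """A minimal vertical pocket for brute-force-sized design problems.

    Grid sites form a single column of ``n_rungs`` points along +y.
    Floor beads (dense, 3 per rung level) sit below the lowest site and
    rim beads (sparse, 1) beside the highest, so low sites accumulate
    more receptor contacts than high sites.
    """
    if n_rungs < 2:
        raise ValueError("need at least two rungs")
    a = spacing
    sites = np.array([[0.0, k * a, 0.0] for k in range(n_rungs)])
    codes, coords = [], []
    # dense hydrophobic floor under the column
    for dx in (-a, 0.0, a):
        coords.append(np.array([dx, -BEAD_OFFSET if dx == 0.0 else
                                -np.sqrt(BEAD_OFFSET ** 2 - a ** 2), 0.0]))
        codes.append(floor_residue)
    # single polar bead level with the top site
    coords.append(np.array([BEAD_OFFSET, (n_rungs - 1) * a, 0.0]))
    codes.append(rim_residue)
    receptor = Receptor(tuple(zip(codes, np.array(coords))), id="ladder")
    return receptor, sites


def make_reference_binders(
    profile: np.ndarray,
    n: int,
    seed: int | None = None,
    alphabet: tuple[str, ...] | None = None,
) -> list[str]:
    """Sample sequences i.i.d. per position from a probability profile.

    ``profile`` is (length, n_types); each row must be a probability
    vector over the alphabet.
    """
    profile = np.atleast_2d(np.asarray(profile, dtype=float))
    if alphabet is None:
        from .energy_model import CANONICAL_CODES
        alphabet = CANONICAL_CODES
    if profile.shape[1] != len(alphabet):
        raise ValueError("profile width does not match alphabet size")
    if np.any(profile < 0) or not np.allclose(profile.sum(axis=1), 1.0,
                                              atol=1e-9):
        raise ValueError("profile rows must be probability vectors")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        seq = [
            alphabet[rng.choice(len(alphabet), p=row)] for row in profile
        ]
        out.append("".join(seq))
    return out
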
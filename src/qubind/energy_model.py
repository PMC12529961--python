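"""Coarse-grained residue-level energy model.

One bead per residue. Pairwise interactions follow a knowledge-based
contact-energy table rescaled to Lennard-Jones parameters, with a hard
distance cutoff. A mean-field term estimates the average interaction a
residue type forms with a generic protein surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "CANONICAL_CODES",
    "THREE_TO_ONE",
    "ResidueAlphabet",
    "ContactEnergyTable",
    "PairPotentialParams",
    "Receptor",
    "InteractionModel",
    "load_alphabet",
    "load_contact_table",
    "load_full_model",
    "epsilon_from_mj",
    "sigma_pair",
    "pair_potential",
    "pair_potential_matrix",
    "mean_field_offset",
    "DEFAULT_CUTOFF",
    "DEFAULT_LAMBDA",
    "DEFAULT_E0",
]

DEFAULT_CUTOFF = 8.5  # Angstrom
DEFAULT_LAMBDA = 0.159
DEFAULT_E0 = -2.27  # kBT

CANONICAL_CODES = tuple("ARNDCQEGHILKMFPSTWYV")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class AlphabetError(KeyError):
    """Raised when a residue type is not part of the alphabet."""


@dataclass(frozen=True)
class ResidueAlphabet:
    """The residue type set with per-type size and surface-frequency data.

    Parameters
    ----------
    names : sequence of str
        One-letter residue codes, in canonical order.
    vdw_diameter : ndarray
        Per-type van der Waals diameter sigma_i in Angstrom.
    surface_freq : ndarray
        Per-type relative frequency on a typical protein surface;
        must sum to 1.
    """

    names: tuple[str, ...]
    vdw_diameter: np.ndarray
    surface_freq: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != 20:
            raise ValueError(f"alphabet must have 20 types, got {len(self.names)}")
        if len(set(self.names)) != 20:
            raise ValueError("duplicate residue codes in alphabet")
        sig = np.asarray(self.vdw_diameter, dtype=float)
        frq = np.asarray(self.surface_freq, dtype=float)
        if sig.shape != (20,) or frq.shape != (20,):
            raise ValueError("vdw_diameter and surface_freq must have shape (20,)")
        if not np.all(sig > 0):
            raise ValueError("all vdW diameters must be positive")
        if abs(frq.sum() - 1.0) > 1e-9:
            raise ValueError(f"surface frequencies sum to {frq.sum()}, expected 1")
        object.__setattr__(self, "vdw_diameter", sig)
        object.__setattr__(self, "surface_freq", frq)

    def index(self, code: str) -> int:
        code = _normalize_code(code)
        try:
            return self.names.index(code)
        except ValueError:
            raise AlphabetError(f"unknown residue type {code!r}") from None

    def __len__(self) -> int:
        return len(self.names)


def _normalize_code(code: str) -> str:
    code = code.strip().upper()
    if len(code) == 3:
        code = THREE_TO_ONE.get(code, code)
    return code


@dataclass(frozen=True)
class ContactEnergyTable:
    """Raw 20x20 contact energies e_ij (kBT) with the rescaling parameters."""

    e: np.ndarray
    lambda_scale: float = DEFAULT_LAMBDA
    e0: float = DEFAULT_E0

    def __post_init__(self) -> None:
        e = np.asarray(self.e, dtype=float)
        if e.shape != (20, 20):
            raise ValueError(f"contact table must be 20x20, got {e.shape}")
        if not np.allclose(e, e.T, atol=1e-12):
            raise ValueError("contact table must be symmetric")
        object.__setattr__(self, "e", e)


@dataclass(frozen=True)
class PairPotentialParams:
    """Lennard-Jones parameters: well depths, diameters and the cutoff."""

    epsilon: np.ndarray
    sigma: np.ndarray
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        eps = np.asarray(self.epsilon, dtype=float)
        sig = np.asarray(self.sigma, dtype=float)
        if eps.ndim != 2 or eps.shape[0] != eps.shape[1]:
            raise ValueError("epsilon must be square")
        if not np.allclose(eps, eps.T, atol=1e-12):
            raise ValueError("epsilon must be symmetric")
        if sig.shape != (eps.shape[0],):
            raise ValueError("sigma length must match epsilon dimension")
        object.__setattr__(self, "epsilon", eps)
        object.__setattr__(self, "sigma", sig)


@dataclass(frozen=True)
class Receptor:
    """Target protein as one bead per residue (Calpha position)."""

    residues: tuple[tuple[str, np.ndarray], ...]
    id: str = "receptor"

    def __post_init__(self) -> None:
        res = []
        for code, xyz in self.residues:
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise ValueError("receptor coordinates must be finite 3-vectors")
            res.append((_normalize_code(code), xyz))
        object.__setattr__(self, "residues", tuple(res))

    @property
    def coords(self) -> np.ndarray:
        if not self.residues:
            return np.zeros((0, 3))
        return np.array([xyz for _, xyz in self.residues])

    @property
    def codes(self) -> list[str]:
        return [code for code, _ in self.residues]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class InteractionModel:
    """A self-contained interaction parameter set over K types.

    Used both for the full 20-letter alphabet and for reduced (clustered)
    alphabets: ``labels`` name the types, ``epsilon``/``sigma`` parametrize
    the pair potential, ``freq`` is the per-type surface frequency and
    ``residue_family`` maps any 20-letter residue code onto a type index.
    """

    labels: tuple[str, ...]
    epsilon: np.ndarray
    sigma: np.ndarray
    freq: np.ndarray
    residue_family: dict = field(default_factory=dict)
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        eps = np.asarray(self.epsilon, dtype=float)
        sig = np.asarray(self.sigma, dtype=float)
        frq = np.asarray(self.freq, dtype=float)
        k = len(self.labels)
        if eps.shape != (k, k) or sig.shape != (k,) or frq.shape != (k,):
            raise ValueError("inconsistent model dimensions")
        object.__setattr__(self, "epsilon", eps)
        object.__setattr__(self, "sigma", sig)
        object.__setattr__(self, "freq", frq)

    @property
    def n_types(self) -> int:
        return len(self.labels)

    def family_of(self, code: str) -> int:
        code = _normalize_code(code)
        try:
            return self.residue_family[code]
        except KeyError:
            raise AlphabetError(f"no family assignment for residue {code!r}") from None

    def params(self) -> PairPotentialParams:
        return PairPotentialParams(self.epsilon, self.sigma, self.cutoff)


# ---------------------------------------------------------------------------
# packaged data

def _data_text(name: str) -> str:
    return resources.files("qubind.data").joinpath(name).read_text()


def load_alphabet() -> ResidueAlphabet:
    """Load the packaged residue alphabet (diameters + surface frequencies)."""
    names, sig, frq = [], [], []
    for line in _data_text("residue_params.txt").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, s, f = line.split()
        names.append(code)
        sig.append(float(s))
        frq.append(float(f))
    frq = np.asarray(frq)
    return ResidueAlphabet(tuple(names), np.asarray(sig), frq / frq.sum())


def load_contact_table(
    lambda_scale: float = DEFAULT_LAMBDA, e0: float = DEFAULT_E0
) -> ContactEnergyTable:
    """Load the packaged 20x20 contact-energy matrix."""
    lines = [
        ln for ln in _data_text("mj_contact_energies.txt").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    header = lines[0].split()
    if tuple(header) != CANONICAL_CODES:
        raise ValueError("packaged matrix header does not match canonical order")
    e = np.array([[float(x) for x in ln.split()[1:]] for ln in lines[1:]])
    return ContactEnergyTable(e, lambda_scale=lambda_scale, e0=e0)


def load_full_model(cutoff: float = DEFAULT_CUTOFF) -> InteractionModel:
    """Full 20-type interaction model from the packaged tables."""
    alphabet = load_alphabet()
    table = load_contact_table()
    eps = epsilon_from_mj(table)
    fam = {code: i for i, code in enumerate(alphabet.names)}
    return InteractionModel(
        labels=alphabet.names,
        epsilon=eps,
        sigma=alphabet.vdw_diameter,
        freq=alphabet.surface_freq,
        residue_family=fam,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# operations

def epsilon_from_mj(table: ContactEnergyTable) -> np.ndarray:
    """Rescale raw contact energies: eps_ij = lambda * (e_ij - e0)."""
    return table.lambda_scale * (table.e - table.e0)


def sigma_pair(i: int | str, j: int | str, alphabet: ResidueAlphabet) -> float:
    """Arithmetic-mean interaction diameter sigma_ij = (sigma_i + sigma_j)/2."""
    ii = alphabet.index(i) if isinstance(i, str) else int(i)
    jj = alphabet.index(j) if isinstance(j, str) else int(j)
    return 0.5 * (alphabet.vdw_diameter[ii] + alphabet.vdw_diameter[jj])


def _lj_core(eps: float, sigma: float, r: np.ndarray) -> np.ndarray:
    sr6 = (sigma / r) ** 6
    lj = sr6 * sr6 - sr6
    r0 = 2.0 ** (1.0 / 6.0) * sigma
    if eps < 0:
        # purely attractive type pair: plain LJ with depth |eps|
        return 4.0 * abs(eps) * lj
    # repulsive type pair: well flipped into a barrier capped at eps
    inner = 4.0 * eps * lj + 2.0 * eps
    outer = -4.0 * eps * lj
    return np.where(r < r0, inner, outer)


def pair_potential(
    i: int | str,
    j: int | str,
    r: float | np.ndarray,
    params: PairPotentialParams,
    alphabet: ResidueAlphabet | None = None,
    model: InteractionModel | None = None,
) -> float | np.ndarray:
    """Piecewise Lennard-Jones pair energy u_ij(r) in kBT.

    Attractive pairs (eps_ij < 0) follow a plain LJ form with minimum
    -|eps_ij| at r = 2^(1/6) sigma_ij; repulsive pairs (eps_ij > 0) are
    capped so the potential rises to a finite barrier instead of a well.
    Exactly zero at and beyond the cutoff.
    """
    if isinstance(i, str) or isinstance(j, str):
        if model is not None:
            src: Sequence[str] = model.labels
        elif alphabet is not None:
            src = alphabet.names
        else:
            raise ValueError("string types require an alphabet or model")
        def _idx(t):
            t = _normalize_code(t) if isinstance(t, str) else t
            if isinstance(t, str):
                try:
                    return list(src).index(t)
                except ValueError:
                    raise AlphabetError(f"unknown residue type {t!r}") from None
            return int(t)
        i, j = _idx(i), _idx(j)

    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("distance must be positive")
    eps = float(params.epsilon[i, j])
    sigma = 0.5 * (params.sigma[i] + params.sigma[j])
    val = np.where(r_arr >= params.cutoff, 0.0, _lj_core(eps, sigma, r_arr))
    if np.isscalar(r) or r_arr.ndim == 0:
        return float(val)
    return val


def pair_potential_matrix(
    r: float, params: PairPotentialParams
) -> np.ndarray:
    """All-pairs u_ij(r) at one distance; zero at/beyond cutoff."""
    if r <= 0:
        raise ValueError("distance must be positive")
    k = params.epsilon.shape[0]
    if r >= params.cutoff:
        return np.zeros((k, k))
    out = np.empty((k, k))
    for a in range(k):
        for b in range(a, k):
            sigma = 0.5 * (params.sigma[a] + params.sigma[b])
            out[a, b] = out[b, a] = float(
                _lj_core(float(params.epsilon[a, b]), sigma, np.asarray(r))
            )
    return out


def mean_field_offset(
    k: int | str,
    n_contacts: float,
    model: InteractionModel,
) -> float:
    """Average-surface interaction E0^(k) = Nc * sum_j f_j eps_kj."""
    if n_contacts < 0:
        raise ValueError("mean contact count must be non-negative")
    if isinstance(k, str):
        k = _normalize_code(k)
        try:
            k = list(model.labels).index(k)
        except ValueError:
            raise AlphabetError(f"unknown type {k!r}") from None
    return float(n_contacts * np.dot(model.freq, model.epsilon[k]))
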
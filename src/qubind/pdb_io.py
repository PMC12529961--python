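"""Structure and sequence file handling (PDB, FASTA)."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .energy_model import ONE_TO_THREE, THREE_TO_ONE, Receptor

__all__ = [
    "read_receptor",
    "write_calpha_pdb",
    "read_fasta",
    "write_fasta",
]


def read_receptor(path: str | Path, id: str | None = None) -> Receptor:
    """Read a receptor as Calpha beads from a PDB file.

    First model only; ATOM records; altloc other than blank or 'A' ignored;
    residues without a recognized three-letter code are skipped.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    model = next(structure.get_models())
    residues = []
    for chain in model:
        for res in chain:
            hetflag = res.id[0]
            if hetflag != " ":
                continue
            resname = res.get_resname().strip()
            if resname not in THREE_TO_ONE:
                continue
            if "CA" not in res:
                continue
            atom = res["CA"]
            if atom.is_disordered():
                try:
                    atom = atom.disordered_get("A")
                except KeyError:
                    continue
            altloc = atom.get_altloc()
            if altloc not in (" ", "", "A"):
                continue
            residues.append((THREE_TO_ONE[resname], np.asarray(atom.coord, float)))
    return Receptor(tuple(residues), id=id or path.stem)


def write_calpha_pdb(
    codes: list[str], coords: np.ndarray, path: str | Path, chain: str = "A"
) -> None:
    """Write one-bead-per-residue coordinates as CA ATOM records."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if len(codes) != len(coords):
        raise ValueError("codes and coordinates differ in length")
    lines = []
    for n, (code, xyz) in enumerate(zip(codes, coords), start=1):
        resname = ONE_TO_THREE.get(code.upper(), code.upper())
        lines.append(
            f"ATOM  {n:5d}  CA  {resname:>3s} {chain}{n:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader: {header: sequence}, order preserved."""
    out: dict[str, str] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name is not None:
            out[name] += line
    return out


def write_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    lines = []
    for name, seq in records.items():
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i:i + width])
    Path(path).write_text("\n".join(lines) + "\n")
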
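"""Assessment statistics for designed binders.

Structure side: native-contact fractions over a ranked pose list, CAPRI-style
binary labels (f_nat > 0.5) and the area under the precision-recall curve.
Sequence side: per-position family-frequency histograms of designed vs
reference sequence sets under a reduced alphabet, and the top-2 agreement
count between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy_model import Receptor
from .reduced_alphabet import ClusterMap

__all__ = [
    "ContactSet",
    "RankedPoses",
    "PositionHistograms",
    "native_contacts",
    "f_nat",
    "label_poses",
    "auprc",
    "family_histograms",
    "top2_overlap",
]


@dataclass(frozen=True)
class ContactSet:
    """Unique (peptide position, receptor residue index) contact pairs."""

    pairs: frozenset
    cutoff: float = 8.5
    rule: str = "calpha"

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class RankedPoses:
    """Poses in external rank order (best first), each with its contacts."""

    contact_sets: tuple[ContactSet, ...]
    scores: tuple[float, ...] = ()

    def __len__(self) -> int:
        return len(self.contact_sets)


@dataclass(frozen=True)
class PositionHistograms:
    """Per-position family-frequency vectors for designed vs reference sets."""

    designed: np.ndarray  # (L, D)
    reference: np.ndarray  # (L, D)

    def __post_init__(self) -> None:
        d = np.asarray(self.designed, dtype=float)
        r = np.asarray(self.reference, dtype=float)
        if d.shape != r.shape:
            raise ValueError("histogram shapes differ")
        for h in (d, r):
            if not np.allclose(h.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("each per-position histogram must sum to 1")
        object.__setattr__(self, "designed", d)
        object.__setattr__(self, "reference", r)

    @property
    def length(self) -> int:
        return self.designed.shape[0]


def native_contacts(
    peptide_coords: np.ndarray, receptor: Receptor, cutoff: float = 8.5
) -> ContactSet:
    """Calpha-Calpha contacts between a peptide pose and the receptor."""
    pep = np.atleast_2d(np.asarray(peptide_coords, dtype=float))
    rec = receptor.coords
    pairs = set()
    for n, x in enumerate(pep):
        d = np.linalg.norm(rec - x, axis=1)
        for m in np.flatnonzero(d <= cutoff):
            pairs.add((n, int(m)))
    return ContactSet(frozenset(pairs), cutoff=cutoff)


def f_nat(pose: ContactSet, native: ContactSet) -> float:
    """Fraction of native contacts reproduced by a pose."""
    if len(native) == 0:
        raise ValueError("native contact set is empty; f_nat undefined")
    return len(pose.pairs & native.pairs) / len(native.pairs)


def label_poses(
    poses: RankedPoses, native: ContactSet, threshold: float = 0.5
) -> np.ndarray:
    """CAPRI-style binary labels: positive iff f_nat strictly above threshold."""
    return np.array(
        [f_nat(cs, native) > threshold for cs in poses.contact_sets],
        dtype=bool,
    )


def auprc(labels: np.ndarray) -> float:
    """Area under the precision-recall curve of a ranked binary label list.

    Average-precision step rule: the mean, over positives, of the precision
    at that positive's rank. Deterministic and interpolation-free.
    """
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError(
            "no positive labels; AUPRC undefined (check the f_nat threshold)"
        )
    tp = 0
    total = 0.0
    for rank, lab in enumerate(labels, start=1):
        if lab:
            tp += 1
            total += tp / rank
    return total / n_pos


def _sequence_histograms(
    sequences: list[str], cmap: ClusterMap
) -> np.ndarray:
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
    (L,) = lengths
    h = np.zeros((L, cmap.D))
    for seq in sequences:
        for pos, code in enumerate(seq):
            h[pos, cmap.family_of(code)] += 1.0
    return h / len(sequences)


def family_histograms(
    designed: list[str], reference: list[str], cmap: ClusterMap
) -> PositionHistograms:
    """Per-position family frequencies of the two sequence sets."""
    if not designed or not reference:
        raise ValueError("both sequence sets must be nonempty")
    hd = _sequence_histograms(designed, cmap)
    hr = _sequence_histograms(reference, cmap)
    if hd.shape != hr.shape:
        raise ValueError(
            f"length mismatch: designed {hd.shape[0]} vs reference {hr.shape[0]}"
        )
    return PositionHistograms(hd, hr)


def _top_families(freqs: np.ndarray, k: int) -> list[int]:
    # stable sort by (-frequency, family index): ties favor lower index
    order = sorted(range(len(freqs)), key=lambda i: (-freqs[i], i))
    return order[:k]


def top2_overlap(h: PositionHistograms) -> int:
    """Positions where the reference's modal family is in the designed top 2."""
    count = 0
    for pos in range(h.length):
        ref_mode = _top_families(h.reference[pos], 1)[0]
        if ref_mode in _top_families(h.designed[pos], 2):
            count += 1
    return count
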
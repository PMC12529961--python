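"""Shared fixtures: packaged tables, reduced alphabets, toy grids/models."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from qubind.energy_model import (
    InteractionModel,
    load_alphabet,
    load_contact_table,
    load_full_model,
)
from qubind.pocket_lattice import ExternalField, PocketGrid
from qubind.reduced_alphabet import build_clustered_model, fit_cluster_map

SPACING = 3.8


@pytest.fixture(scope="session")
def alphabet():
    return load_alphabet()


@pytest.fixture(scope="session")
def contact_table():
    return load_contact_table()


@pytest.fixture(scope="session")
def full_model():
    return load_full_model()


@pytest.fixture(scope="session")
def cmap2(alphabet, contact_table):
    """Reduced D=2 alphabet fitted at a small seeded search budget."""
    cmap, _ = fit_cluster_map(
        contact_table.e, 2, labels=alphabet.names, seed=1, n_restarts=5,
        n_sweeps=150,
    )
    return cmap


@pytest.fixture(scope="session")
def model2(alphabet, contact_table, cmap2):
    _, model = build_clustered_model(
        contact_table.e, alphabet, cmap2,
        contact_table.lambda_scale, contact_table.e0,
    )
    return model


@pytest.fixture(scope="session")
def cmap5(alphabet, contact_table):
    cmap, _ = fit_cluster_map(
        contact_table.e, 5, labels=alphabet.names, seed=1, n_restarts=5,
        n_sweeps=150,
    )
    return cmap


def toy_model(D=1, eps=-1.0, sigma=3.0, freq=None, cutoff=8.5):
    """Uniform D-type interaction model with mild couplings.

    sigma = 3.0 keeps the bond distance (3.8 A) inside the attractive
    well so penalty weights stay small on toy instances.
    """
    e = np.full((D, D), float(eps)) if np.isscalar(eps) else np.asarray(eps)
    if freq is None:
        freq = np.full(D, 1.0 / D)
    return InteractionModel(
        labels=tuple(f"F{i}" for i in range(D)),
        epsilon=e,
        sigma=np.full(D, float(sigma)) if np.isscalar(sigma) else np.asarray(sigma),
        freq=np.asarray(freq),
        residue_family={},
        cutoff=cutoff,
    )


def line_grid(n, anchors=True):
    sites = np.array([[0.0, 0.0, k * SPACING] for k in range(n)])
    g = PocketGrid.from_points(sites)
    return g.with_anchors(0, n - 1) if anchors else g


def box_grid(nx, ny, nz=1, s=None, t=None):
    sites = np.array(
        [
            [i * SPACING, j * SPACING, k * SPACING]
            for i, j, k in itertools.product(range(nx), range(ny), range(nz))
        ]
    )
    g = PocketGrid.from_points(sites)
    if s is not None:
        g = g.with_anchors(s, t)
    return g


def zero_field(grid, D):
    return ExternalField(E=np.zeros((grid.n_sites, D)), E0=np.zeros(D), Nc=0.0)


def all_bitstrings(n):
    codes = np.arange(1 << n, dtype=np.uint64)
    return ((codes[:, None] >> np.arange(n, dtype=np.uint64)) & 1).astype(
        np.uint8
    )


def enumerate_valid_configs(grid, registry):
    """Oracle: every self-avoiding s-t chain bitstring with consistent
    ancillas, by exhaustive simple-path + sequence enumeration."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(range(grid.n_sites))
    G.add_edges_from(grid.edges)
    D = registry.n_families
    out = []
    for path in nx.all_simple_paths(G, grid.s_index, grid.t_index):
        for seq in itertools.product(range(D), repeat=len(path)):
            bits = np.zeros(registry.n_variables, dtype=np.uint8)
            for site, k in zip(path, seq):
                bits[registry.site_var(site, k)] = 1
            for a, b in zip(path, path[1:]):
                bits[registry.bond_var(a, b)] = 1
                lo = min(a, b)
                k_lo = seq[path.index(lo)]
                bits[registry.anc_var(a, b, k_lo)] = 1
            out.append((tuple(path), tuple(seq), bits))
    return out
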
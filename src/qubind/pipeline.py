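"""End-to-end design driver: grid -> field -> QUBO -> solve -> decode -> refine.

Stage 1 jointly optimizes the pose and a reduced-alphabet sequence;
stage 2 freezes the geometry and re-optimizes the sequence over all 20
residues. Both stages run on the same receptor/grid objects the lower
modules expose, so everything here is plain orchestration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import decode_refine, pocket_lattice, qubo_model, solvers
from .config import RunConfig
from .decode_refine import ChainDecode
from .energy_model import (
    InteractionModel,
    Receptor,
    epsilon_from_mj,
    load_alphabet,
    load_contact_table,
    load_full_model,
)
from .pocket_lattice import PocketGrid
from .reduced_alphabet import ClusterMap, build_clustered_model, fit_cluster_map

logger = logging.getLogger("qubind")

__all__ = ["DesignResult", "clustered_model_from_config", "run_design"]


@dataclass
class DesignResult:
    chain: ChainDecode
    family_sequence: str
    refined_sequence: str
    grid: PocketGrid
    stage1_energy: float
    stage2_energy: float
    energy_breakdown: dict
    spectrum: solvers.Spectrum
    config: RunConfig


def clustered_model_from_config(
    config: RunConfig, cmap: ClusterMap | None = None
) -> tuple[InteractionModel, ClusterMap]:
    """Fit (or reuse) the reduced alphabet and build its interaction model."""
    alphabet = load_alphabet()
    table = load_contact_table(config.lambda_scale, config.e0)
    if config.D > 10 or config.D < 5:
        logger.warning(
            "D=%d is outside the recommended 5..10 family range", config.D
        )
    if cmap is None:
        cmap, loss = fit_cluster_map(
            table.e, config.D, labels=alphabet.names, seed=config.seed,
            n_restarts=config.cluster_restarts,
        )
        logger.info("clustered alphabet: D=%d loss=%.4f", config.D, loss)
    _, model = build_clustered_model(
        table.e, alphabet, cmap, config.lambda_scale, config.e0,
        cutoff=config.cutoff,
    )
    return model, cmap


def _solve(model_qubo, config: RunConfig, stage: str) -> solvers.Spectrum:
    if config.solver not in ("sa", "brute", "auto"):
        raise ValueError(f"unknown solver {config.solver!r}")
    if config.solver in ("brute", "auto"):
        if model_qubo.n_variables <= solvers.BRUTE_FORCE_BOUND:
            states, energy = solvers.brute_force(model_qubo)
            results = [
                solvers.SolveResult(b, energy, solver="brute") for b in states
            ]
            return solvers.Spectrum(results)
        if config.solver == "brute":
            logger.info(
                "%s stage: %d variables exceed the enumeration bound; "
                "falling back to simulated annealing",
                stage, model_qubo.n_variables,
            )
    runs = config.n_runs if stage == "design" else config.refine_runs
    sweeps = config.n_sweeps if stage == "design" else config.refine_sweeps
    return solvers.simulated_annealing(
        model_qubo, n_runs=runs, n_sweeps=sweeps, seed=config.seed
    )


def run_design(
    config: RunConfig,
    receptor: Receptor,
    reference: np.ndarray,
    endpoints: tuple[np.ndarray, np.ndarray],
    cmap: ClusterMap | None = None,
) -> DesignResult:
    """Run both design stages and return the best decoded design.

    Raises RuntimeError naming the failing stage if any step cannot
    produce a usable result.
    """
    model, cmap = clustered_model_from_config(config, cmap)

    grid = pocket_lattice.build_grid(
        receptor, reference,
        spacing=config.spacing,
        include_radius=config.include_radius,
        exclude_radius=config.exclude_radius,
    )
    s, t = pocket_lattice.pick_anchors(grid, endpoints[0], endpoints[1])
    grid = grid.with_anchors(s, t)
    logger.info("grid: %d sites, %d edges, anchors %d->%d",
                grid.n_sites, grid.n_edges, s, t)

    fld = pocket_lattice.external_field(
        grid, receptor, model, n_contacts=config.n_contacts
    )
    params = qubo_model.QuboParams(
        A=config.A, L0=config.L0, w=config.w, p=config.p,
        ablate_E0=config.ablate_E0,
    )
    H = qubo_model.assemble(grid, fld, model, params)
    logger.info("stage-1 QUBO: %d variables", H.n_variables)

    spectrum = _solve(H, config, "design")
    registry = H.registry
    best: tuple[float, ChainDecode] | None = None
    for res in sorted(spectrum.results, key=lambda r: r.energy):
        chain = decode_refine.decode(res.bits, registry, grid)
        if chain.valid_path:
            best = (res.energy, chain)
            break
    if best is None:
        raise RuntimeError(
            "design stage: no run produced a valid chain; increase n_runs "
            "or n_sweeps, or loosen the chain-length tolerance"
        )
    stage1_energy, chain = best
    breakdown = {
        name: part.energy(
            sorted(spectrum.results, key=lambda r: r.energy)[0].bits
        )
        for name, part in H.components.items()
    }
    family_seq = "".join(model.labels[k] for k in chain.sequence)

    # stage 2: frozen geometry, full alphabet
    full = load_full_model(cutoff=config.cutoff)
    problem = decode_refine.build_refinement(
        chain, grid, receptor, full, A=config.A,
        n_contacts=config.n_contacts if config.n_contacts is not None
        else fld.Nc,
        ablate_E0=config.ablate_E0,
    )
    spec2 = _solve(problem.qubo, config, "refine")
    best2 = min(spec2.results, key=lambda r: r.energy)
    try:
        refined = decode_refine.decode_refinement(
            best2.bits, problem, full.labels
        )
    except ValueError as exc:
        raise RuntimeError(f"refine stage: {exc}") from exc

    return DesignResult(
        chain=chain,
        family_sequence=family_seq,
        refined_sequence=refined,
        grid=grid,
        stage1_energy=stage1_energy,
        stage2_energy=best2.energy,
        energy_breakdown=breakdown,
        spectrum=spectrum,
        config=config,
    )
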
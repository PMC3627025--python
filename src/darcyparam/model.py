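"""Model/Results facade over the discrete-to-continuum pipeline.

:class:`PerfusionModel` is constructed from a vascular network (or
generated from a seed) and captures the study conditions: partition,
boundary pressures, RVE radius and mesh.  :meth:`PerfusionModel.fit` runs
the full pipeline for one permeability parameterisation method — discrete
Poiseuille solve, RVE averaging, beta and K fields, permeability-scale
optimisation, Darcy solve — and returns a :class:`PerfusionResults` holding
the fitted scale, error metrics, diagnostics and fields, with a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from . import evaluation, fem, synthetic
from .evaluation import (
    ParameterisedCase,
    SweepConfig,
    darcy_rms_for_method,
    parameterise_case,
    poiseuille_vs_averaged_rms,
)
from .fem import GridMesh
from .network import (
    PartitionVector,
    VascularNetwork,
    compute_zeta,
    default_partition_targets,
    optimise_partition,
    partition_by_zeta,
)
from .poiseuille import DEFAULT_VISCOSITY, solve_network_flow
from .rve import RVESpec

__all__ = ["PerfusionModel", "PerfusionResults"]


@dataclass
class PerfusionResults:
    """Fitted scale and diagnostics for one parameterisation method."""

    method: str
    k_scale: float
    rms: float
    rms_poiseuille_vs_averaged: float
    psi_darcy: float
    psi_averaged: float
    n_compartment_vessels: Dict[int, int]
    partition: PartitionVector
    pressure: np.ndarray  # Darcy pressure on the grid, Pa
    p_bar: Dict[int, np.ndarray]
    beta13_max: float
    mesh: GridMesh
    rve_radius: float

    def summary(self) -> str:
        lines = [
            "Perfusion parameterisation results",
            "=" * 50,
            f"{'permeability method':32s} {self.method}",
            f"{'RVE radius (mm)':32s} {self.rve_radius:.4f}",
            f"{'mesh':32s} {self.mesh.n}^3 elements",
            f"{'partition Z':32s} "
            + "[" + ", ".join(f"{z:.6g}" for z in self.partition.Z) + "]",
            f"{'vessels per compartment':32s} "
            + ", ".join(f"{c}: {n}" for c, n in sorted(self.n_compartment_vessels.items())),
            "-" * 50,
            f"{'optimal K scale':32s} {self.k_scale:.6g}",
            f"{'rms(averaged, Darcy)':32s} {self.rms:.6g}",
            f"{'rms(Poiseuille, averaged)':32s} {self.rms_poiseuille_vs_averaged:.6g}",
            f"{'unsmoothness Psi (Darcy)':32s} {self.psi_darcy:.6g}",
            f"{'unsmoothness Psi (averaged)':32s} {self.psi_averaged:.6g}",
            f"{'max |beta_13|':32s} {self.beta13_max:.6g}",
            "=" * 50,
        ]
        return "\n".join(lines)


class PerfusionModel:
    """Multi-compartment Darcy perfusion model built from a vascular network.

    Parameters
    ----------
    network
        Vascular tree with fluxes and radii assigned.  Use
        :meth:`from_seed` to generate the default volume-filling test tree.
    rve_radius
        Averaging-sphere radius in mm (default 0.2667, about 13% of the
        domain length).
    mesh_n
        Elements per axis of the hexahedral mesh (default 16).
    partition_targets / Z
        Either target compartment mean radii (mm) for the rms partition
        optimiser, or an explicit partition vector.
    root_pressure, terminal_pressure
        Discrete Dirichlet boundary pressures in Pa (defaults 13.3/8 kPa).
    """

    def __init__(
        self,
        network: VascularNetwork,
        rve_radius: float = 0.2667,
        mesh_n: int = 16,
        mu: float = DEFAULT_VISCOSITY,
        partition_targets: Optional[Sequence[float]] = None,
        Z: Optional[PartitionVector] = None,
        root_pressure: float = 13300.0,
        terminal_pressure: float = 8000.0,
        domain: Optional[np.ndarray] = None,
        sample_seed: int = 1234,
    ) -> None:
        self.network = network
        self.rve_radius = rve_radius
        self.mesh_n = mesh_n
        self.mu = mu
        self.partition_targets = (
            tuple(partition_targets) if partition_targets is not None else None
        )
        self.Z = Z
        self.root_pressure = root_pressure
        self.terminal_pressure = terminal_pressure
        self.domain = (
            np.asarray(domain, dtype=float)
            if domain is not None
            else np.array([[-1.0, 1.0]] * 3)
        )
        self.sample_seed = sample_seed
        self._case: Optional[ParameterisedCase] = None

    @classmethod
    def from_seed(cls, seed: int = 0, levels: int = 10, **kwargs) -> "PerfusionModel":
        """Build the model on a generated volume-filling tree."""
        cfg = synthetic.GeneratorConfig(levels=levels, seed=seed)
        return cls(synthetic.generate_volume_filling_tree(cfg), **kwargs)

    # -- pipeline -------------------------------------------------------------

    def _prepare(self) -> ParameterisedCase:
        if self._case is not None:
            return self._case
        net = self.network
        if any(v.compartment is None for v in net.vessels.values()):
            hier = compute_zeta(net)
            targets = self.partition_targets or default_partition_targets(net)
            Z = self.Z or optimise_partition(net, hier, targets)
            partition_by_zeta(net, hier, Z)
            self.Z = Z
        elif self.Z is None:
            n = max(v.compartment for v in net.vessels.values())
            self.Z = PartitionVector(np.linspace(1.0, 0.0, n + 1))  # nominal
        dirichlet = {net.root_id: self.root_pressure}
        for t in net.terminal_node_ids():
            dirichlet[t] = self.terminal_pressure
        flow = solve_network_flow(net, dirichlet, mu=self.mu)
        mesh = GridMesh(self.domain, self.mesh_n)
        rve = RVESpec(self.rve_radius, self.domain)
        self._case = parameterise_case(net, flow, mesh, rve)
        return self._case

    def fit(self, method: str = "hvc") -> PerfusionResults:
        """Run the pipeline for one permeability method."""
        case = self._prepare()
        out = darcy_rms_for_method(case, method, mu=self.mu)
        ptilde = poiseuille_vs_averaged_rms(case, seed=self.sample_seed)
        counts: Dict[int, int] = {}
        for v in self.network.vessels.values():
            counts[v.compartment] = counts.get(v.compartment, 0) + 1
        beta13 = case.beta.get((3, 1))
        return PerfusionResults(
            method=method,
            k_scale=out["scale"],
            rms=out["rms"],
            rms_poiseuille_vs_averaged=ptilde,
            psi_darcy=out["psi_darcy"],
            psi_averaged=out["psi_pbar"],
            n_compartment_vessels=counts,
            partition=self.Z,
            pressure=out["pressure"],
            p_bar=case.p_bar,
            beta13_max=float(np.max(np.abs(beta13))) if beta13 is not None else 0.0,
            mesh=case.mesh,
            rve_radius=self.rve_radius,
        )

    def fit_all(self) -> Dict[str, PerfusionResults]:
        """Fit every permeability method on the shared parameterisation."""
        return {m: self.fit(m) for m in ("iso", "hvc", "pca")}
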
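"""Electrostatic forward problem and lead-field assembly.

The quasi-static potential satisfies div(sigma grad V) = 0 inside the
head; each electrode pair is solved with Dirichlet conditions (1 V on the
distal face of the fixed active electrode, 0 V on the distal face of the
return electrode), the delivered current is computed from the stiffness
reaction forces at the constrained nodes, and the solution is rescaled so
that exactly 1 mA flows in.  E = -grad V is piecewise constant on linear
tetrahedra; J = sigma E.  The lead field stacks, column by return
electrode, the outward normal component of E on the cortical surface per
1 mA, so the field of any montage follows by superposition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import SolverError, ValidationError
from .headmodel import CorticalSurface, TetrahedralMesh, TissueTable

MM = 1e-3  # mesh coordinates are mm; assembly is SI

#: node-count threshold above which the pair solver switches from a
#: sparse direct factorisation to preconditioned conjugate gradients
DIRECT_SOLVER_MAX_NODES = 200_000
CG_RTOL = 1e-8


@dataclass
class FEMSystem:
    """Assembled P1 stiffness matrix with element gradient operators."""

    mesh: TetrahedralMesh
    tissue: TissueTable
    K: sp.csr_matrix  # (n, n), S (units: S*m since coords converted to m)
    grads: np.ndarray  # (m, 4, 3) gradients of the 4 barycentric fns, 1/m
    volumes: np.ndarray  # (m,) m^3
    sigma: np.ndarray  # (m,) S/m per tet


def element_stiffness(coords: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """4x4 P1 stiffness matrix of a single tetrahedron (coords in metres)."""
    G, vol = _gradients(coords[None, :, :])
    return sigma * vol[0] * G[0] @ G[0].T


def _gradients(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric-basis gradients and volumes for (m, 4, 3) coordinates."""
    m = p.shape[0]
    M = p[:, 1:] - p[:, :1]  # (m, 3, 3) edge matrix
    vol = np.linalg.det(M) / 6.0
    if np.any(vol <= 0):
        bad = int(np.argmin(vol))
        raise SolverError(f"singular or inverted element geometry at tet {bad}")
    Minv = np.linalg.inv(M)  # rows: grad of lambda_1..3 are columns of Minv?
    # lambda_i (i=1..3) satisfy grad lambda_i = (M^{-1})^T e_i
    g123 = np.transpose(Minv, (0, 2, 1))  # (m, 3, 3); row i = grad lambda_{i+1}
    g0 = -g123.sum(axis=1, keepdims=True)
    G = np.concatenate([g0, g123], axis=1)  # (m, 4, 3)
    return G, vol


def assemble_system(mesh: TetrahedralMesh, tissue: TissueTable) -> FEMSystem:
    """Assemble the global sparse symmetric stiffness matrix.

    Raises if any mesh label lacks a conductivity or an element is
    degenerate.  The matrix is positive semidefinite with the constant
    vector in its null space (rows sum to zero) before boundary
    conditions are applied.
    """
    for lid in np.unique(mesh.tet_label):
        name = mesh.label_names[int(lid)]
        if name not in tissue:
            raise ValidationError(f"no conductivity for tissue {name!r}")
    sigma = np.array(
        [tissue[mesh.label_names[int(l)]] for l in mesh.tet_label], dtype=float
    )
    p = mesh.nodes[mesh.tets] * MM
    G, vol = _gradients(p)
    # element matrices sigma * vol * G G^T, scattered into COO triplets
    Ke = (sigma * vol)[:, None, None] * np.einsum("mik,mjk->mij", G, G)
    rows = np.repeat(mesh.tets, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.tets, (1, 4)).reshape(-1)
    K = sp.coo_matrix(
        (Ke.reshape(-1), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    return FEMSystem(mesh, tissue, K, G, vol, sigma)


@dataclass
class PairSolution:
    """Solution of one active->return pair, normalised to 1 mA."""

    active: str
    return_: str
    V: np.ndarray  # (n,) volts
    E: np.ndarray  # (m, 3) V/m per tet
    J: np.ndarray  # (m, 3) A/m^2 per tet
    current_ma: float  # delivered current after normalisation
    solver: str = "direct"

    def scaled(self, c: float) -> "PairSolution":
        return PairSolution(
            self.active, self.return_, c * self.V, c * self.E, c * self.J,
            c * self.current_ma, self.solver,
        )


def _dirichlet_solve(
    K: sp.csr_matrix, fixed: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, str]:
    n = K.shape[0]
    free = np.setdiff1d(np.arange(n), fixed)
    Kff = K[free][:, free].tocsc()
    rhs = -K[free][:, fixed] @ values
    if n <= DIRECT_SOLVER_MAX_NODES:
        try:
            lu = spla.splu(Kff)
            xf = lu.solve(rhs)
            solver = "direct (sparse LU)"
        except RuntimeError as exc:  # pragma: no cover - singular geometry
            raise SolverError(f"direct factorisation failed: {exc}") from exc
    else:  # pragma: no cover - large external meshes only
        M = spla.LinearOperator(
            Kff.shape, lambda v: v / Kff.diagonal()
        )
        xf, info = spla.cg(Kff, rhs, rtol=CG_RTOL, M=M, maxiter=20000)
        if info != 0:
            res = np.linalg.norm(Kff @ xf - rhs) / np.linalg.norm(rhs)
            raise SolverError(f"CG did not converge (relative residual {res:.2e})")
        solver = f"pcg (rtol {CG_RTOL})"
    V = np.empty(n)
    V[free] = xf
    V[fixed] = values
    return V, solver


def solve_pair(
    system: FEMSystem, active: str, return_electrode: str
) -> PairSolution:
    """Solve one electrode pair and normalise the delivered current to 1 mA.

    The delivered current is the sum of stiffness reaction forces over
    the active electrode's constrained nodes; `distal_flux` provides an
    independent surface-integration cross-check.
    """
    mesh = system.mesh
    if active == return_electrode:
        raise ValidationError("active and return electrodes must differ")
    for name in (active, return_electrode):
        if name not in mesh.electrode_nodes:
            raise ValidationError(f"electrode {name!r} not present in mesh")
    na = mesh.electrode_nodes[active]
    nr = mesh.electrode_nodes[return_electrode]
    fixed = np.concatenate([na, nr])
    vals = np.concatenate([np.ones(len(na)), np.zeros(len(nr))])
    V, solver = _dirichlet_solve(system.K, fixed, vals)

    r = system.K @ V  # reaction forces; ~0 at free nodes
    i_active = float(r[na].sum())  # A flowing in through the active face
    if abs(i_active) < 1e-15:
        raise SolverError("zero delivered current")
    scale = 1e-3 / i_active  # normalise to 1 mA
    V = V * scale
    # E = -grad V per tet, V/m
    Vt = V[mesh.tets]  # (m, 4)
    E = -np.einsum("mi,mik->mk", Vt, system.grads)
    J = system.sigma[:, None] * E
    return PairSolution(
        active, return_electrode, V, E, J, current_ma=i_active * scale * 1e3,
        solver=solver,
    )


def delivered_currents(system: FEMSystem, sol: PairSolution) -> dict[str, float]:
    """Reaction-force current (mA) through each of the pair's electrodes;
    their sum expresses charge conservation."""
    r = system.K @ sol.V
    return {
        name: float(r[system.mesh.electrode_nodes[name]].sum()) * 1e3
        for name in (sol.active, sol.return_)
    }


def distal_flux(system: FEMSystem, sol: PairSolution, electrode: str) -> float:
    """Cross-check: current (mA) through an electrode's distal face by
    surface integration of J . n over the boundary faces spanned by the
    distal node set."""
    mesh = system.mesh
    nodes = set(int(i) for i in mesh.electrode_nodes[electrode])
    faces = mesh.tets[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]]
    flat = faces.reshape(-1, 3)
    on = np.isin(flat, list(nodes)).all(axis=1)
    if not np.any(on):
        raise ValidationError(f"no distal faces found for {electrode!r}")
    tet_idx = np.repeat(np.arange(mesh.n_tets), 4)[on]
    tris = flat[on]
    p = mesh.nodes[tris] * MM
    raw = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # 2*area*n
    # orient outward (away from owning tet centroid)
    tc = mesh.nodes[mesh.tets[tet_idx]].mean(axis=1) * MM
    fc = p.mean(axis=1)
    sgn = np.sign(np.einsum("ij,ij->i", raw, fc - tc))
    flux = 0.5 * np.einsum("ij,ij->i", sol.J[tet_idx], raw * sgn[:, None])
    # inward current = -outward flux
    return float(-flux.sum()) * 1e3


def cortical_normal_field(
    sol: PairSolution, surface: CorticalSurface, mesh: TetrahedralMesh | None = None
) -> np.ndarray:
    """Signed outward-normal component of E (V/m per mA) on each cortical
    element."""
    if mesh is not None and surface.mesh_hash and surface.mesh_hash != mesh.content_hash():
        raise ValidationError("cortical surface does not belong to this mesh")
    if surface.owner_tet.max(initial=-1) >= sol.E.shape[0]:
        raise ValidationError("surface/mesh mismatch: owner tet out of range")
    return np.einsum("ij,ij->i", sol.E[surface.owner_tet], surface.normals)


@dataclass
class LeadField:
    """Real matrix: normal-component E (V/m) per cortical element and per
    1 mA active->return pair."""

    matrix: np.ndarray  # (n_elements, n_returns)
    active: str
    returns: list[str]
    element_areas: np.ndarray  # (n_elements,) mm^2
    mesh_hash: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("lead field contains non-finite entries")
        if self.matrix.shape[1] != len(self.returns):
            raise ValidationError("column count must equal number of returns")

    @property
    def n_elements(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_returns(self) -> int:
        return self.matrix.shape[1]

    def synthesize(self, return_currents_ma: np.ndarray) -> np.ndarray:
        """Field of an arbitrary (possibly complex) return-current vector
        in mA, by superposition."""
        x = np.asarray(return_currents_ma)
        if x.shape != (self.n_returns,):
            raise ValidationError("current vector length must match returns")
        return self.matrix @ x

    def save(self, path) -> None:
        path = Path(path)
        np.savez_compressed(
            path, matrix=self.matrix, element_areas=self.element_areas
        )
        sidecar = {
            "active": self.active,
            "returns": self.returns,
            "units": "V/m per mA",
            "mesh_hash": self.mesh_hash,
            "metadata": self.metadata,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "LeadField":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path)
        side = json.loads(path.with_suffix(".json").read_text())
        return cls(
            arrays["matrix"],
            side["active"],
            list(side["returns"]),
            arrays["element_areas"],
            side.get("mesh_hash", ""),
            side.get("metadata", {}),
        )


def build_leadfield(
    mesh: TetrahedralMesh,
    tissue: TissueTable,
    surface: CorticalSurface,
    active: str = "Fpz",
    returns: list[str] | None = None,
    progress: bool = False,
) -> LeadField:
    """Solve every active->return pair and stack the cortical normal
    fields into the lead-field matrix (one column per return electrode,
    layout order)."""
    if active not in mesh.electrode_nodes:
        raise ValidationError(f"active electrode {active!r} not in mesh")
    if returns is None:
        order = mesh.metadata.get("electrode_order", list(mesh.electrode_nodes))
        returns = [n for n in order if n != active]
    if not returns:
        raise ValidationError("need at least one return electrode")
    system = assemble_system(mesh, tissue)
    cols = np.empty((surface.n_elements, len(returns)))
    solver = ""
    for k, name in enumerate(returns):
        sol = solve_pair(system, active, name)
        cols[:, k] = cortical_normal_field(sol, surface)
        solver = sol.solver
        if progress:  # pragma: no cover
            print(f"  [{k + 1}/{len(returns)}] {active}->{name}", flush=True)
    return LeadField(
        cols,
        active,
        list(returns),
        surface.areas.copy(),
        mesh.content_hash(),
        metadata={
            "solver": solver,
            "direct_max_nodes": DIRECT_SOLVER_MAX_NODES,
            "cg_rtol": CG_RTOL,
            "n_nodes": mesh.n_nodes,
            "n_tets": mesh.n_tets,
        },
    )
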
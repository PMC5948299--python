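"""Linear-elastic voxel finite elements and per-element strain energy density.

One trilinear 8-node hexahedral element per labelled voxel, a single
reference stiffness matrix scaled by the element modulus, homogeneous
Dirichlet constraints on the lateral and distal crop faces, and a
Jacobi-preconditioned conjugate-gradient solve. Units are mm-N-MPa
throughout; strain energy density is reported in MPa.

The assembled stiffness matrix keeps a cached sparsity pattern per model,
so re-solves after a modulus change (remodelling iterations, sensitivity
runs) only recompute matrix entries, not the topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import sparse
from scipy.sparse.linalg import cg

from .image_pipeline import LABEL_BONE, LABEL_CARTILAGE, SegmentedModel
from .unit_loads import LoadCase

__all__ = [
    "FEModel",
    "SEDField",
    "SolverSettings",
    "hex8_stiffness",
    "build_model",
    "solve_load_case",
    "solve_count",
    "reset_solve_count",
]

# local node order: offsets (di, dj, dk), di slowest
_NODE_OFFSETS = np.array(
    [(di, dj, dk) for di in (0, 1) for dj in (0, 1) for dk in (0, 1)], dtype=int
)

_n_solves = 0


def solve_count() -> int:
    """Number of FE solves performed since the last reset (process-wide)."""
    return _n_solves


def reset_solve_count() -> None:
    global _n_solves
    _n_solves = 0


def _elastic_matrix(E: float, nu: float) -> np.ndarray:
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def hex8_stiffness(E: float, nu: float, h: float) -> np.ndarray:
    """Stiffness matrix (24x24) of a cubic trilinear hexahedron of side h.

    2x2x2 Gauss integration; dof order is (node, component) with the node
    order of ``_NODE_OFFSETS``.
    """
    C = _elastic_matrix(E, nu)
    g = _NODE_OFFSETS * 2 - 1  # node signs in the parent element
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    K = np.zeros((24, 24))
    detJ = (h / 2) ** 3
    for xi in gp:
        for eta in gp:
            for zeta in gp:
                s = np.array([xi, eta, zeta])
                # dN_a/dxi_d = g_ad/8 * prod_{e != d} (1 + g_ae * s_e)
                dN = np.empty((8, 3))
                for a in range(8):
                    for dcomp in range(3):
                        other = [e for e in range(3) if e != dcomp]
                        dN[a, dcomp] = (
                            g[a, dcomp] / 8.0
                            * np.prod([1 + g[a, e] * s[e] for e in other])
                        )
                dNdx = dN * (2.0 / h)
                B = np.zeros((6, 24))
                for a in range(8):
                    bx, by, bz = dNdx[a]
                    c = 3 * a
                    B[0, c] = bx
                    B[1, c + 1] = by
                    B[2, c + 2] = bz
                    B[3, c] = by
                    B[3, c + 1] = bx
                    B[4, c + 1] = bz
                    B[4, c + 2] = by
                    B[5, c] = bz
                    B[5, c + 2] = bx
                K += B.T @ C @ B * detJ
    return K


@dataclass
class SolverSettings:
    """Iterative solver controls for the voxel FE solve."""

    tolerance: float = 1e-6  # relative residual
    max_iterations: int = 20000
    preconditioner: str = "jacobi"  # or "none"

    def __post_init__(self) -> None:
        if not 0 < self.tolerance < 1:
            raise ValueError("tolerance must be in (0, 1)")
        if self.preconditioner not in ("jacobi", "none"):
            raise ValueError("preconditioner must be 'jacobi' or 'none'")


@dataclass
class FEModel:
    """Voxel FE mesh: active elements, per-element moduli, constraints."""

    element_mask: np.ndarray  # (nx, ny, nz) bool
    moduli: np.ndarray  # (nel,) MPa, order = np.argwhere(element_mask)
    labels: np.ndarray  # (nel,) uint8 {bone, cartilage}
    poisson: float
    element_size: float  # mm
    origin: np.ndarray  # mm, centre of element (0,0,0)
    constrained_faces: tuple[str, ...] = ("lateral", "distal")
    meta: dict = field(default_factory=dict)

    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.element_mask.sum() != len(self.moduli):
            raise ValueError("moduli length must equal number of active elements")
        if np.any(self.moduli <= 0):
            raise ValueError("all moduli must be > 0")
        if not 0 <= self.poisson < 0.5:
            raise ValueError(
                f"Poisson ratio must be in [0, 0.5) (incompressible limit unsupported), "
                f"got {self.poisson}"
            )

    # -- topology ---------------------------------------------------------
    @property
    def n_elements(self) -> int:
        return int(self.element_mask.sum())

    @property
    def element_indices(self) -> np.ndarray:
        return self._topology()["eidx"]

    def _topology(self) -> dict:
        if "eidx" in self._cache:
            return self._cache
        c = self._cache
        mask = self.element_mask
        eidx = np.argwhere(mask)
        shape_n = tuple(s + 1 for s in mask.shape)
        node_used = np.zeros(shape_n, dtype=bool)
        for off in _NODE_OFFSETS:
            node_used[off[0]:off[0] + mask.shape[0],
                      off[1]:off[1] + mask.shape[1],
                      off[2]:off[2] + mask.shape[2]] |= mask
        node_id = np.full(shape_n, -1, dtype=np.int64)
        node_id[node_used] = np.arange(node_used.sum())
        enodes = np.stack(
            [node_id[eidx[:, 0] + o[0], eidx[:, 1] + o[1], eidx[:, 2] + o[2]]
             for o in _NODE_OFFSETS], axis=1)
        edofs = (enodes[:, :, None] * 3 + np.arange(3)).reshape(len(eidx), 24)

        fixed_node = np.zeros(shape_n, dtype=bool)
        for face in self.constrained_faces:
            axis = {"lateral": 0, "distal": 2}[face]
            sl = [slice(None)] * 3
            sl[axis] = 0
            fixed_node[tuple(sl)] = True
        fixed = (fixed_node & node_used)[node_used]  # per active node
        n_nodes = int(node_used.sum())
        dof_fixed = np.repeat(fixed, 3)
        free_id = np.full(3 * n_nodes, -1, dtype=np.int64)
        free_id[~dof_fixed] = np.arange((~dof_fixed).sum())

        c.update(eidx=eidx, node_id=node_id, n_nodes=n_nodes,
                 edofs=edofs, dof_fixed=dof_fixed, free_id=free_id)
        return c

    def _pattern(self) -> dict:
        """Sparsity pattern of the reduced stiffness matrix (cached)."""
        c = self._topology()
        if "pair_inv" in c:
            return c
        fdofs = c["free_id"][c["edofs"]]  # (nel, 24), -1 where fixed
        rows = np.repeat(fdofs, 24, axis=1).ravel()
        cols = np.tile(fdofs, (1, 24)).ravel()
        valid = (rows >= 0) & (cols >= 0)
        nfree = int((~c["dof_fixed"]).sum())
        keys = rows[valid] * nfree + cols[valid]
        uniq, inv = np.unique(keys, return_inverse=True)
        rows_u = (uniq // nfree).astype(np.int32)
        cols_u = (uniq % nfree).astype(np.int32)
        indptr = np.searchsorted(rows_u, np.arange(nfree + 1))
        c.update(pair_valid=valid, pair_inv=inv, csr_indices=cols_u,
                 csr_indptr=indptr.astype(np.int64), nfree=nfree, nnz=len(uniq))
        return c

    def unit_ke(self) -> np.ndarray:
        key = ("ke", self.poisson, self.element_size)
        if key not in self._cache:
            self._cache[key] = hex8_stiffness(1.0, self.poisson, self.element_size)
        return self._cache[key]

    def stiffness(self) -> sparse.csr_matrix:
        """Assemble the reduced (free-dof) stiffness matrix in MPa*mm."""
        p = self._pattern()
        ke = self.unit_ke().ravel()
        data_all = (self.moduli[:, None] * ke[None, :]).ravel()[p["pair_valid"]]
        data = np.bincount(p["pair_inv"], weights=data_all, minlength=p["nnz"])
        return sparse.csr_matrix(
            (data, p["csr_indices"], p["csr_indptr"]),
            shape=(p["nfree"], p["nfree"]),
        )

    def force_vector(self, nodes: np.ndarray, forces: np.ndarray) -> np.ndarray:
        """Scatter nodal forces (lattice indices) into the free-dof vector."""
        c = self._topology()
        nid = c["node_id"][tuple(np.asarray(nodes, dtype=int).T)]
        if np.any(nid < 0):
            raise ValueError(f"{int((nid < 0).sum())} load nodes are not part of the FE model")
        f = np.zeros((~c["dof_fixed"]).sum())
        dofs = c["free_id"][(nid[:, None] * 3 + np.arange(3)).ravel()]
        vals = np.asarray(forces, dtype=float).ravel()
        keep = dofs >= 0
        np.add.at(f, dofs[keep], vals[keep])
        return f


@dataclass
class SEDField:
    """Per-element strain energy density (MPa) for one load case."""

    sed: np.ndarray  # (nel,), ordering of FEModel.element_indices
    is_bone: np.ndarray  # (nel,) bool; cartilage SED retained but flagged
    case_id: int
    element_size: float
    strain_energy: float  # N*mm, volume integral of the SED
    external_work: float  # N*mm, 0.5 * f . u
    u_free: np.ndarray = field(repr=False, default=None)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.sed)) or np.any(self.sed < -1e-12):
            raise ValueError("SED must be finite and non-negative")


def build_model(
    model: SegmentedModel,
    bone_modulus: float = 10_000.0,
    cartilage_modulus: float = 10.0,
    poisson: float = 0.3,
    constrained_faces: tuple[str, ...] = ("lateral", "distal"),
) -> FEModel:
    """Mesh a segmented model: one hexahedral element per labelled voxel.

    Floating element components not face-connected to a constrained crop
    face are removed with a warning (an unsupported fragment makes the
    system singular).
    """
    labels = model.labels.values
    active = labels > 0
    if not active.any():
        raise ValueError("segmented model contains no elements")

    lab, ncomp = ndimage.label(active, structure=ndimage.generate_binary_structure(3, 1))
    keep = np.zeros(ncomp + 1, dtype=bool)
    for face in constrained_faces:
        axis = {"lateral": 0, "distal": 2}[face]
        sl = [slice(None)] * 3
        sl[axis] = 0
        keep[np.unique(lab[tuple(sl)])] = True
    keep[0] = False
    if not keep.any():
        raise ValueError("no elements connected to the constrained boundary")
    removed = ncomp - int(keep[1:].sum())
    if removed:
        warnings.warn(f"removed {removed} floating element component(s) "
                      "not connected to the constrained boundary")
        active = active & keep[lab]

    eidx = np.argwhere(active)
    elabels = labels[active]
    moduli = np.where(elabels == LABEL_BONE, bone_modulus, cartilage_modulus).astype(float)
    return FEModel(
        element_mask=active,
        moduli=moduli,
        labels=elabels.astype(np.uint8),
        poisson=poisson,
        element_size=model.voxel_size,
        origin=model.labels.origin.copy(),
        constrained_faces=constrained_faces,
    )


def _solve_system(
    fe: FEModel,
    f: np.ndarray,
    settings: SolverSettings,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float]]:
    c = fe._topology()
    if not c["dof_fixed"].any():
        raise ValueError("singular system: model has no constrained nodes")
    K = fe.stiffness()
    M = None
    if settings.preconditioner == "jacobi":
        d = K.diagonal()
        if np.any(d <= 0):
            raise ValueError("singular system: non-positive stiffness diagonal")
        dinv = 1.0 / d
        M = sparse.linalg.LinearOperator(K.shape, matvec=lambda v: dinv * v)
    history: list[float] = []
    bnorm = np.linalg.norm(f)

    def cb(xk):
        history.append(float(np.linalg.norm(f - K @ xk) / bnorm))

    u, info = cg(K, f, x0=x0, rtol=settings.tolerance, atol=0.0,
                 maxiter=settings.max_iterations, M=M, callback=cb)
    if info != 0:
        raise RuntimeError(
            f"CG did not converge in {settings.max_iterations} iterations; "
            f"last relative residuals: {history[-5:]}"
        )
    global _n_solves
    _n_solves += 1
    return u, history


def solve_load_case(
    fe: FEModel,
    lc: LoadCase,
    settings: SolverSettings | None = None,
    x0: np.ndarray | None = None,
) -> SEDField:
    """Solve K u = f for one unit load case and recover per-element SED.

    The per-element SED is the element strain energy divided by the element
    volume, ``0.5 * u_e^T K_e u_e / h^3``, which makes the work balance
    ``0.5 f.u == integral of SED`` hold to solver accuracy.
    """
    settings = settings or SolverSettings()
    f = fe.force_vector(lc.nodes, lc.forces)
    u, history = _solve_system(fe, f, settings, x0=x0)
    c = fe._topology()
    ufull = np.zeros(3 * c["n_nodes"])
    ufull[~c["dof_fixed"]] = u
    ue = ufull[c["edofs"]]
    ke = fe.unit_ke()
    vol = fe.element_size**3
    energy = 0.5 * fe.moduli * np.einsum("ij,jk,ik->i", ue, ke, ue)
    sed = np.maximum(energy / vol, 0.0)
    return SEDField(
        sed=sed,
        is_bone=fe.labels == LABEL_BONE,
        case_id=lc.id,
        element_size=fe.element_size,
        strain_energy=float(energy.sum()),
        external_work=float(0.5 * f @ u),
        u_free=u,
        meta={"iterations": len(history), "relative_residual": history[-1] if history else 0.0},
    )
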
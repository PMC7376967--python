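"""Quasi-electrostatic current-flow solver on the voxel phantom.

At the 40 Hz stimulation frequency the displacement current is negligible
against the ohmic current, so the field problem reduces to the steady
current-flow equation ``div(sigma grad phi) = 0`` with Neumann (zero-flux)
outer boundaries and prescribed current injection at the electrode
contacts.  The discretization is a 7-point finite-volume stencil on the
voxel grid: the conductance of the face between two voxels is the harmonic
mean of their conductivities times face area over spacing, which is exact
for layered (1-D piecewise constant) media.  Electrode contacts inject the
montage current in equal shares per contact voxel; one sink-contact voxel
is pinned to 0 V as the gauge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph, linalg as spla

from .phantom import Electrode, Montage, TissueProperties, VoxelPhantom, place_montage

__all__ = [
    "LinearSystem",
    "PotentialField",
    "FieldMaps",
    "SingularSystemError",
    "NonConvergenceError",
    "Contacts",
    "assemble",
    "assemble_from_contacts",
    "solve",
    "fields_from_potential",
    "surface_current",
    "check_quasistatic",
    "analytic_point_source",
]

_EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

#: list of (role, voxel index array of shape (m, 3)) pairs, one per electrode
Contacts = list[tuple[str, np.ndarray]]


class SingularSystemError(RuntimeError):
    """Source and sink contacts are not connected through conductive tissue."""


class NonConvergenceError(RuntimeError):
    """Iterative solve failed to reach the requested residual."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass
class LinearSystem:
    """Reduced SPD system for the potential on conductive voxels.

    ``unknown_flat`` holds the flat voxel index of every unknown (the gauge
    voxel is excluded; its potential is 0 by construction).
    """

    matrix: sparse.csr_matrix
    rhs: np.ndarray
    unknown_flat: np.ndarray
    gauge_flat: int
    grid_shape: tuple[int, int, int]
    voxel_size_m: float
    injected_current_A: float

    @property
    def n_unknowns(self) -> int:
        return int(self.rhs.size)


@dataclass
class PotentialField:
    """Electric potential on the grid (V); background voxels hold 0."""

    phi: np.ndarray
    residual: float
    iterations: int
    converged: bool
    gauge_flat: int


@dataclass
class FieldMaps:
    """Vector E (V/m) and J (A/m^2) per voxel plus their magnitudes."""

    E: np.ndarray     # (*grid, 3)
    J: np.ndarray     # (*grid, 3)
    magE: np.ndarray  # (*grid,)
    magJ: np.ndarray  # (*grid,)


def assemble(phantom: VoxelPhantom, montage: Montage) -> LinearSystem:
    """Place the montage on the dura and assemble the finite-volume system."""
    placed = place_montage(phantom, montage)
    contacts: Contacts = [(e.role, vox) for e, vox in placed.items()]
    return assemble_from_contacts(phantom, contacts, montage.current_amplitude_A)


def assemble_from_contacts(
    phantom: VoxelPhantom, contacts: Contacts, current_A: float
) -> LinearSystem:
    """Assemble the system for explicit contact voxel sets.

    The total current ``current_A`` is split equally across source
    electrodes, and within each electrode equally across its contact
    voxels (mirrored with negative sign at the sinks), so the right-hand
    side always sums to zero.
    """
    if current_A < 0:
        raise ValueError("current_A must be >= 0")
    labels = phantom.labels
    shape = labels.shape
    conductive = labels > 0
    sigma = phantom.sigma_volume()
    h = phantom.voxel_size_m

    n_vox = labels.size
    flat_index = -np.ones(n_vox, dtype=np.int64)
    cond_flat = np.flatnonzero(conductive.ravel())
    flat_index[cond_flat] = np.arange(cond_flat.size)

    sig_flat = sigma.ravel()
    rows, cols, vals = [], [], []
    strides = (shape[1] * shape[2], shape[2], 1)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, shape[axis] - 1)
        sl_b[axis] = slice(1, shape[axis])
        mask = conductive[tuple(sl_a)] & conductive[tuple(sl_b)]
        ia = np.flatnonzero(np.pad(mask, [(0, 1) if k == axis else (0, 0) for k in range(3)]).ravel())
        ib = ia + strides[axis]
        sa, sb = sig_flat[ia], sig_flat[ib]
        # harmonic-mean face conductance: (2 sa sb / (sa + sb)) * area / spacing
        g = (2.0 * sa * sb / (sa + sb)) * h
        rows.append(flat_index[ia])
        cols.append(flat_index[ib])
        vals.append(-g)
        rows.append(flat_index[ib])
        cols.append(flat_index[ia])
        vals.append(-g)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    n = cond_flat.size
    A = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A = A + sparse.diags(-np.asarray(A.sum(axis=1)).ravel())

    # Right-hand side: equal electrode shares, equal per-voxel shares.
    b = np.zeros(n)
    sources = [(r, v) for r, v in contacts if r == "source"]
    sinks = [(r, v) for r, v in contacts if r == "sink"]
    if not sources or not sinks:
        raise ValueError("contacts must include at least one source and one sink")
    for group, sign in ((sources, +1.0), (sinks, -1.0)):
        per_electrode = current_A / len(group)
        for _, vox in group:
            vox = np.asarray(vox)
            flat = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), shape)
            if np.any(flat_index[flat] < 0):
                raise ValueError("contact voxel lies on a non-conductive voxel")
            b[flat_index[flat]] += sign * per_electrode / vox.shape[0]

    # Connectivity: all electrodes must share one conductive component, and
    # only that component enters the unknowns (floating islands are dropped).
    n_comp, comp = csgraph.connected_components(A, directed=False)
    elec_unknowns = np.flatnonzero(b != 0.0)
    elec_comp = np.unique(comp[elec_unknowns])
    if elec_comp.size > 1:
        raise SingularSystemError(
            "source and sink contacts lie in disconnected conductive regions"
        )
    keep_comp = int(elec_comp[0]) if elec_comp.size else 0

    sink_vox = np.asarray(sinks[0][1])
    gauge_flat = int(np.ravel_multi_index((sink_vox[0, 0], sink_vox[0, 1], sink_vox[0, 2]), shape))
    gauge_unknown = int(flat_index[gauge_flat])

    keep = (comp == keep_comp)
    keep[gauge_unknown] = False
    A_red = A[keep][:, keep].tocsr()
    b_red = b[keep]
    return LinearSystem(
        matrix=A_red,
        rhs=b_red,
        unknown_flat=cond_flat[keep],
        gauge_flat=gauge_flat,
        grid_shape=shape,
        voxel_size_m=h,
        injected_current_A=current_A,
    )


def solve(
    system: LinearSystem,
    tol: float = 1e-8,
    maxiter: int | None = None,
    method: str = "cg",
) -> PotentialField:
    """Solve for the potential.

    ``method='cg'`` runs Jacobi-preconditioned conjugate gradients to a
    relative residual of ``tol``; ``method='direct'`` uses a sparse LU
    factorization (practical for the small oracle systems).  Both are
    deterministic for fixed inputs.
    """
    A, b = system.matrix, system.rhs
    bnorm = float(np.linalg.norm(b))
    if bnorm == 0.0:
        x = np.zeros_like(b)
        residual, iterations = 0.0, 0
    elif method == "direct":
        x = spla.spsolve(A.tocsc(), b)
        residual = float(np.linalg.norm(b - A @ x) / bnorm)
        iterations = 0
    elif method == "cg":
        diag = A.diagonal()
        M = sparse.diags(1.0 / diag)
        history: list[float] = []

        def callback(xk: np.ndarray) -> None:
            history.append(float(np.linalg.norm(b - A @ xk) / bnorm))

        maxiter = maxiter if maxiter is not None else 50_000
        x, info = spla.cg(A, b, rtol=tol, atol=0.0, M=M, maxiter=maxiter, callback=callback)
        residual = float(np.linalg.norm(b - A @ x) / bnorm)
        iterations = len(history)
        if residual > tol:
            raise NonConvergenceError(
                f"CG stalled at relative residual {residual:.3e} after {iterations} "
                f"iterations (requested {tol:.1e})",
                history,
            )
    else:
        raise ValueError(f"unknown method {method!r}")

    phi = np.zeros(int(np.prod(system.grid_shape)))
    phi[system.unknown_flat] = x
    return PotentialField(
        phi=phi.reshape(system.grid_shape),
        residual=residual,
        iterations=iterations,
        converged=True,
        gauge_flat=system.gauge_flat,
    )


def fields_from_potential(potential: PotentialField, phantom: VoxelPhantom) -> FieldMaps:
    """Differentiate the potential into E = -grad(phi) and J = sigma E.

    Central differences are used where both neighbours are conductive,
    one-sided differences at tissue surfaces; background voxels carry zero
    field.
    """
    phi = potential.phi
    conductive = phantom.labels > 0
    h = phantom.voxel_size_m
    E = np.zeros(phi.shape + (3,))

    for axis in range(3):
        fwd_ok = np.zeros_like(conductive)
        bwd_ok = np.zeros_like(conductive)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        fwd_ok[tuple(sl_lo)] = conductive[tuple(sl_hi)]
        bwd_ok[tuple(sl_hi)] = conductive[tuple(sl_lo)]
        fwd_ok &= conductive
        bwd_ok &= conductive

        phi_fwd = np.zeros_like(phi)
        phi_bwd = np.zeros_like(phi)
        phi_fwd[tuple(sl_lo)] = phi[tuple(sl_hi)]
        phi_bwd[tuple(sl_hi)] = phi[tuple(sl_lo)]

        grad = np.zeros_like(phi)
        central = fwd_ok & bwd_ok
        grad[central] = (phi_fwd[central] - phi_bwd[central]) / (2.0 * h)
        fwd_only = fwd_ok & ~bwd_ok
        grad[fwd_only] = (phi_fwd[fwd_only] - phi[fwd_only]) / h
        bwd_only = bwd_ok & ~fwd_ok
        grad[bwd_only] = (phi[bwd_only] - phi_bwd[bwd_only]) / h
        E[..., axis] = -grad

    sigma = phantom.sigma_volume()
    J = E * sigma[..., None]
    magE = np.linalg.norm(E, axis=-1)
    magJ = np.linalg.norm(J, axis=-1)
    magE[~conductive] = 0.0
    magJ[~conductive] = 0.0
    return FieldMaps(E=E, J=J, magE=magE, magJ=magJ)


def surface_current(
    potential: PotentialField, phantom: VoxelPhantom, inside: np.ndarray
) -> float:
    """Net finite-volume current (A) flowing out of the voxel set ``inside``.

    Uses the face conductances of the discretization, for which Kirchhoff's
    current law holds to solver precision; summing the cell-centred J over a
    surface would only be O(h^2) accurate.
    """
    phi = potential.phi
    sigma = phantom.sigma_volume()
    conductive = phantom.labels > 0
    inside = np.asarray(inside, dtype=bool)
    h = phantom.voxel_size_m
    total = 0.0
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        a, b = tuple(sl_a), tuple(sl_b)
        face = conductive[a] & conductive[b]
        crossing_out = face & inside[a] & ~inside[b]
        crossing_in = face & ~inside[a] & inside[b]
        sa, sb = sigma[a], sigma[b]
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(sa + sb > 0, 2.0 * sa * sb / (sa + sb), 0.0) * h
        flux = g * (phi[a] - phi[b])  # current a -> b
        total += float(flux[crossing_out].sum()) - float(flux[crossing_in].sum())
    return total


def check_quasistatic(
    properties: dict[int, TissueProperties] | list[TissueProperties],
    frequency_hz: float,
    flag_ratio: float = 0.1,
) -> pd.DataFrame:
    """Displacement-to-ohmic current ratio ``2 pi f eps0 eps_r / sigma`` per tissue.

    Tissues with a ratio at or above ``flag_ratio`` are flagged: for them the
    purely ohmic solve is questionable at this frequency.
    """
    if frequency_hz < 0:
        raise ValueError("frequency must be >= 0")
    props = list(properties.values()) if isinstance(properties, dict) else list(properties)
    rows = []
    for p in props:
        ratio = 2.0 * np.pi * frequency_hz * _EPS0 * p.eps_r / p.sigma
        rows.append(
            {
                "label_id": p.label_id,
                "name": p.name,
                "sigma_S_per_m": p.sigma,
                "eps_r": p.eps_r,
                "ratio": ratio,
                "flagged": bool(ratio >= flag_ratio),
            }
        )
    return pd.DataFrame(rows)


def analytic_point_source(sigma: float, current_A: float, r_m: float) -> float:
    """Free-space monopole potential ``I / (4 pi sigma r)`` in volts."""
    if r_m <= 0:
        raise ValueError("r must be > 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return current_A / (4.0 * np.pi * sigma * r_m)
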
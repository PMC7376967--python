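"""Parametric layered voxel phantom of the mouse head for current-flow modelling.

The phantom replaces an MRI/Nissl segmentation with a small set of tissue
classes that carry the conductivity contrasts the physics actually depends
on: a resistive dura cover, a thin highly conductive CSF film beneath it, a
gray-matter cortical shell over white matter, CSF-filled lateral ventricles,
a one-voxel subventricular-zone (SVZ) shell around each ventricle, and the
paired hippocampi between ventricle and cortex.

Coordinate conventions
----------------------
Voxel axes are ``(AP, ML, Z)``: axis 0 increases anterior, axis 1 increases
toward the animal's right, axis 2 increases dorsally ("up").  Stereotaxic
coordinates are millimetres relative to bregma with AP positive anterior,
ML positive right and DV positive *downward* from the dura surface, so
``voxel = bregma_voxel + (AP, ML, -DV) / voxel_size``.  Voxel indices are
0-based.  All lengths are mm except voxel size and shell thicknesses, which
are given in micrometres.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Tissue",
    "TissueProperties",
    "PhantomSpec",
    "VoxelPhantom",
    "Electrode",
    "Montage",
    "InvalidSpecError",
    "PlacementError",
    "OutOfBoundsError",
    "REFERENCE_GRID_SHAPE",
    "PARENCHYMA_LABELS",
    "default_tissue_table",
    "load_tissue_table",
    "save_tissue_table",
    "effective_shell_conductivity",
    "build_phantom",
    "add_shell",
    "stereotaxic_to_voxel",
    "place_montage",
    "optimized_montage",
    "candidate_montages",
    "save_phantom_nifti",
    "load_phantom_nifti",
]

#: Grid of the published atlas-based model at 100 um; coarser grids scale it down.
REFERENCE_GRID_SHAPE = (189, 236, 152)
REFERENCE_VOXEL_UM = 100.0

_EPS0 = 8.8541878128e-12  # F/m


class Tissue(IntEnum):
    """Functional tissue classes of the phantom (label 0 is background)."""

    BACKGROUND = 0
    DURA = 1
    CSF = 2          # thin film between dura and cortex
    GRAY = 3
    WHITE = 4
    VENTRICLE = 5    # CSF-filled interior cavity
    HIPPOCAMPUS = 6
    SVZ_SHELL = 7    # 1-voxel parenchymal shell lining the ventricles


#: Labels counted as brain parenchyma (lesion-safety domain).
PARENCHYMA_LABELS = (Tissue.GRAY, Tissue.WHITE, Tissue.HIPPOCAMPUS, Tissue.SVZ_SHELL)


class InvalidSpecError(ValueError):
    """Phantom specification violates a geometric invariant."""


class PlacementError(ValueError):
    """Electrode cannot be placed on the dura as requested."""


class OutOfBoundsError(IndexError):
    """Stereotaxic coordinate maps outside the voxel grid."""


@dataclass(frozen=True)
class TissueProperties:
    """Electrical properties of one tissue class at the stimulation frequency.

    sigma is the conductivity in S/m, eps_r the relative permittivity
    (dimensionless, >= 1) and frequency the Hz at which both apply.
    """

    label_id: int
    name: str
    sigma: float
    eps_r: float
    frequency: float = 40.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma} for {self.name!r}")
        if self.eps_r < 1:
            raise ValueError(f"eps_r must be >= 1, got {self.eps_r} for {self.name!r}")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")


# Low-frequency (40 Hz) conductivities follow the values commonly used in
# transcranial stimulation volume-conductor models; permittivities are
# order-of-magnitude low-frequency figures and only enter the quasi-static
# validity report, never the ohmic solve.
_DEFAULT_TABLE = (
    TissueProperties(int(Tissue.DURA), "dura", 0.16, 1.0e4),
    TissueProperties(int(Tissue.CSF), "csf", 1.79, 1.09e2),
    TissueProperties(int(Tissue.GRAY), "gray matter", 0.276, 1.0e6),
    TissueProperties(int(Tissue.WHITE), "white matter", 0.126, 1.0e6),
    TissueProperties(int(Tissue.VENTRICLE), "ventricle csf", 1.79, 1.09e2),
    TissueProperties(int(Tissue.HIPPOCAMPUS), "hippocampus", 0.276, 1.0e6),
    TissueProperties(int(Tissue.SVZ_SHELL), "svz shell", 0.276, 1.0e6),
)


def default_tissue_table() -> dict[int, TissueProperties]:
    """Return the default label -> properties map (fresh copy)."""
    table = {p.label_id: p for p in _DEFAULT_TABLE}
    _validate_conductivity_ordering(table)
    return table


def _validate_conductivity_ordering(table: Mapping[int, TissueProperties]) -> None:
    """CSF must be more conductive than gray matter, gray more than white."""
    by_name = {p.name: p for p in table.values()}
    try:
        csf, gray, white = by_name["csf"], by_name["gray matter"], by_name["white matter"]
    except KeyError:
        return
    if not (csf.sigma > gray.sigma > white.sigma):
        raise ValueError(
            "conductivity ordering violated: expected csf > gray matter > white matter, "
            f"got {csf.sigma}, {gray.sigma}, {white.sigma}"
        )


def load_tissue_table(path: str | Path) -> dict[int, TissueProperties]:
    """Read a tissue-property table from CSV.

    Expected columns: ``label_id,name,sigma_S_per_m,eps_r,frequency_Hz``.
    """
    df = pd.read_csv(path)
    required = {"label_id", "name", "sigma_S_per_m", "eps_r", "frequency_Hz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tissue table missing columns: {sorted(missing)}")
    if df["label_id"].duplicated().any():
        raise ValueError("label_id values must be unique")
    table = {
        int(r.label_id): TissueProperties(
            int(r.label_id), str(r.name), float(r.sigma_S_per_m), float(r.eps_r), float(r.frequency_Hz)
        )
        for r in df.itertuples()
    }
    _validate_conductivity_ordering(table)
    return table


def save_tissue_table(table: Mapping[int, TissueProperties], path: str | Path) -> None:
    rows = [
        {
            "label_id": p.label_id,
            "name": p.name,
            "sigma_S_per_m": p.sigma,
            "eps_r": p.eps_r,
            "frequency_Hz": p.frequency,
        }
        for p in sorted(table.values(), key=lambda p: p.label_id)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the parametric head phantom.

    Structure centres are mm offsets from the brain centre in ``(AP, ML, Z)``
    with Z positive dorsal; paired structures are mirrored about the midline.
    ``brain_center_ap_mm`` locates the brain centre relative to bregma along
    AP (the mouse brain centre sits roughly 2 mm caudal to bregma).
    """

    grid_shape: tuple[int, int, int] = (95, 118, 76)
    voxel_size_um: float = 200.0
    brain_semiaxes_mm: tuple[float, float, float] = (7.5, 4.5, 3.25)
    cortex_thickness_mm: float = 1.0
    ventricle_center_mm: tuple[float, float, float] = (1.4, 1.2, 0.9)
    ventricle_semiaxes_mm: tuple[float, float, float] = (1.8, 0.45, 0.8)
    hippocampus_center_mm: tuple[float, float, float] = (-1.3, 2.2, 0.8)
    hippocampus_semiaxes_mm: tuple[float, float, float] = (1.5, 0.9, 0.8)
    dura_thickness_um: float = 300.0
    csf_thickness_um: float = 43.0
    brain_center_ap_mm: float = -2.0
    bregma_voxel: tuple[float, float, float] | None = None

    @classmethod
    def default(cls, resolution_um: float = 200.0) -> "PhantomSpec":
        """Default spec at the requested resolution (100 um is the published grid)."""
        factor = resolution_um / REFERENCE_VOXEL_UM
        shape = tuple(int(math.ceil(n / factor)) for n in REFERENCE_GRID_SHAPE)
        return cls(grid_shape=shape, voxel_size_um=float(resolution_um))

    def validate(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise InvalidSpecError(f"grid too small: {self.grid_shape}")
        if self.voxel_size_um <= 0:
            raise InvalidSpecError("voxel_size_um must be > 0")
        for t in (self.dura_thickness_um, self.csf_thickness_um, self.cortex_thickness_mm):
            if t <= 0:
                raise InvalidSpecError("all thicknesses must be > 0")
        if any(a <= 0 for a in self.brain_semiaxes_mm):
            raise InvalidSpecError("brain semi-axes must be > 0")
        if any(a < 0 for a in self.ventricle_semiaxes_mm + self.hippocampus_semiaxes_mm):
            raise InvalidSpecError("structure semi-axes must be >= 0")
        h = self.voxel_size_um / 1000.0
        shells_mm = (
            math.ceil(self.csf_thickness_um / self.voxel_size_um)
            + math.ceil(self.dura_thickness_um / self.voxel_size_um)
        ) * h
        half_extent = [(n - 1) / 2.0 * h for n in self.grid_shape]
        for ax in range(3):
            if self.brain_semiaxes_mm[ax] + shells_mm + h >= half_extent[ax]:
                raise InvalidSpecError(
                    f"brain plus shells does not fit grid along axis {ax}"
                )


@dataclass
class VoxelPhantom:
    """Labelled voxel volume plus tissue properties and stereotaxic origin."""

    labels: np.ndarray                       # int16, shape = grid_shape
    voxel_size_um: float
    bregma_voxel: tuple[float, float, float]
    properties: dict[int, TissueProperties]
    provenance: str = ""

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def voxel_size_m(self) -> float:
        return self.voxel_size_um * 1e-6

    def mask(self, labels: int | Tissue | Iterable[int]) -> np.ndarray:
        if isinstance(labels, (int, np.integer)):
            return self.labels == int(labels)
        return np.isin(self.labels, [int(l) for l in labels])

    def sigma_volume(self) -> np.ndarray:
        """Conductivity per voxel in S/m; background carries 0."""
        sigma = np.zeros(self.labels.shape, dtype=np.float64)
        for label_id, props in self.properties.items():
            sigma[self.labels == label_id] = props.sigma
        return sigma

    def validate(self) -> None:
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.properties)
        if missing:
            raise ValueError(f"labels without properties: {sorted(missing)}")


def effective_shell_conductivity(sigma: float, true_thickness_um: float, voxel_size_um: float) -> float:
    """Conductivity for a sub-voxel shell rasterized at one full voxel.

    A film of thickness t < voxel size painted as a full voxel would
    otherwise overstate its tangential sheet conductance sigma*t; scaling to
    ``sigma * t / voxel`` preserves it (isotropically — the normal-direction
    conductance is deliberately scaled the same way).
    """
    if sigma <= 0 or true_thickness_um <= 0 or voxel_size_um <= 0:
        raise ValueError("all arguments must be > 0")
    if true_thickness_um > voxel_size_um:
        raise ValueError(
            "shell thicker than a voxel must be rasterized over several voxels, not scaled"
        )
    return sigma * true_thickness_um / voxel_size_um


def _ellipsoid_mask(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    center: Sequence[float],
    semiaxes: Sequence[float],
) -> np.ndarray:
    if any(a <= 0 for a in semiaxes):
        return np.zeros(np.broadcast_shapes(*(c.shape for c in coords)), dtype=bool)
    x, y, z = coords
    q = (
        ((x - center[0]) / semiaxes[0]) ** 2
        + ((y - center[1]) / semiaxes[1]) ** 2
        + ((z - center[2]) / semiaxes[2]) ** 2
    )
    return q < 1.0


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def build_phantom(
    spec: PhantomSpec,
    properties: Mapping[int, TissueProperties] | None = None,
) -> VoxelPhantom:
    """Rasterize the parametric head model.

    Layer order from outside in: dura shell, CSF film, gray-matter cortex,
    white matter; ventricles are interior CSF cavities, each wrapped by a
    one-voxel SVZ shell; hippocampi lie between ventricle and cortex.
    Deterministic: identical specs give identical volumes.
    """
    spec.validate()
    table = dict(properties) if properties is not None else default_tissue_table()
    _validate_conductivity_ordering(table)

    h = spec.voxel_size_um / 1000.0
    n0, n1, n2 = spec.grid_shape
    center = ((n0 - 1) / 2.0, (n1 - 1) / 2.0, (n2 - 1) / 2.0)
    ax = ((np.arange(n0) - center[0]) * h)[:, None, None]
    ay = ((np.arange(n1) - center[1]) * h)[None, :, None]
    az = ((np.arange(n2) - center[2]) * h)[None, None, :]
    coords = (ax, ay, az)

    brain = _ellipsoid_mask(coords, (0.0, 0.0, 0.0), spec.brain_semiaxes_mm)
    inner_axes = tuple(a - spec.cortex_thickness_mm for a in spec.brain_semiaxes_mm)
    if any(a <= 0 for a in inner_axes):
        raise InvalidSpecError("cortex shell consumes the whole brain")
    white = _ellipsoid_mask(coords, (0.0, 0.0, 0.0), inner_axes)

    vc, va = spec.ventricle_center_mm, spec.ventricle_semiaxes_mm
    hc, ha = spec.hippocampus_center_mm, spec.hippocampus_semiaxes_mm
    ventricle = np.zeros(spec.grid_shape, dtype=bool)
    hippocampus = np.zeros(spec.grid_shape, dtype=bool)
    for side in (+1.0, -1.0):
        ventricle |= _ellipsoid_mask(coords, (vc[0], side * vc[1], vc[2]), va)
        hippocampus |= _ellipsoid_mask(coords, (hc[0], side * hc[1], hc[2]), ha)
    ventricle &= brain
    hippocampus &= brain

    if (ventricle & hippocampus).any():
        raise InvalidSpecError("ventricle and hippocampus geometries intersect")

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[brain] = Tissue.GRAY
    labels[white] = Tissue.WHITE
    labels[hippocampus] = Tissue.HIPPOCAMPUS
    if ventricle.any():
        svz = ndimage.binary_dilation(ventricle, structure=_FACE_STRUCT) & (
            (labels == Tissue.GRAY) | (labels == Tissue.WHITE)
        )
        labels[svz] = Tissue.SVZ_SHELL
        labels[ventricle] = Tissue.VENTRICLE

    phantom = VoxelPhantom(
        labels=labels,
        voxel_size_um=spec.voxel_size_um,
        bregma_voxel=(0.0, 0.0, 0.0),  # fixed after shells are added
        properties=table,
        provenance=(
            f"parametric mouse-head phantom, grid {spec.grid_shape}, "
            f"voxel {spec.voxel_size_um:g} um"
        ),
    )

    # CSF film then dura cover; sub-voxel films get conductance-preserving sigma.
    for thickness_um, label in (
        (spec.csf_thickness_um, Tissue.CSF),
        (spec.dura_thickness_um, Tissue.DURA),
    ):
        props = table[int(label)]
        if thickness_um < spec.voxel_size_um:
            sigma_eff = effective_shell_conductivity(props.sigma, thickness_um, spec.voxel_size_um)
            phantom.properties[int(label)] = replace(
                props,
                sigma=sigma_eff,
                name=f"{props.name} ({thickness_um:g} um effective)",
            )
        phantom = add_shell(phantom, thickness_um, int(label))

    phantom.bregma_voxel = _locate_bregma(phantom, spec, center)
    phantom.validate()
    return phantom


def _locate_bregma(
    phantom: VoxelPhantom, spec: PhantomSpec, center: tuple[float, float, float]
) -> tuple[float, float, float]:
    if spec.bregma_voxel is not None:
        return tuple(float(v) for v in spec.bregma_voxel)
    h = spec.voxel_size_um / 1000.0
    ap = center[0] + (-spec.brain_center_ap_mm) / h  # bregma anterior of brain centre
    ml = center[1]
    column = phantom.labels[int(round(ap)), int(round(ml)), :]
    dura_z = np.nonzero(column == Tissue.DURA)[0]
    if dura_z.size == 0:
        raise InvalidSpecError("no dura surface found at the bregma column")
    return (float(ap), float(ml), float(dura_z.max()))


def add_shell(phantom: VoxelPhantom, thickness_um: float, new_label: int) -> VoxelPhantom:
    """Grow an outward shell of ``ceil(thickness/voxel)`` voxels over the surface.

    Existing labels are never overwritten.  For thickness below one voxel the
    shell is one voxel thick and the caller must register a conductance-
    preserving conductivity via :func:`effective_shell_conductivity`.
    """
    if thickness_um <= 0:
        raise InvalidSpecError("shell thickness must be > 0")
    if int(new_label) not in phantom.properties:
        raise InvalidSpecError(f"label {new_label} not registered in the property table")
    n_layers = max(1, math.ceil(thickness_um / phantom.voxel_size_um))
    body = phantom.labels > 0
    if not body.any():
        raise InvalidSpecError("cannot add a shell to an empty phantom")

    # Reject shells that would be clipped by the grid boundary.
    edge = np.ones(body.shape, dtype=bool)
    edge[n_layers:-n_layers or None, n_layers:-n_layers or None, n_layers:-n_layers or None] = False
    if (body & edge).any():
        raise InvalidSpecError("shell exceeds grid bounds")

    grown = ndimage.binary_dilation(body, structure=_FACE_STRUCT, iterations=n_layers)
    new_labels = phantom.labels.copy()
    new_labels[grown & ~body] = new_label
    return VoxelPhantom(
        labels=new_labels,
        voxel_size_um=phantom.voxel_size_um,
        bregma_voxel=phantom.bregma_voxel,
        properties=dict(phantom.properties),
        provenance=phantom.provenance,
    )


def stereotaxic_to_voxel(
    phantom: VoxelPhantom, ap_mm: float, ml_mm: float, dv_mm: float = 0.0
) -> tuple[int, int, int]:
    """Map (AP, ML, DV) mm relative to bregma to the nearest voxel index."""
    h = phantom.voxel_size_mm
    b = phantom.bregma_voxel
    idx = (
        int(round(b[0] + ap_mm / h)),
        int(round(b[1] + ml_mm / h)),
        int(round(b[2] - dv_mm / h)),
    )
    for i, n in zip(idx, phantom.labels.shape):
        if i < 0 or i >= n:
            raise OutOfBoundsError(
                f"stereotaxic ({ap_mm}, {ml_mm}, {dv_mm}) mm maps outside the grid: {idx}"
            )
    return idx


@dataclass(frozen=True)
class Electrode:
    """A screw contact resting on the dura surface."""

    center_ap_mm: float
    center_ml_mm: float
    contact_diameter_mm: float = 1.5
    role: str = "source"

    def __post_init__(self) -> None:
        if self.contact_diameter_mm <= 0:
            raise ValueError("contact_diameter_mm must be > 0")
        if self.role not in ("source", "sink"):
            raise ValueError(f"role must be 'source' or 'sink', got {self.role!r}")


@dataclass(frozen=True)
class Montage:
    """Electrode set plus injected current amplitude and frequency."""

    electrodes: tuple[Electrode, ...]
    current_amplitude_A: float = 1e-4
    frequency_hz: float = 40.0
    name: str = "montage"

    def __post_init__(self) -> None:
        roles = [e.role for e in self.electrodes]
        if "source" not in roles or "sink" not in roles:
            raise ValueError("montage needs at least one source and one sink")
        if self.current_amplitude_A <= 0:
            raise ValueError("current_amplitude_A must be > 0")
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be > 0")

    @property
    def sources(self) -> tuple[Electrode, ...]:
        return tuple(e for e in self.electrodes if e.role == "source")

    @property
    def sinks(self) -> tuple[Electrode, ...]:
        return tuple(e for e in self.electrodes if e.role == "sink")


def optimized_montage(
    current_amplitude_A: float = 1e-4,
    frequency_hz: float = 40.0,
    contact_diameter_mm: float = 1.5,
) -> Montage:
    """The deployed bilateral montage: AP -2 mm, ML +/-4 mm on the dura."""
    return Montage(
        electrodes=(
            Electrode(-2.0, 4.0, contact_diameter_mm, "source"),
            Electrode(-2.0, -4.0, contact_diameter_mm, "sink"),
        ),
        current_amplitude_A=current_amplitude_A,
        frequency_hz=frequency_hz,
        name="optimized",
    )


def candidate_montages(current_amplitude_A: float = 1e-4) -> dict[str, Montage]:
    """The deployed wide pair plus four narrow candidate pairs (I-IV).

    The narrow candidates keep the contacts close to the midline, i.e. a
    much shorter inter-electrode distance than the 8 mm of the wide pair.
    """

    def pair(name: str, ap: float, ml: float) -> Montage:
        return Montage(
            electrodes=(
                Electrode(ap, ml, 1.5, "source"),
                Electrode(ap, -ml, 1.5, "sink"),
            ),
            current_amplitude_A=current_amplitude_A,
            name=name,
        )

    return {
        "optimized": optimized_montage(current_amplitude_A),
        "I": pair("I", -2.0, 1.0),
        "II": pair("II", -1.0, 1.0),
        "III": pair("III", -3.0, 1.0),
        "IV": pair("IV", -2.0, 1.5),
    }


def place_montage(phantom: VoxelPhantom, montage: Montage) -> dict[Electrode, np.ndarray]:
    """Project each contact disc onto the dura surface.

    A grid column belongs to a disc iff its centre lies strictly within the
    contact radius of the electrode centre (half-open, centre-based rule);
    within each column the topmost dura voxel is taken.  The returned voxel
    sets are disjoint and consist of dura voxels only.
    """
    h = phantom.voxel_size_mm
    b = phantom.bregma_voxel
    n0, n1, _ = phantom.labels.shape
    dura = phantom.labels == Tissue.DURA

    out: dict[Electrode, np.ndarray] = {}
    claimed: set[tuple[int, int, int]] = set()
    for elec in montage.electrodes:
        c0 = b[0] + elec.center_ap_mm / h
        c1 = b[1] + elec.center_ml_mm / h
        r_vox = (elec.contact_diameter_mm / 2.0) / h
        i_lo, i_hi = int(math.floor(c0 - r_vox)), int(math.ceil(c0 + r_vox))
        j_lo, j_hi = int(math.floor(c1 - r_vox)), int(math.ceil(c1 + r_vox))
        if i_lo < 0 or j_lo < 0 or i_hi >= n0 or j_hi >= n1:
            raise PlacementError(f"electrode {elec} extends outside the grid")
        voxels: list[tuple[int, int, int]] = []
        for i in range(i_lo, i_hi + 1):
            for j in range(j_lo, j_hi + 1):
                if (i - c0) ** 2 + (j - c1) ** 2 >= r_vox**2:
                    continue
                ks = np.nonzero(dura[i, j, :])[0]
                if ks.size == 0:
                    raise PlacementError(
                        f"contact column ({i}, {j}) of electrode {elec} misses the dura"
                    )
                voxels.append((i, j, int(ks.max())))
        if not voxels:
            raise PlacementError(f"electrode {elec} rasterizes to an empty contact")
        overlap = claimed.intersection(voxels)
        if overlap:
            raise PlacementError(f"electrode discs overlap at voxels {sorted(overlap)[:3]}")
        claimed.update(voxels)
        out[elec] = np.asarray(voxels, dtype=np.intp)
    return out


# ---------------------------------------------------------------------------
# NIfTI input/output


def save_phantom_nifti(phantom: VoxelPhantom, path: str | Path) -> Path:
    """Write labels as int16 NIfTI plus a JSON sidecar with metadata."""
    path = Path(path)
    h = phantom.voxel_size_mm
    img = nib.Nifti1Image(phantom.labels.astype(np.int16), np.diag([h, h, h, 1.0]))
    img.header["descrip"] = f"bregma={','.join(f'{v:g}' for v in phantom.bregma_voxel)}".encode()
    nib.save(img, str(path))
    sidecar = {
        "voxel_size_um": phantom.voxel_size_um,
        "bregma_voxel": list(phantom.bregma_voxel),
        "provenance": phantom.provenance,
        "properties": [
            {
                "label_id": p.label_id,
                "name": p.name,
                "sigma_S_per_m": p.sigma,
                "eps_r": p.eps_r,
                "frequency_Hz": p.frequency,
            }
            for p in sorted(phantom.properties.values(), key=lambda p: p.label_id)
        ],
    }
    sidecar_path = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return path


def load_phantom_nifti(path: str | Path) -> VoxelPhantom:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj, dtype=np.int16)
    sidecar_path = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    properties = {
        int(p["label_id"]): TissueProperties(
            int(p["label_id"]), p["name"], p["sigma_S_per_m"], p["eps_r"], p["frequency_Hz"]
        )
        for p in meta["properties"]
    }
    return VoxelPhantom(
        labels=labels,
        voxel_size_um=float(meta["voxel_size_um"]),
        bregma_voxel=tuple(meta["bregma_voxel"]),
        properties=properties,
        provenance=meta.get("provenance", ""),
    )
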
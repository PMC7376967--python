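"""Synthetic inputs with the statistical and physical structure of the study.

Two kinds of synthetic objects are produced:

* hierarchical cell-count datasets whose group structure matches the
  reported summaries (3 groups x 5 animals x 2 regions x 3 markers, counted
  over 6 sections x 3 views), generated from a between-animal normal model
  with within-animal Poisson view counts;
* toy phantoms (uniform cube, layered slab, point-source box) whose exact
  field solutions are known in closed form, used as solver oracles.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phantom import TissueProperties, VoxelPhantom
from .solver import Contacts, analytic_point_source
from .stats import GroupSummary

__all__ = [
    "GroupSpec",
    "HierarchicalSpec",
    "generate_animal_counts",
    "generate_view_counts",
    "generate_study_views",
    "reported_group_summaries",
    "toy_phantom",
]


@dataclass(frozen=True)
class GroupSpec:
    """Target mean and between-animal SD for one experimental group."""

    name: str
    mu: float
    sd: float
    n_animals: int = 5

    def __post_init__(self) -> None:
        if self.mu < 0 or self.sd < 0:
            raise ValueError("mu and sd must be >= 0")
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")

    @classmethod
    def from_summary(cls, s: GroupSummary) -> "GroupSpec":
        return cls(name=s.group, mu=s.mean, sd=s.sd, n_animals=s.n)


@dataclass(frozen=True)
class HierarchicalSpec:
    """Sampling design: sections x views per animal, each view 200 x 200 um^2."""

    sections: int = 6
    views_per_section: int = 3
    view_area_um2: tuple[float, float] = (200.0, 200.0)

    def __post_init__(self) -> None:
        if self.sections * self.views_per_section < 1:
            raise ValueError("need at least one view")

    @property
    def n_views(self) -> int:
        return self.sections * self.views_per_section


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_truncated_normal(
    rng: np.random.Generator, mu: float, sd: float, size: int
) -> np.ndarray:
    """Normal(mu, sd^2) truncated at zero (counts cannot be negative)."""
    if sd == 0.0:
        return np.full(size, float(mu))
    a = (0.0 - mu) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=size, random_state=rng)


def generate_animal_counts(spec: GroupSpec, seed: int | np.random.Generator) -> np.ndarray:
    """Per-animal totals: truncated-normal draws rounded to integers."""
    rng = _rng(seed)
    draws = _draw_truncated_normal(rng, spec.mu, spec.sd, spec.n_animals)
    return np.rint(draws).astype(np.int64)


def generate_view_counts(
    gspec: GroupSpec,
    hspec: HierarchicalSpec,
    seed: int | np.random.Generator,
    region: str = "SVZ",
    marker: str = "Ki67",
) -> pd.DataFrame:
    """View-level counts for one group under the normal/Poisson hierarchy.

    Each animal gets a latent total theta ~ TruncNormal(mu, sd^2); every one
    of its ``sections x views`` counts is Poisson with rate
    ``theta / n_views``, so summing the views recovers the latent total in
    expectation.
    """
    rng = _rng(seed)
    thetas = _draw_truncated_normal(rng, gspec.mu, gspec.sd, gspec.n_animals)
    rows = []
    for i, theta in enumerate(thetas):
        rate = theta / hspec.n_views
        counts = rng.poisson(rate, size=hspec.n_views)
        idx = 0
        for section in range(1, hspec.sections + 1):
            for view in range(1, hspec.views_per_section + 1):
                rows.append(
                    {
                        "animal_id": f"{gspec.name}-{i + 1:02d}",
                        "group": gspec.name,
                        "region": region,
                        "marker": marker,
                        "section": section,
                        "view": view,
                        "count": int(counts[idx]),
                    }
                )
                idx += 1
    return pd.DataFrame(rows)


def generate_study_views(
    seed: int | np.random.Generator, hspec: HierarchicalSpec | None = None
) -> pd.DataFrame:
    """A full synthetic study: view counts for every group/region/marker cell,
    parameterized by the reported group summaries."""
    rng = _rng(seed)
    hspec = hspec or HierarchicalSpec()
    frames = []
    for s in reported_group_summaries():
        gspec = GroupSpec.from_summary(s)
        frames.append(generate_view_counts(gspec, hspec, rng, region=s.region, marker=s.marker))
    return pd.concat(frames, ignore_index=True)


def reported_group_summaries() -> list[GroupSummary]:
    """The 18 reported group summaries (3 groups x 3 markers x 2 regions, n=5)."""
    ref = importlib.resources.files("iacskit.data") / "reported_group_summaries.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return [
        GroupSummary(
            group=r.group,
            region=r.region,
            marker=r.marker,
            mean=float(r.mean),
            sem=float(r.sem),
            n=int(r.n),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Toy phantoms with closed-form field solutions


def _single_tissue_phantom(
    labels: np.ndarray, sigma: float, voxel_mm: float, name: str
) -> VoxelPhantom:
    return VoxelPhantom(
        labels=labels.astype(np.int16),
        voxel_size_um=voxel_mm * 1000.0,
        bregma_voxel=(0.0, 0.0, 0.0),
        properties={1: TissueProperties(1, name, sigma, 1.0)},
        provenance=f"toy phantom: {name}",
    )


def toy_phantom(kind: str, **params) -> tuple[VoxelPhantom, Contacts, dict]:
    """Build an analytically solvable phantom plus its contacts and oracle.

    Kinds
    -----
    ``uniform_cube``: homogeneous cube, opposite full faces as electrodes;
    expected uniform |J| = I/A and face-to-face drop I*L/(sigma*A).

    ``layered_slab``: two layers in series along the z axis; expected
    per-layer face-to-face drops ``I * t_i / (sigma_i * A)``.

    ``point_source_box``: homogeneous box, one source voxel at the centre,
    sink spread over the full outer boundary; near-field potential follows
    the monopole ``I / (4 pi sigma r)``.
    """
    if kind == "uniform_cube":
        sigma = params.get("sigma", 1.0)
        size_mm = params.get("size_mm", 10.0)
        voxel_mm = params.get("voxel_mm", 1.0)
        current = params.get("current_A", 1e-4)
        n = int(round(size_mm / voxel_mm))
        labels = np.ones((n, n, n), dtype=np.int16)
        phantom = _single_tissue_phantom(labels, sigma, voxel_mm, "uniform medium")
        top = np.array([(i, j, n - 1) for i in range(n) for j in range(n)], dtype=np.intp)
        bottom = np.array([(i, j, 0) for i in range(n) for j in range(n)], dtype=np.intp)
        contacts: Contacts = [("source", top), ("sink", bottom)]
        area_m2 = (size_mm * 1e-3) ** 2
        expected = {
            "magJ_A_per_m2": current / area_m2,
            "magE_V_per_m": current / area_m2 / sigma,
            "drop_V": current * (size_mm * 1e-3) / (sigma * area_m2),
        }
        return phantom, contacts, expected

    if kind == "layered_slab":
        sigmas = params.get("sigmas", (1.0, 0.5))
        thick_mm = params.get("thickness_mm", (1.0, 1.0))
        side_mm = params.get("side_mm", 1.0)
        voxel_mm = params.get("voxel_mm", 0.25)
        current = params.get("current_A", 1e-4)
        nx = int(round(side_mm / voxel_mm))
        nz_layers = [int(round(t / voxel_mm)) for t in thick_mm]
        nz = sum(nz_layers)
        labels = np.zeros((nx, nx, nz), dtype=np.int16)
        properties = {}
        z0 = 0
        for li, (s, nl) in enumerate(zip(sigmas, nz_layers), start=1):
            labels[:, :, z0 : z0 + nl] = li
            properties[li] = TissueProperties(li, f"layer {li}", s, 1.0)
            z0 += nl
        phantom = VoxelPhantom(
            labels=labels,
            voxel_size_um=voxel_mm * 1000.0,
            bregma_voxel=(0.0, 0.0, 0.0),
            properties=properties,
            provenance="toy phantom: layered slab",
        )
        bottom = np.array([(i, j, 0) for i in range(nx) for j in range(nx)], dtype=np.intp)
        top = np.array([(i, j, nz - 1) for i in range(nx) for j in range(nx)], dtype=np.intp)
        contacts = [("source", top), ("sink", bottom)]
        area_m2 = (side_mm * 1e-3) ** 2
        expected = {
            "layer_drops_V": tuple(
                current * (t * 1e-3) / (s * area_m2) for s, t in zip(sigmas, thick_mm)
            ),
            "magJ_A_per_m2": current / area_m2,
            "layer_boundaries_vox": tuple(np.cumsum([0] + nz_layers)),
        }
        return phantom, contacts, expected

    if kind == "point_source_box":
        sigma = params.get("sigma", 0.3)
        n = int(params.get("n_voxels", 61))
        voxel_mm = params.get("voxel_mm", 0.2)
        current = params.get("current_A", 1e-4)
        if n % 2 == 0:
            raise ValueError("point_source_box needs an odd grid for a central voxel")
        labels = np.ones((n, n, n), dtype=np.int16)
        phantom = _single_tissue_phantom(labels, sigma, voxel_mm, "uniform medium")
        c = n // 2
        source = np.array([(c, c, c)], dtype=np.intp)
        boundary = np.ones((n, n, n), dtype=bool)
        boundary[1:-1, 1:-1, 1:-1] = False
        sink = np.argwhere(boundary).astype(np.intp)
        contacts = [("source", source), ("sink", sink)]
        expected = {
            "phi_of_r": lambda r_m: analytic_point_source(sigma, current, r_m),
            "center_voxel": (c, c, c),
        }
        return phantom, contacts, expected

    raise ValueError(f"unknown toy phantom kind {kind!r}")
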
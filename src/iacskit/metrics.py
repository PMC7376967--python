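"""Region summaries of the field maps, montage ranking and the lesion bound.

Reported current densities above roughly 20 A/m^2 are associated with
tissue lesions; the safety check therefore takes the maximum |J| over brain
parenchyma only (gray and white matter, hippocampus, SVZ shell).  Dura and
CSF voxels are excluded, as is a one-voxel neighbourhood of the electrode
contacts where the uniform-flux contact model makes the discrete field
discretization-dominated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import Montage, PARENCHYMA_LABELS, Tissue, VoxelPhantom
from .solver import FieldMaps, assemble, fields_from_potential, solve

__all__ = [
    "SafetyReport",
    "roi_statistics",
    "compare_montages",
    "safety_check",
    "lesion_threshold_current",
    "LESION_THRESHOLD_A_PER_M2",
]

#: Lesion-inducing current density reported in the stimulation literature.
LESION_THRESHOLD_A_PER_M2 = 20.0

_CUBE_STRUCT = ndimage.generate_binary_structure(3, 3)  # 26-connectivity


def _label_name(phantom: VoxelPhantom, label: int) -> str:
    props = phantom.properties.get(int(label))
    return props.name if props is not None else str(int(label))


def roi_statistics(
    fields: FieldMaps,
    phantom: VoxelPhantom,
    regions: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Unweighted per-label mean and max of |E| and |J| over region voxels."""
    if fields.magE.shape != phantom.labels.shape:
        raise ValueError("field maps and phantom must share the voxel grid")
    if regions is None:
        regions = [int(l) for l in np.unique(phantom.labels) if l != 0]
    rows = []
    for label in regions:
        mask = phantom.labels == int(label)
        count = int(mask.sum())
        if count == 0:
            raise ValueError(f"region {_label_name(phantom, label)!r} (label {int(label)}) is empty")
        rows.append(
            {
                "label": int(label),
                "region": _label_name(phantom, label),
                "mean_magJ_A_per_m2": float(fields.magJ[mask].mean()),
                "max_magJ_A_per_m2": float(fields.magJ[mask].max()),
                "mean_magE_V_per_m": float(fields.magE[mask].mean()),
                "max_magE_V_per_m": float(fields.magE[mask].max()),
                "voxel_count": count,
            }
        )
    return pd.DataFrame(rows).set_index("label")


def compare_montages(
    phantom: VoxelPhantom,
    montages: Sequence[Montage] | Mapping[str, Montage],
    targets: Sequence[int] = (int(Tissue.HIPPOCAMPUS), int(Tissue.SVZ_SHELL)),
    tol: float = 1e-8,
    method: str = "cg",
) -> pd.DataFrame:
    """Solve each montage and rank them by deep-target coverage.

    The coverage score is the maximin rule: the minimum over target regions
    of the region's mean |E|, so a montage only scores well if it reaches
    *both* targets.  Ties break by the summed target mean |E|, then by input
    order.  Returns a tidy frame with one row per montage and target region.
    """
    if isinstance(montages, Mapping):
        items = list(montages.items())
    else:
        items = [(m.name, m) for m in montages]
    if not items:
        raise ValueError("at least one montage is required")

    per_montage = []
    for order, (name, montage) in enumerate(items):
        try:
            system = assemble(phantom, montage)
        except Exception as exc:  # noqa: BLE001 - re-raise with montage context
            raise type(exc)(f"montage {name!r}: {exc}") from exc
        potential = solve(system, tol=tol, method=method)
        fields = fields_from_potential(potential, phantom)
        stats = roi_statistics(fields, phantom, regions=list(targets))
        coverage = float(stats["mean_magE_V_per_m"].min())
        total = float(stats["mean_magE_V_per_m"].sum())
        per_montage.append((name, montage, stats, coverage, total, order))

    ranked = sorted(per_montage, key=lambda t: (-t[3], -t[4], t[5]))
    rank_of = {name: i + 1 for i, (name, *_rest) in enumerate(ranked)}

    rows = []
    for name, montage, stats, coverage, _total, _order in per_montage:
        for label, r in stats.iterrows():
            rows.append(
                {
                    "montage": name,
                    "region": r["region"],
                    "mean_magJ_A_per_m2": r["mean_magJ_A_per_m2"],
                    "max_magJ_A_per_m2": r["max_magJ_A_per_m2"],
                    "mean_magE_V_per_m": r["mean_magE_V_per_m"],
                    "max_magE_V_per_m": r["max_magE_V_per_m"],
                    "voxel_count": int(r["voxel_count"]),
                    "coverage_score_V_per_m": coverage,
                    "rank": rank_of[name],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SafetyReport:
    """Maximum parenchymal current density against the lesion bound."""

    max_parenchymal_magJ_A_per_m2: float
    argmax_voxel: tuple[int, int, int]
    threshold_A_per_m2: float
    passed: bool
    excluded_voxels: int

    def to_dict(self) -> dict:
        return {
            "max_parenchymal_magJ_A_per_m2": self.max_parenchymal_magJ_A_per_m2,
            "argmax_voxel": list(self.argmax_voxel),
            "threshold_A_per_m2": self.threshold_A_per_m2,
            "passed": self.passed,
            "excluded_voxels": self.excluded_voxels,
        }


def safety_check(
    fields: FieldMaps,
    phantom: VoxelPhantom,
    threshold: float = LESION_THRESHOLD_A_PER_M2,
    contact_voxels: np.ndarray | None = None,
) -> SafetyReport:
    """Check max |J| over parenchyma against the lesion threshold.

    ``contact_voxels`` (an (m, 3) index array, e.g. the concatenated output
    of ``place_montage``) and their one-voxel neighbourhood are excluded
    from the maximum.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    parenchyma = phantom.mask(PARENCHYMA_LABELS)
    excluded = 0
    if contact_voxels is not None and len(contact_voxels):
        contact_mask = np.zeros(phantom.labels.shape, dtype=bool)
        cv = np.asarray(contact_voxels)
        contact_mask[cv[:, 0], cv[:, 1], cv[:, 2]] = True
        contact_mask = ndimage.binary_dilation(contact_mask, structure=_CUBE_STRUCT)
        excluded = int((parenchyma & contact_mask).sum())
        parenchyma &= ~contact_mask
    if not parenchyma.any():
        raise ValueError("no parenchymal voxels to evaluate")
    magJ = np.where(parenchyma, fields.magJ, -np.inf)
    argmax = np.unravel_index(int(np.argmax(magJ)), magJ.shape)
    max_j = float(fields.magJ[argmax])
    return SafetyReport(
        max_parenchymal_magJ_A_per_m2=max_j,
        argmax_voxel=tuple(int(i) for i in argmax),
        threshold_A_per_m2=float(threshold),
        passed=bool(max_j < threshold),
        excluded_voxels=excluded,
    )


def lesion_threshold_current(
    max_parenchymal_magJ: float,
    current_A: float,
    threshold: float = LESION_THRESHOLD_A_PER_M2,
) -> float:
    """Injected current (A) at which the parenchymal maximum reaches the bound.

    The solve is linear in the injected current, so the limit is
    ``I0 * threshold / max|J|(I0)``.
    """
    if max_parenchymal_magJ <= 0:
        raise ValueError("max parenchymal |J| must be > 0 to extrapolate")
    if current_A <= 0 or threshold <= 0:
        raise ValueError("current and threshold must be > 0")
    return current_A * threshold / max_parenchymal_magJ
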
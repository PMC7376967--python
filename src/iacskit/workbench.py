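"""Pipeline orchestration: field simulation runs, statistics runs, waveform QC.

The field pipeline builds (or loads) a phantom, places one or more
montages, solves the current-flow problem and writes potential / |E| / |J|
volumes, ROI tables, a montage ranking and a safety report into an output
directory together with a run log carrying the package version and a hash
of the configuration.  The statistics pipeline runs the cell-count
analysis either on a user CSV or on the embedded reported summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import signal as spsig

from . import __version__
from .metrics import (
    LESION_THRESHOLD_A_PER_M2,
    compare_montages,
    roi_statistics,
    safety_check,
)
from .phantom import (
    Montage,
    PhantomSpec,
    Tissue,
    VoxelPhantom,
    build_phantom,
    candidate_montages,
    load_phantom_nifti,
    optimized_montage,
    place_montage,
    save_phantom_nifti,
)
from .solver import assemble_from_contacts, check_quasistatic, fields_from_potential, solve
from .stats import (
    GROUPS,
    GroupSummary,
    aggregate_views,
    anova_from_summary,
    fold_change,
    reported_fold_changes,
    reproduce_reported_table,
    summarize_counts,
    tukey_hsd,
)

__all__ = [
    "RunConfig",
    "Waveform",
    "run_field_pipeline",
    "run_stats_pipeline",
    "generate_stim_waveform",
    "psd_peak",
]

log = logging.getLogger("iacskit")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Configuration of a field-simulation run."""

    out_dir: Path
    resolution_um: float = 200.0
    phantom_path: Path | None = None          # optional NIfTI override
    montages: dict[str, Montage] = field(default_factory=dict)
    solver_tol: float = 1e-8
    solver_maxiter: int | None = None
    target_labels: tuple[int, ...] = (int(Tissue.HIPPOCAMPUS), int(Tissue.SVZ_SHELL))
    safety_threshold: float = LESION_THRESHOLD_A_PER_M2
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.safety_threshold <= 0:
            raise ConfigError("safety threshold must be > 0")
        if self.phantom_path is not None and not Path(self.phantom_path).exists():
            raise ConfigError(f"phantom path does not exist: {self.phantom_path}")
        if not self.montages:
            self.montages = {"optimized": optimized_montage()}

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        montages = {}
        for m in raw.get("montages", []):
            electrodes = tuple(
                _electrode_from_dict(e) for e in m.get("electrodes", [])
            )
            montages[m["name"]] = Montage(
                electrodes=electrodes,
                current_amplitude_A=float(m.get("current_amplitude_A", 1e-4)),
                frequency_hz=float(m.get("frequency_hz", 40.0)),
                name=m["name"],
            )
        return cls(
            out_dir=Path(out_dir or raw.get("out_dir", "iacskit_out")),
            resolution_um=float(raw.get("resolution_um", 200.0)),
            phantom_path=Path(raw["phantom_path"]) if raw.get("phantom_path") else None,
            montages=montages,
            solver_tol=float(raw.get("solver_tol", 1e-8)),
            solver_maxiter=raw.get("solver_maxiter"),
            safety_threshold=float(raw.get("safety_threshold", LESION_THRESHOLD_A_PER_M2)),
            seed=int(raw.get("seed", 0)),
        )

    def config_hash(self) -> str:
        payload = {
            "resolution_um": self.resolution_um,
            "phantom_path": str(self.phantom_path) if self.phantom_path else None,
            "montages": {
                name: {
                    "current_A": m.current_amplitude_A,
                    "frequency_hz": m.frequency_hz,
                    "electrodes": [
                        (e.center_ap_mm, e.center_ml_mm, e.contact_diameter_mm, e.role)
                        for e in m.electrodes
                    ],
                }
                for name, m in sorted(self.montages.items())
            },
            "solver_tol": self.solver_tol,
            "safety_threshold": self.safety_threshold,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _electrode_from_dict(e: dict):
    from .phantom import Electrode

    return Electrode(
        center_ap_mm=float(e["ap_mm"]),
        center_ml_mm=float(e["ml_mm"]),
        contact_diameter_mm=float(e.get("contact_diameter_mm", 1.5)),
        role=e.get("role", "source"),
    )


def _save_volume(data: np.ndarray, phantom: VoxelPhantom, path: Path) -> None:
    h = phantom.voxel_size_mm
    img = nib.Nifti1Image(data.astype(np.float32), np.diag([h, h, h, 1.0]))
    nib.save(img, str(path))


def run_field_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full field workflow; returns the artifact manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if config.phantom_path is not None:
        phantom = load_phantom_nifti(config.phantom_path)
    else:
        phantom = build_phantom(PhantomSpec.default(config.resolution_um))
    phantom_path = out / "phantom_labels.nii"
    save_phantom_nifti(phantom, phantom_path)
    artifacts["phantom"] = phantom_path

    # Reference montage = first by insertion order; it provides the volumes
    # and the safety report, while every montage enters the ranking.
    names = list(config.montages)
    ref_name = names[0]
    ref_montage = config.montages[ref_name]
    placed = place_montage(phantom, ref_montage)
    contacts = [(e.role, v) for e, v in placed.items()]
    system = assemble_from_contacts(phantom, contacts, ref_montage.current_amplitude_A)
    potential = solve(system, tol=config.solver_tol, maxiter=config.solver_maxiter)
    fields = fields_from_potential(potential, phantom)

    for name, data in (("phi_V", potential.phi), ("magE_V_per_m", fields.magE), ("magJ_A_per_m2", fields.magJ)):
        p = out / f"{name}.nii"
        _save_volume(data, phantom, p)
        artifacts[name] = p

    roi = roi_statistics(fields, phantom)
    roi_path = out / "roi_statistics.csv"
    roi.to_csv(roi_path)
    artifacts["roi_csv"] = roi_path

    ranking = compare_montages(
        phantom,
        config.montages,
        targets=config.target_labels,
        tol=config.solver_tol,
    )
    ranking_path = out / "montage_ranking.csv"
    ranking.to_csv(ranking_path, index=False)
    artifacts["ranking_csv"] = ranking_path

    all_contacts = np.concatenate([v for _, v in contacts])
    report = safety_check(fields, phantom, config.safety_threshold, contact_voxels=all_contacts)
    safety_path = out / "safety_report.json"
    safety_path.write_text(json.dumps(report.to_dict(), indent=2))
    artifacts["safety_json"] = safety_path

    qs = check_quasistatic(phantom.properties, ref_montage.frequency_hz)
    qs_path = out / "quasistatic_report.csv"
    qs.to_csv(qs_path, index=False)
    artifacts["quasistatic_csv"] = qs_path

    log_path = out / "run_log.json"
    log_path.write_text(
        json.dumps(
            {
                "iacskit_version": __version__,
                "config_hash": config.config_hash(),
                "reference_montage": ref_name,
                "solver": {
                    "iterations": potential.iterations,
                    "relative_residual": potential.residual,
                    "converged": potential.converged,
                },
                "grid_shape": list(phantom.labels.shape),
                "voxel_size_um": phantom.voxel_size_um,
            },
            indent=2,
        )
    )
    artifacts["log"] = log_path
    return artifacts


def run_stats_pipeline(
    source: str | Path | pd.DataFrame, out_dir: str | Path | None = None
) -> dict[str, pd.DataFrame]:
    """Run the cell-count analysis.

    ``source`` is either the string ``"fixture"`` (use the embedded reported
    summaries), a CSV path, or a DataFrame.  CSV/DataFrame input may be
    view-level (``animal_id,group,region,marker,section,view,count``) or
    animal-level (``animal_id,group,region,marker,value``).
    """
    from .synth import reported_group_summaries

    if isinstance(source, str) and source == "fixture":
        summaries = reported_group_summaries()
    else:
        df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
        if len(df) == 0:
            raise ValueError("input table is empty")
        if "count" in df.columns:
            df = aggregate_views(df)
        if "value" not in df.columns:
            raise ValueError(
                "input must carry either view-level 'count' or animal-level 'value' columns; "
                f"got {list(df.columns)}"
            )
        summaries = summarize_counts(df)

    by_cell: dict[tuple[str, str], list[GroupSummary]] = {}
    for s in summaries:
        by_cell.setdefault((s.marker, s.region), []).append(s)

    anova_rows, tukey_rows, fold_rows = [], [], []
    for (marker, region), cell in sorted(by_cell.items()):
        res = anova_from_summary(cell)
        anova_rows.append(
            {
                "marker": marker,
                "region": region,
                "F": res.F,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p": res.p,
                "ms_between": res.ms_between,
                "ms_within": res.ms_within,
            }
        )
        tk = tukey_hsd(summaries=cell)
        for pair in tk.pairs:
            tukey_rows.append(
                {
                    "marker": marker,
                    "region": region,
                    "group_a": pair.group_a,
                    "group_b": pair.group_b,
                    "mean_difference": pair.mean_difference,
                    "q": pair.q,
                    "p": pair.p,
                }
            )
        lookup = {s.group: s for s in cell}
        if marker in ("Ki67", "DCX") and {"5xFAD", "5xFAD+iACS"} <= set(lookup):
            fc = fold_change(lookup["5xFAD+iACS"], lookup["5xFAD"])
            fold_rows.append(
                {
                    "marker": marker,
                    "region": region,
                    "numerator_group": fc.numerator_group,
                    "denominator_group": fc.denominator_group,
                    "ratio": fc.ratio,
                    "ratio_rounded": fc.ratio_rounded,
                }
            )

    result = {
        "anova": pd.DataFrame(anova_rows),
        "tukey": pd.DataFrame(tukey_rows),
        "fold_changes": pd.DataFrame(fold_rows),
    }
    if isinstance(source, str) and source == "fixture":
        result["reported_comparison"] = reproduce_reported_table()
        result["reported_fold_changes"] = reported_fold_changes()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in result.items():
            frame.to_csv(out / f"{name}.csv", index=False)
    return result


@dataclass
class Waveform:
    """A commanded stimulation waveform."""

    samples: np.ndarray        # A
    sampling_rate_hz: float
    nominal_frequency_hz: float
    amplitude_A: float


def generate_stim_waveform(
    frequency_hz: float,
    amplitude_A: float,
    sampling_rate_hz: float,
    duration_s: float,
) -> Waveform:
    """Pure zero-mean sine at the stimulation frequency (no DC component)."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be > 0")
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if sampling_rate_hz <= 2.0 * frequency_hz:
        raise ValueError(
            f"sampling rate {sampling_rate_hz} Hz violates Nyquist for {frequency_hz} Hz"
        )
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    samples = amplitude_A * np.sin(2.0 * np.pi * frequency_hz * t)
    return Waveform(samples, sampling_rate_hz, frequency_hz, amplitude_A)


def psd_peak(waveform: Waveform) -> float:
    """Frequency (Hz) of the maximum of the periodogram over the full record."""
    n = waveform.samples.size
    duration = n / waveform.sampling_rate_hz
    if waveform.nominal_frequency_hz > 0 and duration * waveform.nominal_frequency_hz < 2.0:
        raise ValueError("record too short: need at least two cycles for a PSD peak")
    freqs, pxx = spsig.periodogram(waveform.samples, fs=waveform.sampling_rate_hz)
    return float(freqs[int(np.argmax(pxx))])
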
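"""End-to-end analysis runs: normalize -> arrange -> metrics -> LSA -> correlate.

A run is fully described by a :class:`RunConfig`; its single seed fans out
to per-stage seeds keyed by stage name, so each stage is reproducible in
isolation and a repeated run is byte-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arrange, normalize, project, robustness, stuartlandau
from .io import Connectome, RegionPartition, DEFAULT_BANDS

__all__ = ["RunConfig", "run_subject_analysis", "run_cohort_summary", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    return (seed ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Configuration of a subject or cohort analysis run."""

    velocity_mps: float = 5.0
    frequencies_hz: list[float] = field(default_factory=lambda: [0.0, 10.0, 20.0])
    arrangement_policy: str = "maximize"
    regime: str = "critical"
    G: float = 1.0
    D: float = 0.0
    seed: int = 0
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def run_subject_analysis(
    c: Connectome, cfg: RunConfig
) -> dict[str, pd.DataFrame]:
    """Single-subject pipeline; returns a bundle of tables.

    ``metrics_<f>`` tables hold per-node label, S, C, S/C and arrangement
    sign per frequency; ``lsa`` the eigen-report at criticality per
    frequency; ``correlation`` the LSA-power vs metric correlations.
    """
    bundle: dict[str, pd.DataFrame] = {}
    labels = list(c.labels) or [f"region_{i:03d}" for i in range(c.n_regions)]
    lsa_rows = []
    corr_frames = []
    for f in cfg.frequencies_hz:
        nc = normalize.wave_couplings(c, f, cfg.velocity_mps)
        seed_f = stage_seed(cfg.seed, f"arrange-{f}")
        if cfg.arrangement_policy == "maximize":
            arr = arrange.maximize_spectral_strength(nc, seed=seed_f)
        elif cfg.arrangement_policy == "eigenvector":
            arr = arrange.eigenvector_arrangement(nc)
        else:
            raise ValueError(
                f"unknown arrangement_policy {cfg.arrangement_policy!r}"
            )
        m = normalize.metrics_at(nc, arr)
        bundle[f"metrics_{f:g}"] = pd.DataFrame(
            dict(
                label=labels,
                S=m.strength,
                C=m.capacity,
                ratio=m.ratio,
                sign=arr.signs,
            )
        )
        omega = nc.omega if f > 0 else 2.0 * np.pi * 1.0
        r_crit = stuartlandau.find_critical_r(nc, omega)
        lsa = stuartlandau.lsa_normalized(nc, r_crit, omega)
        lsa_rows.append(
            dict(
                frequency_hz=f,
                r_critical=r_crit,
                max_real_part=lsa.max_real_part,
                velocity_mps=cfg.velocity_mps,
            )
        )
        power = stuartlandau.lsa_power_pattern(lsa)
        eig_arr = arrange.arrangement_from_signs(
            lsa.leading_eigenvector, provenance="eigenvector"
        )
        metrics_dict = {
            "S_conn": m.strength,
            "S_eig": normalize.spectral_strength(nc, eig_arr),
            "C_signed": normalize.signs_of(eig_arr) * m.capacity,
            "C0": normalize.particle_strength(c, eig_arr),
        }
        corr = stuartlandau.correlate_metrics_with_power(
            power, metrics_dict, arrangement=eig_arr, null_key="C0"
        )
        corr = corr.assign(frequency_hz=f)
        corr_frames.append(corr.reset_index())
    bundle["lsa"] = pd.DataFrame(lsa_rows)
    bundle["correlation"] = pd.concat(corr_frames, ignore_index=True)
    return bundle


def run_cohort_summary(
    subjects: list[Connectome],
    cfg: RunConfig,
    partition: RegionPartition | None = None,
) -> dict[str, pd.DataFrame]:
    """Cohort pipeline: per-subject metrics, sign-aligned averages, projections."""
    if len(subjects) < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    n = subjects[0].n_regions
    if any(s.n_regions != n for s in subjects):
        raise ValueError("subjects have heterogeneous region counts")

    per_freq_strengths: dict[float, list[np.ndarray]] = {
        f: [] for f in cfg.frequencies_hz
    }
    per_freq_capacity: dict[float, list[np.ndarray]] = {
        f: [] for f in cfg.frequencies_hz
    }
    for k, c in enumerate(subjects):
        for f in cfg.frequencies_hz:
            nc = normalize.wave_couplings(c, f, cfg.velocity_mps)
            arr = arrange.maximize_spectral_strength(
                nc, seed=stage_seed(cfg.seed, f"cohort-{k}-{f}")
            )
            per_freq_strengths[f].append(normalize.spectral_strength(nc, arr))
            per_freq_capacity[f].append(normalize.spectral_capacity(nc))

    mean_rows, disp_rows = {}, {}
    for f in cfg.frequencies_hz:
        avg = project.cross_subject_average(per_freq_strengths[f])
        mean_rows[f] = avg["mean"]
        disp_rows[f] = avg["dispersion"]
    strength_mean = pd.DataFrame(mean_rows).T  # freq x node
    strength_std = pd.DataFrame(disp_rows).T
    capacity_mean = pd.DataFrame(
        {f: np.mean(per_freq_capacity[f], axis=0) for f in cfg.frequencies_hz}
    ).T

    bundle = {
        "strength_mean": strength_mean,
        "strength_std": strength_std,
        "capacity_mean": capacity_mean,
    }
    if partition is not None:
        bands = {
            name: (lo, hi)
            for name, (lo, hi) in (partition.band_table or cfg.bands).items()
        }
        try:
            banded = project.band_average(strength_mean, bands)
        except ValueError:
            banded = None  # frequency grid does not cover the bands
        if banded is not None:
            rows = []
            for band in banded.index:
                proj = project.project_to_partition(
                    banded.loc[band].to_numpy(), partition
                )
                for sub, val in proj.items():
                    rows.append(dict(subnetwork=sub, band=band, value=val))
            bundle["band_projection"] = pd.DataFrame(rows)
    return bundle
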
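"""Projection of per-node spectral metrics onto bands, lobes/RSNs, cohorts.

Per-node values are averaged per subnetwork (per number of member regions),
per frequency band (mean over grid frequencies inside [f_low, f_high)), and
across subjects.  Cross-subject averaging of signed spectral strengths first
aligns the global sign of each subject so that the region with the largest
cohort-mean magnitude is positive — an anti-phase arrangement is only
defined up to a global flip, so without alignment the mean would be
meaningless.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import RegionPartition

__all__ = [
    "project_to_partition",
    "band_average",
    "cross_subject_average",
]


def project_to_partition(
    values: np.ndarray, partition: RegionPartition
) -> pd.Series:
    """Mean of member-region values per subnetwork label."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(partition.membership):
        raise ValueError(
            f"{values.shape[0]} values for {len(partition.membership)} regions"
        )
    out = {}
    for label in partition.subnetworks:
        members = partition.members(label)
        if not members:
            raise ValueError(f"subnetwork {label!r} has no member regions")
        out[label] = float(values[members].mean())
    return pd.Series(out, name="mean")


def band_average(
    spectrum: pd.DataFrame,
    bands: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Average a (frequency x node) spectrum over frequency bands.

    ``spectrum`` is indexed by frequency in Hz; each band averages the rows
    with f_low <= f < f_high.  A band covering no grid frequency is an
    error.
    """
    freqs = np.asarray(spectrum.index, dtype=float)
    rows = {}
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs < hi)
        if not mask.any():
            raise ValueError(
                f"band {name!r} [{lo}, {hi}) covers no frequency of the grid"
            )
        rows[name] = spectrum.iloc[mask].mean(axis=0)
    return pd.DataFrame(rows).T


def cross_subject_average(
    signed_strengths: list[np.ndarray],
) -> dict[str, np.ndarray]:
    """Sign-consistent cohort mean and dispersion of signed node metrics.

    Each subject's vector is globally flipped so that the region with the
    largest cohort-mean magnitude is positive, then the per-region mean and
    standard deviation are taken.  Regions whose arrangement varies across
    subjects end up with |mean| below the mean magnitude.
    """
    if not signed_strengths:
        raise ValueError("need at least one subject")
    mats = [np.asarray(v, dtype=float) for v in signed_strengths]
    n = mats[0].shape[0]
    if any(m.shape != (n,) for m in mats):
        raise ValueError("subjects have mismatched region sets")
    stack = np.stack(mats)
    ref = int(np.argmax(np.abs(stack).mean(axis=0)))
    flips = np.where(stack[:, ref] < 0, -1.0, 1.0)
    aligned = stack * flips[:, None]
    return {
        "mean": aligned.mean(axis=0),
        "dispersion": aligned.std(axis=0),
        "aligned": aligned,
    }
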
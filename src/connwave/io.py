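"""Reading, writing and synthesis of structural connectomes.

A structural connectome is a pair of symmetric matrices over ``n`` cortical
regions: coupling *weights* (streamline counts, or their natural logarithms)
and tract *lengths* in millimetres.  Files are plain whitespace-separated
numeric matrices (one row per region), the de-facto exchange format used by
The Virtual Brain and similar tools (``weights.txt`` / ``tract_lengths.txt``).

The synthetic generator emulates diffusion-tractography connectomes:
symmetric non-negative heavy-tailed weights, zero diagonal, lengths in a
physiologically plausible range, and optional homotopic (mirror-hemisphere)
symmetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Connectome",
    "RegionPartition",
    "read_connectome",
    "write_connectome",
    "generate_synthetic_connectome",
    "load_partition_table",
    "DEFAULT_BANDS",
]

SYMMETRY_TOL = 1e-9

#: Default EEG frequency bands in Hz (artifact defaults, user-overridable).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 80.0),
}

# file names accepted (TVB-style aliases first)
_WEIGHT_ALIASES = ("weights.txt", "weights.tsv")
_LENGTH_ALIASES = ("tract_lengths.txt", "lengths.txt", "tract_lengths.tsv")
_LABEL_ALIASES = ("labels.txt", "region_labels.txt")


def _check_symmetric(m: np.ndarray, name: str) -> None:
    dev = np.abs(m - m.T)
    if dev.max(initial=0.0) > SYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(dev), dev.shape)
        raise ValueError(
            f"{name} matrix is asymmetric: max deviation {dev[i, j]:.3g} at "
            f"entry ({i}, {j}) — ({m[i, j]!r} vs {m[j, i]!r})"
        )


@dataclass(frozen=True)
class Connectome:
    """Structural connectome: symmetric weights and tract lengths.

    Attributes
    ----------
    weights : (n, n) ndarray
        Non-negative symmetric coupling weights with zero diagonal.
        Streamline counts (``weight_mode='raw'``) or their natural
        logarithms (``weight_mode='log'``).
    lengths : (n, n) ndarray
        Symmetric tract lengths in mm; positive wherever a link exists.
    labels : tuple of str
        Region names, one per node.
    """

    weights: np.ndarray
    lengths: np.ndarray
    labels: tuple[str, ...] = ()
    weight_mode: str = "raw"
    subject_id: str | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        l = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "lengths", l)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if l.shape != w.shape:
            raise ValueError(
                f"lengths shape {l.shape} does not match weights shape {w.shape}"
            )
        if self.weight_mode not in ("raw", "log"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if (l < 0).any():
            raise ValueError("lengths must be non-negative")
        _check_symmetric(w, "weights")
        _check_symmetric(l, "lengths")
        if np.abs(np.diag(w)).max(initial=0.0) > 0 or np.abs(np.diag(l)).max(initial=0.0) > 0:
            raise ValueError("self-links are forbidden: diagonals must be zero")
        if ((w > 0) & (l <= 0)).any():
            raise ValueError("every link with positive weight needs a positive length")
        if self.labels and len(self.labels) != w.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {w.shape[0]} regions"
            )
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def n_links(self) -> int:
        """Number of undirected links (nonzero upper-triangle weights)."""
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def with_weights(self, weights: np.ndarray, weight_mode: str | None = None) -> "Connectome":
        return replace(self, weights=weights, weight_mode=weight_mode or self.weight_mode)

    def with_lengths(self, lengths: np.ndarray) -> "Connectome":
        return replace(self, lengths=lengths)


@dataclass(frozen=True)
class RegionPartition:
    """Assignment of regions to subnetworks (lobes or resting-state networks).

    ``membership`` maps region index -> subnetwork label; ``band_table`` maps
    band name -> (f_low, f_high) in Hz.
    """

    membership: Mapping[int, str]
    band_table: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.band_table.items():
            if not hi > lo:
                raise ValueError(f"band {name!r} is empty: [{lo}, {hi})")

    @property
    def subnetworks(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.membership.values())))

    def members(self, label: str) -> list[int]:
        return [i for i, lab in self.membership.items() if lab == label]


def _log_transform(counts: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """ln of streamline counts, floored so weights stay non-negative.

    Zero counts (absent links) stay zero; counts >= 1 map to max(ln c, floor);
    fractional counts in (0, 1) are clipped to the floor so that the sign of a
    wave coupling can only come from the delay term, never from the log.
    """
    out = np.zeros_like(counts, dtype=float)
    nz = counts > 0
    out[nz] = np.maximum(np.log(np.maximum(counts[nz], 1.0)), floor)
    return out


def _find_alias(dir_path: Path, aliases: Sequence[str]) -> Path | None:
    for name in aliases:
        p = dir_path / name
        if p.exists():
            return p
    return None


def read_connectome(
    weights_path: str | Path,
    lengths_path: str | Path,
    labels_path: str | Path | None = None,
    weight_mode: str = "raw",
    subject_id: str | None = None,
    log_floor: float = 0.0,
) -> Connectome:
    """Read a connectome from plain-text matrix files.

    Parameters
    ----------
    weight_mode : {'raw', 'log', 'log_transform'}
        ``raw`` and ``log`` record how the stored weights are to be
        interpreted; ``log_transform`` reads raw streamline counts and
        replaces each nonzero count ``c`` by ``max(ln c, log_floor)``
        (zero counts stay zero), yielding a log-mode connectome.
    """
    weights_path, lengths_path = Path(weights_path), Path(lengths_path)
    for p in (weights_path, lengths_path):
        if not p.exists():
            raise FileNotFoundError(f"connectome file not found: {p}")
    w = np.loadtxt(weights_path, ndmin=2)
    l = np.loadtxt(lengths_path, ndmin=2)
    if w.shape != l.shape:
        raise ValueError(
            f"shape mismatch: weights {w.shape} vs lengths {l.shape}"
        )
    labels: tuple[str, ...] = ()
    if labels_path is not None:
        labels = tuple(
            line.strip()
            for line in Path(labels_path).read_text().splitlines()
            if line.strip()
        )
    if weight_mode == "log_transform":
        w = _log_transform(w, floor=log_floor)
        mode = "log"
    elif weight_mode in ("raw", "log"):
        mode = weight_mode
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    return Connectome(w, l, labels=labels, weight_mode=mode, subject_id=subject_id)


def read_connectome_dir(dir_path: str | Path, weight_mode: str = "raw") -> Connectome:
    """Read a connectome from a directory using TVB-style file names."""
    dir_path = Path(dir_path)
    wp = _find_alias(dir_path, _WEIGHT_ALIASES)
    lp = _find_alias(dir_path, _LENGTH_ALIASES)
    if wp is None or lp is None:
        raise FileNotFoundError(
            f"no weights/tract_lengths matrices found in {dir_path}"
        )
    return read_connectome(
        wp, lp, _find_alias(dir_path, _LABEL_ALIASES), weight_mode=weight_mode,
        subject_id=dir_path.name,
    )


def write_connectome(c: Connectome, dir_path: str | Path) -> list[Path]:
    """Write ``weights.txt``, ``tract_lengths.txt`` (and ``labels.txt``).

    Uses full repr precision so that read∘write is an identity.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    written = []
    for name, mat in (("weights.txt", c.weights), ("tract_lengths.txt", c.lengths)):
        p = dir_path / name
        np.savetxt(p, mat, fmt="%.17g", delimiter="\t")
        written.append(p)
    if c.labels:
        p = dir_path / "labels.txt"
        p.write_text("\n".join(c.labels) + "\n")
        written.append(p)
    return written


def _mirror_orbit(i: int, j: int, half: int) -> frozenset[tuple[int, int]]:
    """Orbit of an undirected edge under the homotopic mirror i <-> i+half."""
    def mirror(k: int) -> int:
        return k + half if k < half else k - half

    a, b = sorted((i, j))
    ma, mb = sorted((mirror(i), mirror(j)))
    return frozenset({(a, b), (ma, mb)})


def generate_synthetic_connectome(
    n_regions: int,
    density: float = 0.3,
    seed: int = 0,
    homotopic: bool = False,
    length_range: tuple[float, float] = (5.0, 170.0),
    weight_distribution: str = "lognormal",
    subject_id: str | None = None,
) -> Connectome:
    """Generate a random connectome emulating tractography-derived matrices.

    Weights are heavy-tailed positive streamline-like counts (lognormal by
    default), lengths uniform in ``length_range`` mm on existing links, the
    diagonal is zero and both matrices are exactly symmetric.  With
    ``homotopic=True``, ``n_regions`` must be even; node ``i`` is paired with
    node ``i + n/2`` and the edge set, weights and lengths are invariant
    under that mirror, emulating inter-hemispheric symmetry.

    Deterministic for a fixed seed.  The realized number of links is within
    one edge of ``density * n(n-1)/2``.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    if homotopic and n_regions % 2:
        raise ValueError("homotopic pairing needs an even number of regions")
    lo, hi = length_range
    if not (0 < lo <= hi):
        raise ValueError("length_range must be positive and ordered")

    rng = np.random.default_rng(seed)
    n = n_regions
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    target = int(round(density * len(all_pairs)))

    chosen: list[tuple[int, int]] = []
    if homotopic:
        half = n // 2
        orbits = list({_mirror_orbit(i, j, half) for (i, j) in all_pairs})
        orbits.sort(key=lambda o: sorted(o))
        order = rng.permutation(len(orbits))
        for k in order:
            if len(chosen) >= target:
                break
            chosen.extend(sorted(orbits[k]))
    else:
        idx = rng.choice(len(all_pairs), size=target, replace=False)
        chosen = [all_pairs[k] for k in sorted(idx)]

    w = np.zeros((n, n))
    l = np.zeros((n, n))

    def draw_weight() -> float:
        if weight_distribution == "lognormal":
            # median ~ e^2 ≈ 7.4 streamlines, heavy right tail
            return float(rng.lognormal(mean=2.0, sigma=1.0))
        if weight_distribution == "uniform":
            return float(rng.uniform(0.5, 1.5))
        raise ValueError(f"unknown weight_distribution {weight_distribution!r}")

    if homotopic:
        half = n // 2
        seen: set[frozenset[tuple[int, int]]] = set()
        for (i, j) in chosen:
            orbit = _mirror_orbit(i, j, half)
            if orbit in seen:
                continue
            seen.add(orbit)
            wij = draw_weight()
            lij = float(rng.uniform(lo, hi))
            for (a, b) in orbit:
                w[a, b] = w[b, a] = wij
                l[a, b] = l[b, a] = lij
    else:
        for (i, j) in chosen:
            w[i, j] = w[j, i] = draw_weight()
            l[i, j] = l[j, i] = float(rng.uniform(lo, hi))

    n_comp, _ = connected_components((w > 0).astype(int), directed=False)
    if n_comp > 1:
        warnings.warn(
            f"synthetic connectome is disconnected ({n_comp} components) at "
            f"density {density}",
            stacklevel=2,
        )
    labels = tuple(f"region_{i:03d}" for i in range(n))
    return Connectome(w, l, labels=labels, weight_mode="raw",
                      subject_id=subject_id or f"synthetic-{seed}")


def load_partition_table(
    path: str | Path,
    labels: Sequence[str],
    band_path: str | Path | None = None,
) -> RegionPartition:
    """Load a two-column region-label -> subnetwork-label TSV.

    Every connectome region must appear exactly once; unknown region labels
    in the table are rejected.  ``band_path`` optionally overrides the
    default EEG band table with rows ``name  f_low  f_high``.
    """
    table = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                        names=["region", "subnetwork"], dtype=str)
    mapping_by_label = dict(zip(table["region"], table["subnetwork"]))
    unknown = sorted(set(table["region"]) - set(labels))
    if unknown:
        raise ValueError(f"partition table names unknown regions: {unknown}")
    missing = [lab for lab in labels if lab not in mapping_by_label]
    if missing:
        raise ValueError(f"regions missing from partition table: {missing}")
    membership = {i: mapping_by_label[lab] for i, lab in enumerate(labels)}

    bands = dict(DEFAULT_BANDS)
    if band_path is not None:
        bt = pd.read_csv(band_path, sep=r"\s+", header=None, comment="#",
                         names=["band", "f_low", "f_high"])
        bands = {
            str(r.band): (float(r.f_low), float(r.f_high)) for r in bt.itertuples()
        }
    return RegionPartition(membership=membership, band_table=bands)
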
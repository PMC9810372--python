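"""Frequency-dependent normalization of the connectome.

With finite conduction velocity ``v`` every link carries a delay
``tau_ij = l_ij / v``.  For oscillations synchronized at frequency ``f``
(angular ``Omega = 2*pi*f``) the effective ("wave") coupling of a link is

    w_ij^(f) = w_ij * cos(Omega * tau_ij),

so a link can even turn inhibitory for the synchronization at a given
frequency.  From the signed wave couplings two node metrics follow:

* spectral strength ``S_i = sum_{j in Q_i} w_ij^(f) - sum_{j not in Q_i}
  w_ij^(f)`` — the effective hubness of node ``i`` under an in-/anti-phase
  arrangement whose cluster ``Q_i`` holds the nodes in phase with ``i``;
* spectral capacity ``C_i = sum_j |w_ij^(f)|`` — the upper bound of the
  node's synchronizability, independent of the arrangement.

Both reduce to the topological node strength ``sum_j w_ij`` in the particle
limit ``f -> 0`` or ``v -> inf`` (zero effective delays).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import Connectome

__all__ = [
    "NormalizedConnectome",
    "SpectralMetrics",
    "delays_from_lengths",
    "wave_couplings",
    "spectral_strength",
    "spectral_capacity",
    "particle_strength",
    "metric_spectrum",
    "signs_of",
]

DEFAULT_VELOCITY_MPS = 5.0  # homogeneous conduction velocity, m/s


def signs_of(arrangement) -> np.ndarray:
    """Extract a ±1 sign vector from an Arrangement or a plain array."""
    signs = np.asarray(getattr(arrangement, "signs", arrangement), dtype=float)
    if signs.ndim != 1 or not np.all(np.abs(signs) == 1):
        raise ValueError("arrangement signs must be a 1-d vector over {-1, +1}")
    return signs


@dataclass(frozen=True)
class NormalizedConnectome:
    """A connectome normalized for synchronization at one frequency.

    Holds the base connectome, the working frequency (Hz), the conduction
    velocity (m/s, may be ``inf``), the delay matrix (s) and the signed
    wave-coupling matrix ``w^(f)``.
    """

    base: Connectome
    frequency_hz: float
    velocity_mps: float
    delays: np.ndarray
    wave_weights: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.base.n_regions

    @property
    def omega(self) -> float:
        """Angular frequency Omega = 2*pi*f in rad/s."""
        return 2.0 * math.pi * self.frequency_hz


@dataclass(frozen=True)
class SpectralMetrics:
    """Per-node spectral strength/capacity at one frequency."""

    frequency_hz: float
    strength: np.ndarray
    capacity: np.ndarray
    ratio: np.ndarray  # S/C, defined 0 where C == 0
    arrangement: object  # Arrangement used for the strengths


def delays_from_lengths(c: Connectome, velocity_mps: float) -> np.ndarray:
    """Delay matrix tau_ij = (l_ij / 1000) / v in seconds.

    ``velocity_mps=inf`` is the particle limit and yields zero delays.
    """
    if not velocity_mps > 0:
        raise ValueError(f"conduction velocity must be positive, got {velocity_mps}")
    if math.isinf(velocity_mps):
        return np.zeros_like(c.lengths)
    return (c.lengths / 1000.0) / velocity_mps


def wave_couplings(
    c: Connectome, frequency_hz: float, velocity_mps: float = DEFAULT_VELOCITY_MPS
) -> NormalizedConnectome:
    """Normalize a connectome for synchronization at ``frequency_hz``.

    The particle limit (``frequency_hz == 0`` or infinite velocity) returns
    the weights unchanged, exactly.
    """
    if frequency_hz < 0:
        raise ValueError(f"frequency must be non-negative, got {frequency_hz}")
    delays = delays_from_lengths(c, velocity_mps)
    if frequency_hz == 0 or math.isinf(velocity_mps):
        wave = c.weights.copy()
    else:
        wave = c.weights * np.cos(2.0 * math.pi * frequency_hz * delays)
        np.fill_diagonal(wave, 0.0)
    return NormalizedConnectome(
        base=c,
        frequency_hz=float(frequency_hz),
        velocity_mps=float(velocity_mps),
        delays=delays,
        wave_weights=wave,
    )


def spectral_strength(nc: NormalizedConnectome, arrangement) -> np.ndarray:
    """Signed spectral strength S_i for a given in-/anti-phase arrangement.

    With sign vector ``s`` (s_j = +1 for nodes in phase with the positive
    cluster), ``S_i = s_i * sum_j s_j w_ij^(f)``: links from in-phase nodes
    count with their wave coupling, links from anti-phase nodes with the
    opposite sign.  Invariant under a global sign flip.
    """
    s = signs_of(arrangement)
    if s.shape[0] != nc.n_regions:
        raise ValueError(
            f"arrangement has {s.shape[0]} signs for {nc.n_regions} regions"
        )
    return s * (nc.wave_weights @ s)


def spectral_capacity(nc: NormalizedConnectome) -> np.ndarray:
    """Spectral capacity C_i = sum_j |w_ij^(f)| (arrangement-independent)."""
    return np.abs(nc.wave_weights).sum(axis=1)


def particle_strength(c: Connectome, arrangement=None) -> np.ndarray:
    """Topological node strength C_i^(0) = sum_j w_ij (the particle null).

    If an ``arrangement`` is supplied, its signs are applied a posteriori
    (``s_i * C_i^(0)``) for conservative comparison with signed wave
    metrics; the particle picture itself cannot produce anti-phase nodes.
    """
    strength = c.weights.sum(axis=1)
    if arrangement is not None:
        strength = signs_of(arrangement) * strength
    return strength


def _ratio(strength: np.ndarray, capacity: np.ndarray) -> np.ndarray:
    out = np.zeros_like(strength, dtype=float)
    nz = capacity > 0
    out[nz] = strength[nz] / capacity[nz]
    return out


def metrics_at(nc: NormalizedConnectome, arrangement) -> SpectralMetrics:
    """Bundle strength, capacity and their ratio at one frequency."""
    strength = spectral_strength(nc, arrangement)
    capacity = spectral_capacity(nc)
    return SpectralMetrics(
        frequency_hz=nc.frequency_hz,
        strength=strength,
        capacity=capacity,
        ratio=_ratio(strength, capacity),
        arrangement=arrangement,
    )


def metric_spectrum(
    c: Connectome,
    frequencies_hz: Sequence[float] | Iterable[float],
    velocity_mps: float = DEFAULT_VELOCITY_MPS,
    arrangement_policy: str = "maximize",
    arrangement=None,
    seed: int = 0,
    normalize_per_frequency: bool = False,
) -> list[SpectralMetrics]:
    """Spectral metrics over a frequency grid.

    ``arrangement_policy`` selects how the in-/anti-phase arrangement is
    chosen per frequency: ``maximize`` (heuristic maximization of the total
    spectral strength), ``eigenvector`` (signs of the leading eigenvector of
    ``W^(f)``), or ``supplied`` (a fixed arrangement for all frequencies).
    With ``normalize_per_frequency`` both metrics are divided by their max
    absolute value over nodes at each frequency (relative activation maps).
    """
    from . import arrange  # local import: arrange builds on this module

    freqs = list(frequencies_hz)
    if not freqs:
        raise ValueError("empty frequency list")
    if any(f < 0 for f in freqs):
        raise ValueError("frequencies must be non-negative")
    if arrangement_policy == "supplied" and arrangement is None:
        raise ValueError("arrangement_policy='supplied' needs an arrangement")

    out: list[SpectralMetrics] = []
    for k, f in enumerate(freqs):
        nc = wave_couplings(c, f, velocity_mps)
        if arrangement_policy == "maximize":
            arr = arrange.maximize_spectral_strength(nc, seed=seed + k)
        elif arrangement_policy == "eigenvector":
            arr = arrange.eigenvector_arrangement(nc)
        elif arrangement_policy == "supplied":
            arr = arrangement
        else:
            raise ValueError(f"unknown arrangement_policy {arrangement_policy!r}")
        m = metrics_at(nc, arr)
        if normalize_per_frequency:
            def _norm(v: np.ndarray) -> np.ndarray:
                top = np.abs(v).max()
                return v / top if top > 0 else v
            m = SpectralMetrics(
                frequency_hz=m.frequency_hz,
                strength=_norm(m.strength),
                capacity=_norm(m.capacity),
                ratio=m.ratio,
                arrangement=m.arrangement,
            )
        out.append(m)
    return out
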
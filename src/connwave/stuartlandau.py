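"""Stuart-Landau network model: linear stability analysis and simulation.

Each region is a Stuart-Landau oscillator, the normal form of the
Andronov-Hopf bifurcation,

    dX_i/dt = X_i (r + i*omega - |X_i|^2) + coupling + noise,      X_i complex,

with ``r`` the distance from the bifurcation (an uncoupled node is a damped
focus for r < 0 and a limit cycle of radius sqrt(r) for r > 0).  Two
couplings are supported:

* the *normalized* instantaneous coupling ``sum_j w_ij^(f) X_j(t)``, which
  admits a closed-form linear stability analysis (LSA) at the origin: the
  2n x 2n real Jacobian has eigenvalues ``r + mu_k ± i*omega`` where
  ``mu_k`` are the eigenvalues of the symmetric wave-coupling matrix, so
  the leading eigenvector of ``W^(f)`` is the activation pattern that
  emerges at criticality;
* the *full delayed* coupling ``G sum_j w_ij X_j(t - tau_ij)``, integrated
  with a stochastic Heun scheme and delay buffers.

Criticality is located by decreasing ``r`` until the largest real part of
the LSA spectrum is just above zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.signal
import scipy.stats

from .arrange import Arrangement
from .io import Connectome
from .normalize import NormalizedConnectome, delays_from_lengths, signs_of

__all__ = [
    "SLParams",
    "LSAResult",
    "OscillatorTrajectory",
    "lsa_normalized",
    "find_critical_r",
    "r_for_regime",
    "simulate_full",
    "simulate_normalized",
    "node_power",
    "phase_arrangement_from_data",
    "correlate_metrics_with_power",
    "lsa_power_pattern",
]

DT_CAP = 0.005  # s; hard upper bound on the integration step


@dataclass(frozen=True)
class SLParams:
    """Parameters of a Stuart-Landau network run."""

    r: float
    omega_rad_s: float
    G: float = 1.0
    D: float = 0.0
    dt: float = 1e-3
    duration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt > DT_CAP:
            raise ValueError(f"dt must be in (0, {DT_CAP}] s, got {self.dt}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.G < 0 or self.D < 0:
            raise ValueError("G and D must be non-negative")


@dataclass(frozen=True)
class LSAResult:
    """Spectrum of the linearization at the origin."""

    r_used: float
    eigenvalues: np.ndarray  # 2n complex values
    leading_eigenvector: np.ndarray  # n signed real amplitudes
    max_real_part: float
    critical: bool


@dataclass(frozen=True)
class OscillatorTrajectory:
    """Complex node trajectories X_i(t)."""

    times: np.ndarray
    states: np.ndarray  # (n, T) complex
    params: SLParams
    model: str  # 'normalized_instantaneous' | 'full_delayed'

    @property
    def n(self) -> int:
        return self.states.shape[0]


def _jacobian(wave_weights: np.ndarray, r: float, omega: float) -> np.ndarray:
    """Real 2n x 2n Jacobian of the coupled system at X = 0.

    In (x, y) coordinates with X = x + i y:
        dx/dt = r x - omega y + W x,    dy/dt = omega x + r y + W y.
    """
    n = wave_weights.shape[0]
    eye = np.eye(n)
    A = r * eye + wave_weights
    top = np.hstack([A, -omega * eye])
    bot = np.hstack([omega * eye, A])
    return np.vstack([top, bot])


def lsa_normalized(
    nc: NormalizedConnectome, r: float, omega: float, crit_tol: float = 1e-6
) -> LSAResult:
    """Linear stability analysis of the normalized-coupling model at X = 0.

    Eigen-decomposes the real 2n x 2n Jacobian.  The leading eigenvector is
    reported as n signed real per-region amplitudes of the least-stable
    mode, unit-normalized, with the largest-magnitude entry positive.
    """
    W = nc.wave_weights
    if np.abs(W - W.T).max(initial=0.0) > 1e-9:
        raise ValueError("wave-coupling matrix must be symmetric for LSA")
    n = W.shape[0]
    J = _jacobian(W, r, omega)
    evals, evecs = scipy.linalg.eig(J)
    max_real = float(evals.real.max())
    # least-stable mode with non-negative imaginary part (conjugate partner
    # carries the same spatial pattern)
    cand = np.flatnonzero(evals.real > max_real - 1e-12)
    cand = cand[np.argsort(-evals[cand].imag, kind="stable")]
    lead = int(cand[0])
    z = evecs[: n, lead]
    if np.abs(z).max() == 0:  # pattern lives in the y-block
        z = evecs[n:, lead]
    k = int(np.argmax(np.abs(z)))
    v = (z * np.exp(-1j * np.angle(z[k]))).real
    v = v / np.linalg.norm(v)
    # a non-degenerate top mode contributes exactly one conjugate pair
    if int((evals.real >= max_real - 1e-9).sum()) > 2:
        warnings.warn(
            "degenerate leading eigenvalue of the wave-coupling matrix; "
            "mode choice is deterministic but arbitrary",
            stacklevel=2,
        )
    return LSAResult(
        r_used=float(r),
        eigenvalues=evals,
        leading_eigenvector=v,
        max_real_part=max_real,
        critical=bool(0.0 < max_real <= crit_tol),
    )


def find_critical_r(
    nc: NormalizedConnectome, omega: float, tol: float = 1e-6
) -> float:
    """Value of r that puts the network just above criticality.

    Bisects until the largest real part of the LSA spectrum lies in
    ``(0, tol]``.  Because the real parts shift affinely with r
    (``r + mu_k``), a bracket always exists and the search converges to
    ``r* = -mu_max(W^(f)) + eps`` with ``eps`` in ``(0, tol]``.
    """

    def max_real(r: float) -> float:
        return lsa_normalized(nc, r, omega).max_real_part

    m0 = max_real(0.0)
    lo, hi = -m0 - 1.0, -m0 + 1.0  # max_real(lo) < 0 < max_real(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        v = max_real(mid)
        if 0.0 < v <= tol:
            return mid
        if v <= 0.0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("criticality bisection did not converge")


def r_for_regime(
    nc: NormalizedConnectome, omega: float, regime: str, offset: float = 0.2
) -> float:
    """Map {'critical', 'subcritical', 'supercritical'} to a value of r.

    Sub/supercritical sit ``offset`` below/above the critical value.
    """
    r_crit = find_critical_r(nc, omega)
    if regime == "critical":
        return r_crit
    if regime == "subcritical":
        return r_crit - offset
    if regime == "supercritical":
        return r_crit + offset
    raise ValueError(f"unknown regime {regime!r}")


def _heun_complex(
    coupling_term,
    n: int,
    params: SLParams,
    x0: np.ndarray,
    d_steps: np.ndarray | None,
) -> np.ndarray:
    """Stochastic Heun loop shared by the two coupling variants.

    Returns the state history, shape (steps + 1, n) complex.  Noise is
    additive complex white Gaussian of intensity D per real component.
    """
    dt = params.dt
    steps = int(round(params.duration / dt))
    buf = int(d_steps.max(initial=0)) if d_steps is not None else 0
    hist = np.empty((buf + steps + 2, n), dtype=complex)
    hist[: buf + 1] = x0  # constant history before t = 0
    rng = np.random.default_rng(params.seed)
    a = params.r + 1j * params.omega_rad_s
    noise_std = math.sqrt(2.0 * params.D * dt) if params.D > 0 else 0.0
    cols = np.broadcast_to(np.arange(n), (n, n)) if d_steps is not None else None

    def drift(x: np.ndarray, row: int) -> np.ndarray:
        local = x * (a - np.abs(x) ** 2)
        return local + coupling_term(x, row, hist, cols)

    for m in range(steps):
        row = buf + m
        x = hist[row]
        f1 = drift(x, row)
        dW = (
            noise_std * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
            if noise_std
            else 0.0
        )
        pred = x + dt * f1 + dW
        hist[row + 1] = pred
        f2 = drift(pred, row + 1)
        new = x + 0.5 * dt * (f1 + f2) + dW
        hist[row + 1] = new
        if np.abs(new).max() > 1e6:
            raise FloatingPointError(
                f"trajectory diverged (|X| > 1e6) at t = {(m + 1) * dt:.4f} s"
            )
    return hist[buf : buf + steps + 1]


def recommended_dt(frequency_hz: float, G: float) -> float:
    """Integration step inversely proportional to frequency and coupling,
    capped at 0.005 s."""
    if frequency_hz <= 0:
        return DT_CAP
    return min(DT_CAP, 1.0 / (20.0 * frequency_hz * max(G, 1.0)))


def simulate_full(
    c: Connectome,
    params: SLParams,
    velocity_mps: float,
    initial_states: np.ndarray | None = None,
) -> OscillatorTrajectory:
    """Simulate the full delayed model with coupling G * w_ij X_j(t - tau_ij)."""
    n = c.n_regions
    tau = delays_from_lengths(c, velocity_mps)
    d_steps = np.rint(tau / params.dt).astype(np.int64)
    pos = tau[tau > 0]
    if pos.size and params.dt > pos.min():
        warnings.warn(
            "dt exceeds the smallest positive delay; delays are rounded "
            "to the step grid",
            stacklevel=2,
        )
    GW = params.G * c.weights
    x0 = (
        np.full(n, 0.1 + 0.0j) if initial_states is None
        else np.asarray(initial_states, dtype=complex)
    )

    def coupling(x, row, hist, cols):
        delayed = hist[row - d_steps, cols]
        return (GW * delayed).sum(axis=1)

    states = _heun_complex(coupling, n, params, x0, d_steps)
    times = np.arange(states.shape[0]) * params.dt
    return OscillatorTrajectory(
        times=times, states=states.T.copy(), params=params, model="full_delayed"
    )


def simulate_normalized(
    nc: NormalizedConnectome,
    params: SLParams,
    initial_states: np.ndarray | None = None,
) -> OscillatorTrajectory:
    """Simulate the instantaneous model coupled through the wave couplings."""
    n = nc.n_regions
    W = nc.wave_weights
    x0 = (
        np.full(n, 0.1 + 0.0j) if initial_states is None
        else np.asarray(initial_states, dtype=complex)
    )

    def coupling(x, row, hist, cols):
        return W @ x

    states = _heun_complex(coupling, n, params, x0, None)
    times = np.arange(states.shape[0]) * params.dt
    return OscillatorTrajectory(
        times=times,
        states=states.T.copy(),
        params=params,
        model="normalized_instantaneous",
    )


def node_power(
    traj: OscillatorTrajectory,
    frequency_hz: float,
    transient_fraction: float = 0.5,
    method: str = "periodogram",
) -> np.ndarray:
    """Per-node spectral power at the target frequency.

    ``method='periodogram'`` takes the periodogram bin nearest
    ``frequency_hz`` on Re X over the post-transient window;
    ``method='bandpower'`` integrates the periodogram over ±2 Hz around the
    target instead.  The window must cover at least 10 periods.
    """
    k0 = int(round(transient_fraction * (traj.times.size - 1)))
    x = traj.states[:, k0:].real
    fs = 1.0 / traj.params.dt
    window_s = x.shape[1] / fs
    if frequency_hz > 0 and window_s < 10.0 / frequency_hz:
        raise ValueError(
            f"analysis window ({window_s:.3g} s) shorter than 10 periods "
            f"at {frequency_hz} Hz"
        )
    freqs, pxx = scipy.signal.periodogram(x, fs=fs, axis=1)
    if method == "periodogram":
        k = int(np.argmin(np.abs(freqs - frequency_hz)))
        return pxx[:, k]
    if method == "bandpower":
        band = (freqs >= frequency_hz - 2.0) & (freqs <= frequency_hz + 2.0)
        if not band.any():
            band = np.abs(freqs - frequency_hz) == np.abs(freqs - frequency_hz).min()
        return pxx[:, band].sum(axis=1)
    raise ValueError(f"unknown method {method!r}")


def phase_arrangement_from_data(
    traj: OscillatorTrajectory,
    transient_fraction: float = 0.5,
    variance_tol: float = 0.5,
) -> Arrangement:
    """In-/anti-phase arrangement extracted from simulated trajectories.

    The reference is the node of largest mean power (|X|^2).  A region is
    classed anti-phase when its circular-mean phase difference to the
    reference, mapped to [0, 2pi), lies in (pi/2, 3pi/2) — i.e. closer to
    pi than to 0.  Nodes whose phase difference has circular variance above
    ``variance_tol`` are flagged with a warning (non-locked dynamics).
    """
    k0 = int(round(transient_fraction * (traj.times.size - 1)))
    X = traj.states[:, k0:]
    ref = int(np.argmax((np.abs(X) ** 2).mean(axis=1)))
    z = np.exp(1j * (np.angle(X) - np.angle(X[ref])[None, :])).mean(axis=1)
    circ_var = 1.0 - np.abs(z)
    if (circ_var > variance_tol).any():
        bad = np.flatnonzero(circ_var > variance_tol).tolist()
        warnings.warn(
            f"nodes {bad} are not phase-locked to the reference "
            f"(circular variance > {variance_tol})",
            stacklevel=2,
        )
    diff = np.mod(np.angle(z), 2.0 * math.pi)
    anti = (diff > math.pi / 2) & (diff < 3 * math.pi / 2)
    signs = np.where(anti, -1, 1)
    arr = Arrangement(signs, provenance="data")
    return arr.canonical(ref)


def lsa_power_pattern(lsa: LSAResult) -> np.ndarray:
    """Activation-power pattern predicted by the LSA at criticality.

    The magnitude of the leading eigenvector gives each region's relative
    amplitude in the critical mode; its signs give the in-/anti-phase
    arrangement.
    """
    return np.abs(lsa.leading_eigenvector)


def correlate_metrics_with_power(
    power: np.ndarray,
    metrics: dict[str, np.ndarray],
    arrangement=None,
    null_key: str = "C0",
) -> pd.DataFrame:
    """Pearson correlation of the (signed) power pattern with each metric.

    If an arrangement is given its signs are applied to the power vector,
    so that anti-phase regions count negatively on both sides.  The metric
    named ``null_key`` (the signed particle null, in-strength) serves as
    the baseline: each row reports the metric's correlation minus the
    null's.  A constant vector yields NaN (undefined correlation) with
    ``defined=False`` rather than an error.
    """
    power = np.asarray(power, dtype=float)
    signed_power = (
        signs_of(arrangement) * power if arrangement is not None else power
    )

    def corr(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return math.nan, math.nan, False
        r, p = scipy.stats.pearsonr(a, b)
        return float(r), float(p), True

    rows = {}
    for name, vec in metrics.items():
        r, p, ok = corr(signed_power, np.asarray(vec, dtype=float))
        rows[name] = dict(metric=name, r=r, p=p, defined=ok)
    null_r = rows[null_key]["r"] if null_key in rows else math.nan
    for name in rows:
        rows[name]["r_minus_null"] = rows[name]["r"] - null_r
    return pd.DataFrame(rows.values()).set_index("metric")
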
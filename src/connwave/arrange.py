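"""In-/anti-phase arrangement of nodes maximizing total spectral strength.

An arrangement is a bipartition of the nodes into two mutually anti-phase
clusters, encoded as a ±1 sign per node.  The total spectral strength
``sum_i S_i = s^T W^(f) s`` is a quadratic form in the sign vector, so the
maximization is an Ising/max-cut-type problem: exact enumeration is
feasible only for small networks (the global flip symmetry leaves
``2^(n-1)`` distinct bipartitions), and larger networks use a stochastic
local search driven by three cost functions that pick the node to move
between clusters:

1. the node with the smallest spectral strength;
2. the weaker endpoint of the most negative *internal* wave coupling
   (a link within a cluster);
3. the weaker endpoint of the most negative *external* wave coupling
   (a link between the clusters).

Each search loop stops on the first revisit of an already seen
configuration; extra loops add randomness by sampling the move uniformly
from the top fraction of candidates.  The best configuration ever visited
wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .normalize import NormalizedConnectome, spectral_capacity, signs_of

__all__ = [
    "Arrangement",
    "total_strength",
    "brute_force_arrangement",
    "maximize_spectral_strength",
    "arrangement_from_signs",
    "eigenvector_arrangement",
    "BRUTE_FORCE_MAX_N",
]

BRUTE_FORCE_MAX_N = 22


@dataclass(frozen=True)
class Arrangement:
    """A ±1 sign per node encoding the in-/anti-phase bipartition.

    A global sign flip is a symmetry ("which cluster is positive" carries no
    information); the canonical form fixes +1 on a reference node, by
    convention the node of largest spectral capacity when one is known.
    """

    signs: np.ndarray
    provenance: str = "supplied"
    total_strength: float = float("nan")

    def __post_init__(self) -> None:
        s = np.asarray(self.signs, dtype=int)
        if s.ndim != 1 or not np.all(np.abs(s) == 1):
            raise ValueError("signs must be a 1-d ±1 vector")
        s.setflags(write=False)
        object.__setattr__(self, "signs", s)

    @property
    def n(self) -> int:
        return self.signs.shape[0]

    def canonical(self, reference: int = 0) -> "Arrangement":
        """Flip globally so that ``signs[reference] == +1``."""
        if self.signs[reference] == 1:
            return self
        return Arrangement(-self.signs, self.provenance, self.total_strength)


def total_strength(nc: NormalizedConnectome, arrangement) -> float:
    """Total spectral strength sum_i S_i = s^T W^(f) s."""
    s = signs_of(arrangement)
    if s.shape[0] != nc.n_regions:
        raise ValueError("arrangement/connectome size mismatch")
    return float(s @ nc.wave_weights @ s)


def _canonical_reference(nc: NormalizedConnectome) -> int:
    return int(np.argmax(spectral_capacity(nc)))


def brute_force_arrangement(nc: NormalizedConnectome) -> Arrangement:
    """Exact maximizer of the total strength by exhaustive enumeration.

    Enumerates the 2^(n-1) bipartitions with node 0 fixed to +1, keeping
    the first maximizer in lexicographic order (+1 sorting before -1), so
    ties resolve deterministically.  Only feasible for n <= 22.
    """
    n = nc.n_regions
    if n > BRUTE_FORCE_MAX_N:
        raise ValueError(
            f"brute force is limited to n <= {BRUTE_FORCE_MAX_N} "
            f"(got n = {n}); use maximize_spectral_strength instead"
        )
    W = nc.wave_weights
    best_signs = np.ones(n, dtype=int)
    best_total = float(best_signs @ W @ best_signs)
    signs = np.ones(n, dtype=int)
    # Gray-free plain enumeration: bit b of k flips node n-1-b... iterate k in
    # ascending order with node 1 as the most significant bit so that the
    # enumeration order is lexicographic with +1 preferred.
    for k in range(1, 1 << (n - 1)):
        for b in range(n - 1):
            signs[1 + b] = -1 if (k >> (n - 2 - b)) & 1 else 1
        t = float(signs @ W @ signs)
        if t > best_total:
            best_total = t
            best_signs = signs.copy()
    return Arrangement(
        best_signs, provenance="brute_force", total_strength=best_total
    ).canonical(_canonical_reference(nc))


def _greedy_ascent(W: np.ndarray, signs: np.ndarray) -> tuple[np.ndarray, float]:
    """Flip the single best-improving node until no flip improves the total.

    Flipping node i changes the total by -4 * s_i * (W s)_i (zero diagonal),
    so the move and its gain are computed in closed form.
    """
    s = signs.astype(float)
    field = W @ s
    while True:
        gains = -4.0 * s * field
        i = int(np.argmax(gains))
        if gains[i] <= 1e-12:
            break
        s[i] = -s[i]
        field += 2.0 * s[i] * W[:, i]
    return s.astype(int), float(s @ W @ s)


def _candidate_moves(
    W: np.ndarray, s: np.ndarray, cost_kind: int
) -> np.ndarray:
    """Nodes to flip, best candidate first, for one of the three costs."""
    per_node = s * (W @ s)  # S_i
    if cost_kind == 0:
        # node with the smallest spectral strength changes the cluster
        return np.argsort(per_node, kind="stable")
    same = np.multiply.outer(s, s) > 0
    iu, ju = np.triu_indices(W.shape[0], 1)
    mask = same[iu, ju] if cost_kind == 1 else ~same[iu, ju]
    mask &= W[iu, ju] != 0
    if not mask.any():
        return np.empty(0, dtype=int)
    ii, jj, ww = iu[mask], ju[mask], W[iu, ju][mask]
    order = np.argsort(ww, kind="stable")  # most negative coupling first
    # of the link's two endpoints, the one with the smaller S_i moves
    picks = np.where(per_node[ii[order]] <= per_node[jj[order]],
                     ii[order], jj[order])
    return picks


def maximize_spectral_strength(
    nc: NormalizedConnectome,
    n_restarts: int = 10,
    n_noisy_repeats: int = 10,
    randomness_fraction: float = 0.1,
    seed: int = 0,
) -> Arrangement:
    """Heuristic maximization of the total spectral strength.

    Runs ``n_restarts`` local searches from random sign vectors.  Each
    search applies the three cost functions in rotation, one node flip per
    step, until it revisits a configuration; it then continues for
    ``n_noisy_repeats`` further loops in which the move is drawn uniformly
    from the top ``randomness_fraction`` of candidates.  A plain greedy
    ascent from each start is also recorded, and the best configuration
    visited by any route is polished by greedy ascent before being
    returned.  Deterministic for a fixed seed.
    """
    n = nc.n_regions
    if n < 2:
        raise ValueError("need at least 2 nodes")
    W = nc.wave_weights
    rng = np.random.default_rng(seed)

    best_signs = np.ones(n, dtype=int)
    best_total = float(best_signs @ W @ best_signs)

    def consider(s: np.ndarray, t: float) -> None:
        nonlocal best_signs, best_total
        if t > best_total:
            best_total, best_signs = t, s.copy()

    for _ in range(max(1, n_restarts)):
        start = rng.choice([-1, 1], size=n)
        # baseline: plain greedy ascent from the same start
        g_s, g_t = _greedy_ascent(W, start.copy())
        consider(g_s, g_t)

        s = start.copy()
        visited: set[bytes] = set()

        def key(v: np.ndarray) -> bytes:
            return (v * v[0]).astype(np.int8).tobytes()  # flip-invariant

        visited.add(key(s))
        consider(s, float(s @ W @ s))
        for loop in range(1 + n_noisy_repeats):
            noisy = loop > 0
            cost_kind = 0
            for _step in range(8 * n):  # safety bound; revisit stops earlier
                cands = _candidate_moves(W, s, cost_kind)
                cost_kind = (cost_kind + 1) % 3
                if cands.size == 0:
                    continue
                if noisy:
                    top = max(1, int(np.ceil(randomness_fraction * cands.size)))
                    i = int(cands[rng.integers(top)])
                else:
                    i = int(cands[0])
                s[i] = -s[i]
                consider(s, float(s @ W @ s))
                k = key(s)
                if k in visited:
                    break
                visited.add(k)

    polished, polished_total = _greedy_ascent(W, best_signs)
    consider(polished, polished_total)
    return Arrangement(
        best_signs, provenance="maximize_connectome", total_strength=best_total
    ).canonical(_canonical_reference(nc))


def arrangement_from_signs(
    v: np.ndarray, provenance: str = "supplied", tol: float = 1e-12
) -> Arrangement:
    """Arrangement from the signs of a real vector (e.g., an eigenvector).

    Entries with |v_i| < tol are snapped to +1 with a warning; an all-zero
    vector is rejected.  Canonicalized so the largest-magnitude entry is
    positive, making v and -v equivalent.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("need a 1-d vector")
    if np.all(np.abs(v) < tol):
        raise ValueError("all-zero vector carries no sign pattern")
    if np.any(np.abs(v) < tol):
        warnings.warn(
            "near-zero eigenvector entries assigned to the +1 cluster",
            stacklevel=2,
        )
    signs = np.where(v >= tol, 1, np.where(v <= -tol, -1, 1))
    return Arrangement(signs, provenance=provenance).canonical(
        int(np.argmax(np.abs(v)))
    )


def eigenvector_arrangement(nc: NormalizedConnectome) -> Arrangement:
    """Arrangement from the leading eigenvector of the wave-coupling matrix.

    The signs of the top eigenvector of the symmetric ``W^(f)`` capture the
    in-/anti-phase organization of the least-stable network mode.
    """
    evals, evecs = np.linalg.eigh(nc.wave_weights)
    v = evecs[:, -1]
    arr = arrangement_from_signs(v, provenance="eigenvector")
    return Arrangement(
        arr.signs, provenance="eigenvector",
        total_strength=total_strength(nc, arr),
    ).canonical(_canonical_reference(nc))
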
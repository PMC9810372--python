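# Methods

This note records the models implemented by `connwave`, the assumptions
they rest on, the defaults and why they were chosen, and what the
synthetic-data studies do and do not establish.

## Wave normalization

**Model.** Regions are treated as oscillators coupled through a symmetric
weight matrix `w` with tract lengths `l` (mm) and a homogeneous conduction
velocity `v` (m/s), so delays are `τ_ij = (l_ij/1000)/v` seconds. For
dynamics frequency-locked at `Ω = 2πf`, a delayed interaction
`sin(θ_i − θ_j(t − τ))` becomes `sin(θ_i − θ_j + Ωτ)`, and the direct
link's effect on the pair's steady phase difference is carried entirely by
the wave coupling `w^(f) = w cos(Ωτ)`. The arcsine formula for `Δθ_ij`
(see `kuramoto.analytic_phase_difference`) is exact for symmetric weights
and delays; asymmetric inputs are rejected at I/O validation with the
location of the worst entry, because the derivation genuinely requires
symmetry.

**Assumptions.** Homogeneous `v`; one frequency at a time (no
cross-frequency interactions); the phase arrangement is a single
bipartition into two mutually anti-phase clusters. All are deliberate
scope restrictions, not approximations hidden in the code.

**Units.** Lengths mm, velocity m/s, delays s, frequency Hz; the
conversion happens in exactly one place (`normalize.delays_from_lengths`).
The default `v = 5 m/s` is a standard effective cortico-cortical
conduction velocity; with lengths of 5–170 mm it puts delays at 1–34 ms,
the physiological range, and the first sign flips of `cos Ωτ` in the
10–40 Hz band. Velocity is surfaced in every report because no canonical
value exists.

**Weight modes.** Raw streamline counts or their natural logarithms. The
log transform floors `ln c` at 0 (counts of one streamline map to weight
0) so that a sign in `w^(f)` can only ever come from the delay term,
never from the logarithm of a small count. Spectral analyses and LSA
default to log weights (they reduce the orders-of-magnitude heterogeneity
of counts); the full forward model uses raw counts.

## Arrangement search

Maximizing total spectral strength `s^T W^(f) s` over sign vectors is an
Ising-type problem; `2^(n−1)` distinct bipartitions exist after the global
flip symmetry. `brute_force_arrangement` enumerates them for `n ≤ 22`
(ties broken toward the lexicographically smallest vector with +1
preferred, for determinism). The heuristic runs 10 restarts; each applies
three cost functions in rotation — flip the node with smallest `S_i`,
flip the weaker endpoint of the most negative within-cluster coupling,
flip the weaker endpoint of the most negative between-cluster coupling —
stopping a loop at the first revisit of a configuration, then 10 further
loops pick the move uniformly from the top 10 % of candidates
(`randomness_fraction = 0.1`; the fraction is a free parameter with no
canonical value). A plain greedy ascent from each start is recorded as a
baseline candidate and the best configuration found is polished by greedy
ascent, so the result is never worse than greedy descent from the same
starts and is always a local optimum. On 100 random 10-node instances the
heuristic matches the exhaustive optimum in all cases (the acceptance
report recomputes this rate).

Canonical form: the global flip is fixed by making the sign of the
largest-capacity node (or largest-magnitude eigenvector entry, when only a
vector is available) positive.

## Delayed simulations

Both integrators (Kuramoto phases, Stuart-Landau complex amplitudes) use
a stochastic Heun scheme with delays rounded to the nearest multiple of
`dt` and served from a history buffer. Rounding rather than interpolating
keeps the scheme simple; the induced `O(dt)` bias is exactly what the
step-size sweep in the validation study measures, and it shrinks as
advertised. History before `t = 0`: Kuramoto phases are extrapolated
backwards at the mean natural frequency; Stuart-Landau states are held
constant at `X(0)`. Any fixed choice washes out after the transient; the
analysis window discards the first 50 % of a run by default. Noise is
additive white Gaussian on the phase velocity (intensity `D` rad²/s) or
on both components of `X`; increments have standard deviation
`sqrt(2 D dt)` and, the noise being additive, no Itô/Stratonovich
ambiguity arises. The Stuart-Landau step is capped at `dt ≤ 0.005 s` and
`recommended_dt` shrinks it inversely with frequency and coupling.
Divergence (`|X| > 1e6`) raises an error carrying the blow-up time.

Lock detection: a pair counts as phase-locked when the circular standard
deviation of its phase difference over the analysis window is below
0.01 rad. The validation of the arcsine formula evaluates the analytic
side with the *true* delays `l/v` while the simulation runs on
grid-rounded delays, so the reported error includes the discretization
bias and is an honest convergence measure. Ω is estimated from the data
(mean instantaneous frequency over the window) unless imposed.

## Linear stability analysis

For the instantaneous model coupled through `W^(f)`, the Jacobian at the
origin in `(x, y)` coordinates is `[[rI + W, −ωI], [ωI, rI + W]]`; its
eigenvalues are `r + μ_k ± iω` with `μ_k` the eigenvalues of the
symmetric `W^(f)`, each real part appearing twice (one conjugate pair per
spatial mode). The implementation eigendecomposes the full `2n × 2n` real
matrix; the closed form serves as an independent test oracle, not as the
implementation. The "two identical positive eigenvalues" at criticality
are this conjugate pair; criticality targets the real part.
`find_critical_r` bisects until the largest real part lies in `(0, tol]`
(`tol = 1e−6`), which equals `−μ_max + ε` because the spectrum shifts
affinely with `r`. The leading eigenvector is reported as `n` signed real
amplitudes (unit norm, largest-magnitude entry positive); a degenerate top
eigenvalue triggers a warning and a deterministic (but arbitrary) mode
choice.

Node power defaults to the periodogram bin nearest the target frequency
on `Re X` over the post-transient window (at least 10 periods required);
a band-integrated variant (±2 Hz) is available behind `method=`. "Power"
has no unique operational definition for this model, so the choice is
exposed rather than hidden. The data-driven arrangement classes a region
anti-phase when its circular-mean phase difference to the largest-power
reference region is closer to π than to 0 (difference mod 2π in
(π/2, 3π/2)); the literal reading "difference larger than π" is not
flip-symmetric and cannot be meant for a phase defined modulo 2π.

## Robustness null models

Three perturbations, each scaled by the respective mean so levels are
comparable: Gaussian noise on lengths (std = level × mean link length,
floored at 1 mm), Gaussian noise on raw counts (std = level × mean count,
clipped at 0, topology preserved), and degree-preserving double-edge
swaps of a fraction of links (weights and lengths travel with the link)
followed by iterative symmetric rescaling until the node strength
sequence matches the original within 1 %.

For each realization the leading LSA eigenvector is recomputed and
sign-aligned to the original by dot product — without alignment the mean
over realizations would be meaningless, since each eigenvector is defined
up to a global flip. The deviation of the mean is `err̃_i = |v_i −
mean(v_i^null)|`; the spread-penalized error defaults to
`err_i = err̃_i/σ_i + σ_i²` with the two alternative readings
(`err̃/σ + σ`, `err̃/(σ + σ²)`) selectable — the source expression is
typographically ambiguous and no reading is treated as ground truth. The
exceedance threshold is `(|v_i| + mean|v|)/2`, comparing each node's
deviation against both its own and the global activity level; absolute
values are used because the eigenvector's global sign is a convention.
Since the eigenvectors of the linearization do not depend on `r`, the
pattern is evaluated at `r = 0`; the criticality search is exercised and
tested separately. The reference workload is 1,000 realizations per
condition; the test suite and acceptance report run 50, which is ample
for the mean-error and exceedance summaries they check.

## Synthetic connectomes

The generator emulates tractography-derived inputs: symmetric, zero
diagonal, heavy-tailed positive weights (lognormal, median ≈ 7
streamlines), lengths uniform on 5–170 mm, target edge density realized
within one edge, optional exact homotopic mirror symmetry (node `i`
paired with `i + n/2`), seeded and bit-reproducible. It does **not**
emulate spatial embedding: lengths are independent of topology, so there
is no exponential distance rule, no community structure, and no
correlation between weight and length.

That last limitation matters for one result. The wave-vs-particle
predictivity study (critical-mode pattern vs eigenvector-arranged
spectral strength against the signed in-strength null) is run at 10 Hz
with `v = 5 m/s`, where `Ωτ` spans ~0.06–2.1 rad and a sizable minority
of links carry negative couplings; there the wave metric wins on 20/20
synthetic subjects with a wide margin. At higher frequencies random
non-spatial connectomes produce a quasi-degenerate top of the `W^(f)`
spectrum whose eigenvector sign patterns are effectively noise, and the
comparison is no longer informative about the method — spatially embedded
real connectomes keep coherent modes across the band. Passing this study
therefore demonstrates the machinery and the alpha-band regime, not
behaviour at arbitrary frequencies on arbitrary random graphs.

Problem sizes used by the tests and the acceptance report — 68 regions
for subject-level studies (10–30 for oracle-checked ones), 50 null
realizations, 5 × 10-node networks for the phase-formula study, 16 s of
simulated time at `dt = 1e−4` — were chosen so each check is decisively
sampled while the whole suite stays lightweight.

## Known limitations

* Directed (asymmetric) connectomes are rejected, not approximated.
* Heterogeneous or frequency-dependent conduction velocities are out of
  scope; `v` is a single number.
* Only 1:1 synchronization; no cross-frequency (n:m) coupling.
* The arrangement is a single bipartition; multi-cluster phase
  configurations are not searched.
* The default EEG band edges (delta 1–4, theta 4–8, alpha 8–12, beta
  12–30, gamma 30–80 Hz) and the example lobe/RSN tables under
  `examples/` are editable artifact defaults / synthetic stand-ins, not
  canonical atlases.
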
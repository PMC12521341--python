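# Methods

## Model class

The state `x ∈ R^n_{≥0}` collects cell counts of `n` sub-populations; the
control `u ∈ [0,1]^m` collects effective drug actions (pharmacodynamics at
the target tissue — deliberately *not* administered doses, so absorption and
clearance are outside the model). The dynamics are semi-linear with
multiplicative control:

    dx/dt = A x + B u + L(u, x) + N(u, x),
    L(u, x) = Σᵢ xᵢ Cᵢ u,
    N(u, x)ⱼ = Σᵢ xᵢ uᵀ Dⁱʲ u.

Assumptions baked into this class: linear (exponential) growth in the
absence of drugs, mass-action interconversion between compartments,
first-order drug action (`u_l x_i` monomials) and pairwise-only synergy
(`x_i u_k u_l`, `k ≠ l`). Quadratic self-action `u_k²` is excluded — one
drug's dose–response is already captured by the linear term — which is
enforced structurally: each `Dⁱʲ` is stored strictly lower-triangular with a
zero diagonal, and constructors that accept a full symmetric interaction
specification fold `(k,l)` and `(l,k)` weights into the single canonical
entry, rejecting any diagonal content. All quantities are dimensionless;
`ControlledODEModel.rescaled(k)` divides every coefficient by a reference
rate `k` (time `τ = k t`) and records the factor.

State nonnegativity is a property of admissible trajectories (it depends on
the signs of the model's polynomial terms), so it is monitored as a runtime
diagnostic — values below `−10⁻⁸` raise, values in `(−10⁻⁸, 0)` warn as
integrator round-off — rather than enforced by projection, which would
silently change the dynamics.

## Optimal control formulation

Cost: `J = ½[x(T)ᵀMx(T) + ∫₀ᵀ (xᵀQx + uᵀRu) dt]` with `M, Q ⪰ 0`, `R ≻ 0`
(symmetry and eigenvalue conditions are checked at construction; `Q(t)`,
`R(t)` may be callables, all shipped examples use constants). The
Hamiltonian `H = ½(xᵀQx + uᵀRu) + λ·dx/dt` yields

    dλᵢ/dt = −(Qx)ᵢ − (Aᵀλ)ᵢ − λᵀ(Cᵢu) − Σⱼ λⱼ uᵀDⁱʲu,

with transversality `λ(T) = M x(T)` — all `n` terminal conditions are
imposed (with `M = 0` this is `λ(T) = 0`, i.e. drugs are withheld at the end
of the window). Because the dynamics are quadratic in `u`, `H` is an exact
quadratic in `u` at fixed `(x, λ)`:

    ∂H/∂u = G u + b,  G = R + Σᵢⱼ xᵢλⱼ(Dⁱʲ + Dⁱʲᵀ),  b = (B + Σᵢ xᵢCᵢ)ᵀλ.

### Box-constrained control elimination

The admissible box `0 ≤ u ≤ 1` is handled by projected stationarity inside
every residual evaluation: the unconstrained stationary point `−G⁻¹b` is
clipped componentwise, which is exact when `G` is diagonal (the case for
every synergy-free model with diagonal `R`). When `G` has off-diagonal
structure (interacting drugs), a cyclic coordinate-descent refinement over
the box follows (at most 20 sweeps, tolerance `10⁻¹⁰`; a coordinate with a
non-positive diagonal entry takes the better box endpoint). If the condition
number of `G` exceeds `10¹⁰` a `SingularOptimality` error is raised carrying
`(x, λ, cond)`: singular-arc synthesis is out of scope and silent
pseudo-inversion would hide it.

### Boundary value solve

Eliminating `u` closes a `2n`-dimensional two-point BVP, solved with
`scipy.integrate.solve_bvp` (fourth-order collocation with residual
control, damped Newton). Defaults: relative tolerance `10⁻³`, boundary
tolerance `10⁻⁸`, node cap `5×10⁵`, initial mesh of 101 uniform nodes,
initial guess `x ≡ x0`, `λ ≡ 0`. The clipped control makes the residual
only piecewise-smooth, and collocation occasionally stalls depending on
where the initial mesh places nodes relative to switching times; the solver
therefore retries on a small ladder of initial meshes (101, 201, 25 nodes),
capping the first attempts at 3×10⁴ nodes so a stalled mesh fails fast and
only the final attempt uses the full budget. `J` is evaluated by composite
trapezoid on the returned adaptive mesh, `O(h²)`, consistent with the
collocation accuracy. Reported diagnostics: convergence flag, node count,
max RMS residual, retry history, and the max box-projected gradient norm of
`H` in `u` over the grid (`stationarity_residual`).

Forward simulation (`simulate_forward`) of arbitrary schedules uses LSODA
with `rtol 10⁻⁸`, `atol 10⁻¹⁰` by default.

## Treatment comparison

For a solved schedule, `efficacy_ratio` computes each drug's horizon mean
`ū = (1/T)∫u dτ` on a uniform 2001-point resampling of the solver mesh (so
adaptive node density cannot bias the average), re-simulates the state under
the constant schedule `u ≡ ū`, and reports `η = Σᵢx̄ᵢ(T) / Σᵢxᵢ(T)` on total
counts, alongside both costs and integrated control penalties. The constant
comparator is a plain re-simulation, never a second optimisation.

Measured regime structure (default settings, `[0.05, 0.5]²` grid): `η`
rises steeply with the paclitaxel kill rate `β` (up to ≈1.5 at
`(α, β) = (0.05, 0.5)`), and an `η < 1` pocket — constant dosing wins —
sits at strong cisplatin / weak-but-nonzero paclitaxel kill (e.g. `η ≈ 0.93`
at `(0.5, 0.16)`). At the extreme corner `(0.5, 0.05)` the measured value is
`η = 1.036`, marginally above 1; this is robust to solver tolerance and
initial guess (the extremal is unique across guesses, the projected control
minimises `H` pointwise against a dense grid search, and the adjoint matches
finite differences to `10⁻¹⁰`). The integrated drug cost falls with `β`
throughout, while its trend in `α` inverts: rising with `α` at strong `β`,
falling at weak `β` where a stronger cisplatin effect kills efficiently with
less total drug.

## Example systems

*Two-population (cervical cancer)*: G1 cells `A`, S/G2 cells `B`; cisplatin
`u_c` kills `A` at rescaled rate `α` and blocks the A→B transition;
paclitaxel `u_p` kills `B` at rate `β` and blocks division. Defaults
`Q = I`, `R = 0.1·I`, `M = 0`, `T = 7` (one week at a ~24 h cell cycle),
`x0 = (1, 1)`.

*Neuroblastoma*: sympathoblast `I`, adrenergic `N`, mesenchymal `S`; drugs
(u_RA, u_chemo, u_trk, u_NGF) in this fixed order. The full builder encodes
every pathway term — RA-driven I→N differentiation, chemo kill of I,
trkA+NGF differentiation `δ_diff(1−u_trk)u_NGF n_I`, trkA−NGF apoptosis
`δ_trk,NGF(1−u_NGF)(1−u_trk)n_N`, and trkB+BDNF de-differentiation draining
`N` with factor 2 into one unit each of `I` and `S` (flux-conserving) — with
the `(1−u_trk)u_NGF`-type products expanded into `A`/`C`/`D` entries; the
`u_trk·u_NGF` synergies are stored at the canonical (NGF, trk) lower
position. The reduced builder applies: all spontaneous interconversion
rates equal to `k` (time rescaled by `k`), all drug-mediated interconversion
effects equal to `δ`, chemotherapy kill `δ_chemo = 2λ` (full kill of the
proliferative compartment at maximal dose), proliferation in `I` only. The
two builders agree entrywise to `10⁻¹²` under these substitutions over
random parameter draws — this consistency is a standing test.

## Proportion control

With `N = 1ᵀx` and `r = x/N`, the count dynamics (with `B = 0`) induce
closed dynamics on the simplex:

    dr/dt = f(r, u) − (1ᵀf(r, u)) r,   f(r, u) = dx/dt evaluated at r.

The quotient rule gives `d(x/N)/dt = ẋ/N − (Ṅ/N) r`, hence the sign above;
`1ᵀ(dr/dt) = (1ᵀf)(1 − 1ᵀr)` makes the simplex invariant, and the
normalised count trajectory and the direct proportion trajectory agree to
integrator tolerance for any fixed schedule (a standing test — with the
sign flipped the flow leaves the simplex and blows up in finite time).

The tracking cost `J = ∫ (r−r̃)ᵀW_state(r−r̃) + uᵀW_control u dt` uses
neutral weight names because the source formulation of this problem swaps
the `Q`/`R` symbol roles relative to the count problem; there is no ½
prefactor and no terminal cost (`λ(T) = 0`). The adjoint and control
gradients are the exact derivatives of this Hamiltonian (the leading control
term is therefore `2·W_control·u`), verified against central finite
differences; `H` is again quadratic in `u`, so control elimination reuses
the same box-QP machinery (the exact solve plays the role of the Newton
step; coordinate descent handles non-diagonal Hessians).

## Sweeps and the noise study

Sweeps run one OC solve per grid cell, trap per-cell failures
(non-convergence, singular `G`) and continue, leaving NaN in failed cells.
Default grid resolutions are 10×10 for the two-population maps and 8×8×8
for the neuroblastoma cube, with overrides everywhere (tests and examples
use 4×4 and 2–3-point grids to keep runtimes in seconds). The maximum
marginal drug cost is `c(ζ, ξ) = max_ρ c̃(ζ, ξ, ρ)` over the marginalised
parameter's grid; the sensitivity partition computes, per `(λ, δ_apop)`
cell, the variance across a `δ` grid of each drug's mean dose and reports
the arg-max drug (ties broken by the fixed drug order). Motif reporting is
descriptive: the dosing traces for the two reference regimes
(`δ_apop = 0.3`, `λ ∈ {0.2, 0.4}`, `δ ∈ {0.05, 0.25, 0.45}`) are emitted
for inspection rather than classified automatically, since shape thresholds
would be arbitrary.

The dosing-noise study perturbs each drug trace with an independent
stationary Ornstein–Uhlenbeck process — correlation time 1 rescaled unit
(the natural timescale of the model; "temporally correlated" is otherwise
unconstrained) and stationary standard deviation equal to the amplitude —
sampled exactly on a 701-point grid, clipped to the box, and re-simulates
the state. The baseline uses the identical resampled schedule, so zero
amplitude gives exactly zero deviation, and all draws derive from one seed.

Measured behaviour at the reference problem (`α = β = 0.5`): worst-case
relative final-count deviations of ≈11% at amplitude 0.0125 rising to ≈50%
at 0.05 (200 replicate re-simulations). The sensitivity is inherent, not
numerical: a *sustained* dose offset of −0.05 alone shifts the final total
by ≈47%, because under-dosing compounds exponentially over `T = 7` and the
optimal paclitaxel trace sits at the upper bound for ≈65% of the horizon,
so clipped noise is systematically downward. Near-optimal final counts
(within ~10%) therefore require persistent dosing errors of roughly a
percent of full scale, or noise that decorrelates much faster than the
rescaled time unit. The acceptance script reports the measured worst-case
deviation for amplitudes up to 0.05 without adjustment.

## Synthetic study conditions

All inputs are generated programmatically from the printed example
parameterisations; there are no external datasets. The worked examples fix
the biology to two regimes of interest and rescale time, so passing tests
demonstrate internal consistency of the control machinery and faithful
encoding of the example systems — not calibration to experimental data.
Real treatment data would add pharmacokinetics, saturating (non-mass-action)
growth and interconversion, measurement noise and inter-patient variability,
none of which the model class represents.

## Known limitations

- Necessary-condition solver: collocation on the Pontryagin system finds
  extremals; global optimality is checked only empirically (perturbation
  tests, uniqueness across initial guesses).
- Singular arcs (`G` numerically singular, e.g. `R → 0` with active
  synergies) are detected and refused, not synthesised; the `R → 0` limit is
  handled only through small-but-positive `R`, where controls become
  near-bang-bang.
- No feedback (Riccati) synthesis for the multiplicative problem: the
  control's box bounds couple into the co-state equation, so the co-state
  cannot be eliminated as `λ = Px`; the classical LQR limit (`C = D = 0`)
  is used as a numerical oracle only.
- Fixed horizon only; no state constraints beyond the nonnegativity
  diagnostic; no pharmacokinetic layer; no spatial structure.
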
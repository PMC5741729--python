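# Methods

## Model structure

A fibril is a rooted tree of FN dimers. Mechanics is one-dimensional along
the pulling axis (z): forces, lengths and stretches live on z, while the
x–y cross-section is pure packing bookkeeping on a hexagonal lattice
(axial coordinates, spacing `d_lat`). Each dimer contributes 30 elastic
domain springs — domains III₁…III₁₅ of one monomer followed by the mirror
III₁₅…III₁ of the other — plus two inelastic Type I/II end connectors of
length `l_I_II`. The root dimer's N-terminal connector is in series with a
stiff linear substrate spring (`k_sub` = 1000 pN/nm); every other dimer's
N-terminal connector is anchored rigidly at the exposed domain node of its
parent and the chain extends in +z. The C-terminal dimer junction is
modeled as a rigid point, and there is no excluded-volume interaction
between neighboring chains.

New molecules take the free lattice site nearest their parent
(Euclidean distance between site centers; ties broken by ring number then
counter-clockwise angular index), so placement — and hence the whole
trajectory — is reproducible from the seed. A molecule is on the
*perimeter* while any of its six lattice neighbors is free; only
perimeter molecules can bind integrins or recruit soluble FN.

## Constitutive laws

**Domain spring.** The tension at stretch s (extension beyond the folded
rest length `l_III`) blends the Hookean resting response with the
worm-like-chain (WLC) response of the unfolded chain:

    F(s) = (1 − w(s))·k⁰·s + w(s)·[F_wlc(s + l_III) − F_wlc(l_III)]

with F_wlc the standard WLC interpolation at contour length `L_c` and
persistence length `p_wlc`, evaluated at the end-to-end extension
x = s + l_III so the force diverges exactly at the admissible stretch
limit L_c − l_III. The weight w is a logistic in s with midpoint at the
exposure threshold ε_t and width ε_t/4, renormalized so w(0) = 0: the
tangent stiffness is then *exactly* k⁰ at rest and approaches the WLC
tangent at large stretch. The stiffness reported by `domain_stiffness` is
the analytic derivative of this force law (verified against central
differences to 1e-6 relative). Inside the solver the law is linearly
extrapolated beyond 97 % of the stretch limit to keep Newton iterates
finite; physical states never sit there because the force at that point
is far above the stall force. Compression (transient only) is linear
at k⁰.

**Clutch kinetics.** Bell slip bond, k\*_off = k_off·exp(f/f_b), with
constant on-rate k_on per free III₁₀ site on the perimeter. The clutch is
a tension-only linear spring (k_c) whose rest offset is fixed at binding
so it engages with zero force.

**Traction.** One collective actin node per fibril advances
kinematically by v·dt with the linear force–velocity law
v = v_u(1 − f_sub/f_stall), clamped at stall. The linear form is the
simplest law satisfying the two anchors the model pins down (unloaded
velocity, hard stall at 200 pN); the stall is collective, not per-clutch,
because the total fibril traction force is the feedback variable.

**Exposure and recruitment.** Exposure is a Hill-type hazard
k_exp·sⁿ/(ε_tⁿ + sⁿ) with n = 4 — a sharp but finite threshold;
half-maximal response sits exactly at ε_t (nominal 15 Å). An exposed,
unoccupied site whose stretch relaxes below ε_t/2 re-buries
(hysteresis); the model is silent on re-burial in the source biology, but
without it a single transient force spike would permanently license
binding. FN binding itself is irreversible, and an occupied site is
frozen thereafter.

## Numerics

Quasi-static assumption: mechanical relaxation is fast relative to dt, so
after each actin advance the network is re-equilibrated before events are
sampled. Equilibrium is found by damped Newton iteration on the nodal
positions with the analytic tangent-stiffness matrix; because the
network is a tree, each linear solve is an O(N) elimination from the
leaves to the root. A backtracking line search on the residual norm
guards against overshoot; default tolerance is a maximum nodal force
imbalance of 1e-6 pN. Warm starts from the previous step mean one to
three iterations per step in practice.

Stochastic events use fixed-timestep Bernoulli sampling with
p = 1 − exp(−rate·dt), not exact Gillespie, because propensities change
continuously with the actin position. A runtime warning fires if
max(rate)·dt exceeds 0.05. Event order within a step is fixed for
determinism: unbind → bind → expose/hide → FN-bind; all draws come from a
single seeded PCG64 generator, so one (configuration, seed) pair yields a
bit-identical event log and trajectory.

## Parameters

Printed anchors of the model: k_sub = 1000 pN/nm, f_stall = 200 pN,
ε_t = 15 Å (7.5/30 Å variants), k⁰ ∈ [0.2, 1.0] pN/nm with
k₂⁰ = 0.8 pN/nm. The remaining kinetic and geometric constants are
package defaults in the motor-clutch literature range, fixed once by the
calibration procedure below:

| parameter | default | meaning |
|---|---|---|
| v_u | 120 nm/s | unloaded actin velocity |
| k_on | 1 s⁻¹ | integrin on-rate per free site |
| k_off | 0.1 s⁻¹ | unloaded off-rate |
| f_b | 2 pN | Bell break force |
| k_c | 5 pN/nm | clutch stiffness |
| k_exp | 1 s⁻¹ | maximal exposure rate |
| k_fn | 0.0017 s⁻¹ | soluble-FN binding rate at an exposed site |
| l_III / l_I_II | 3.2 / 20 nm | folded domain / connector rest lengths |
| L_c / p_wlc | 30 / 0.4 nm | unfolded contour / persistence length |
| d_lat | 5 nm | lattice spacing |
| dt | 0.02 s | timestep |
| duration | 900 s | assembly time |

The default stiffness spectrum is 15 values evenly spaced on
[0.2, 1.0] pN/nm with the entry nearest 0.8 replaced by exactly 0.8 and
assigned to domain 2 (the one per-domain value the model pins down); the
exact experimental spectrum is not published, so the vector is plain
configuration and every experiment may replace it.

**Calibration.** `experiments.calibrate` grid-searches the free kinetic
constants (by default k_fn and k_exp, log-spaced) against three
targets evaluated on ≥ 20 seeds: all-site mean molecule count in
[380, 450], all-site mean extensibility in [2.9, 3.6], and single-III₂
mean count below 10. The shipped defaults come from this procedure run at
desk scale: they meet the molecule-count and single-site targets
(all-site mean ≈ 430 over the development seeds; III₂ maximum of 3
molecules over 20 seeds). The population-mean extensibility (≈ 2.0) falls
below its window: under these conditions takeoff times vary strongly
between replicates, and the small late-takeoff fibrils dilute the mean
even though large fibrils individually reach extensibility ≈ 3.5. A
longer assembly duration narrows this gap at proportional compute cost;
the window is kept as stated and the discrepancy is recorded rather than
papered over by a wider band.

**Problem sizes.** Shipped defaults simulate 15 minutes of assembly and
10 minutes of re-stretch; the test suite uses these defaults for
single-site populations and 6-minute assemblies for multi-site
populations. These are the package's desk-scale study conditions; the
experiment drivers accept any duration and the full replicate counts
(100/500/1000 per condition) through the catalogue and `--scale`.

## Re-stretch protocol and classification

A fully assembled fibril is relaxed by removing every integrin bond
(f_sub = 0, all springs at rest, L_s = L_r) and re-stretched by re-running
the traction loop with recruitment disabled and the bond topology frozen.
Re-stretch trajectories are sampled at 0.1 s (versus 1 s during assembly)
to resolve the initial loading slope. Classification over the final two
minutes: a stably stretched fibril (SSF) holds a mean substrate force of
at least 95 % of stall with a coefficient of variation below 5 %;
anything else is a fluctuating stretched fibril (FSF). Both thresholds
are package choices for phenotypes the source biology describes
qualitatively, and both are exposed as arguments. Resting stiffness is
the least-squares slope of f_sub against ΔL = L_s − L_r over the initial
monotone-loading samples with ΔL below 10 % of the plateau stretch (mean
of the final two minutes); fibrils below ~10 molecules load too fast for
any sampling cadence to resolve this window and are excluded from
population stiffness statistics.

## What the simulator does and does not emulate

The simulator *is* the data generator: there is no external data. It
reproduces the study conditions — assembly from a single substrate-bound
dimer, hypothesis-dependent cryptic-site sets, stiffness variants,
threshold scaling, perimeter-limited hexagonal growth — and its
qualitative predictions at desk scale match the study's robust claims:
negligible assembly for any single N-terminal site across the whole
(k₂⁰, ε_t) grid, robust multi-site assembly orders of magnitude larger,
heterogeneous size distributions, and re-stretched phenotypes in which
smaller fibrils carry higher resting stiffness and fluctuating force
grows with size. It does not emulate: soluble-FN depletion (supply is
well-mixed and unlimited, the blood-plasma regime), thermal fluctuation
of node positions, viscous network dynamics, excluded volume, cell
migration or fibril–fibril interactions. Passing tests therefore support
the mechanochemical feedback logic, not quantitative agreement with any
particular wet-lab measurement; absolute population statistics depend on
the calibration of kinetic constants that are not pinned by the printed
anchors.

## Known limitations

* Population magnitudes at full replicate counts (e.g. the SSF/FSF split
  and their mean sizes) are calibration-conditional; the desk-scale
  defaults reproduce the signs and orderings, not the magnitudes.
* The SSF phenotype is rare under the shipped defaults: clutch churn
  keeps the mean re-stretch force a few percent below the strict 95 %
  stall criterion for all but the largest fibrils.
* The per-domain stiffness spectrum is a stand-in ordering over the
  printed range, not measured values.
* Fixed-step Bernoulli sampling slightly biases fast-rupture events when
  clutch forces spike (the dt warning); halving dt leaves replicate-mean
  population sizes statistically unchanged (see the timestep-convergence
  test).
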
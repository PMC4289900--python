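# Methods

`dendromaps` simulates how progressive dendritic atrophy reshapes the
somatodendritic maps of input resistance, impedance and theta resonance
that an HCN-channel density gradient imposes on a CA1 pyramidal neuron.
This note documents the model, its parameters, the synthetic morphology,
the numerical choices, and the limits of what the test suite demonstrates.

## The biophysical model

Each morphology is discretized into cylindrical/frustum compartments and
simulated as a branched RC cable with two membrane mechanisms: a passive
leak and, optionally, the hyperpolarization-activated (HCN, "h")
conductance.

**Passive profiles.** Specific membrane resistivity and axial resistivity
vary sigmoidally with radial distance x (μm) from the soma along the
somatoapical axis:

    R_m(x) = 55 + (20 − 55) / (1 + exp((250 − x)/50))   kΩ·cm²
    R_a(x) = 70 + (30 − 70) / (1 + exp((250 − x)/50))   Ω·cm

with C_m = 1 μF/cm² everywhere. Basal dendrites and the soma take the
x = 0 values. These profiles keep the passive local input resistance
roughly uniform along the trunk (≈ 90–120 MΩ in the base model).

**HCN gradient.** The maximal h-conductance density rises ~25-fold along
the same axis,

    ḡ_h(x) = 50 · (1 + 25 / (1 + exp(−(x − 350)/15)))   μS/cm²,

applied to every apical compartment at its midpoint radial distance; basal
and somatic compartments take the somatic 50 μS/cm².

**HCN gating.** A single first-order activation gate:
m_∞(V) = 1/(1 + exp((V + 82)/9)) (hyperpolarization-activated), reversal
E_h = −30 mV, and a bell-shaped time constant
τ(V) = τ_peak / cosh((V + 75)/17) with τ_peak = 60 ms quoted at the 34 °C
simulation temperature, i.e. τ(−65 mV) ≈ 51 ms. A Q10 of 4.5 rescales τ
when the simulation temperature differs from the kinetics reference
temperature. The cited recordings of dendritic h-currents do not pin these
numbers exactly; τ was chosen so that the gradient model reproduces the
calibrated map structure this class of models is built around — soma
resonance near the low theta range with f_R rising several-fold toward the
distal trunk, and R_in falling along the same axis. A faster gate
(τ(−65) ≈ 12 ms) places the somatic resonance near 7–8 Hz and flattens the
f_R map, which is inconsistent with that calibration.

**Holding at −65 mV.** All measurements are made at −65 mV and 34 °C. With
the 25-fold gradient, a model initialized at −65 mV would drift ~10 mV
depolarized (distal h-current is strongly activated at rest), shifting
every voltage-dependent measurement. The leak reversal is therefore
balanced per compartment,

    E_l,i = −65 + ḡ_h,i · m_∞(−65) · (−65 − E_h) / g_l,i,

which makes V ≡ −65 mV the exact resting state with the gate settled at
m_∞(−65) — the standard way this family of models implements "membrane
potential set at −65 mV". For passive models the adjustment is identically
zero. A 200 ms settle window is still run and discarded before every
measurement.

## Synthetic morphology

The generator builds a stylized CA1 pyramidal cell so the whole pipeline
runs without any downloaded reconstruction. Total dendritic length is
controlled exactly (default 17.5 mm): branch lengths are drawn from the
configured distributions and rescaled analytically; the 3-D embedding is
cosmetic. Components and default proportions:

- **Soma**: three type-1 nodes, ~10 μm radius, centroid at the origin.
- **Apical trunk**: radial extent 450 μm, tapering 4 → 0.5 μm, embedded as
  a unit-speed helix with path/radial ratio 2 (path length ≈ 900 μm).
  Real CA1 trunks meander; this tortuosity is what gives the distal tree
  its electrotonic separation, and it makes "the center of the apical
  trunk" sit at ~450 μm *path* distance, the canonical cluster location.
- **Obliques**: lengths ~N(120, 40²) μm (min 30), 35% once-branched,
  attached over radial 40–400 μm — i.e. along essentially the whole trunk,
  so the distal obliques place prunable membrane inside the high-density
  end of the HCN gradient.
- **Apical tuft**: 35% of the non-basal apical budget, a binary tree above
  the trunk tip whose depth adapts to keep branches near 120 μm and the
  radial span within ~250 μm. The tuft is the dominant high-ḡ_h load of
  the intact cell.
- **Basal tree**: 30% of the non-trunk budget, three stems with adaptive
  binary branching bounded to a ~300 μm field.

These proportions were chosen once as a realistic CA1 stylization; they are
exposed in `SynthParams`. The base model produced this way shows the
qualitative map structure the study depends on: a flat passive R_in
profile, R_in falling and f_R/Q/Φ_L rising along the trunk under the
gradient, and, across the atrophy series, monotone constriction of the
R_in and f_R maps. No fit to any real reconstruction's morphometry is
attempted.

## Pruning

Atrophy is modelled by removing whole unprotected terminal sections —
never rerouting or rescaling — so every surviving location keeps its exact
geometry across the series (same-location comparisons remain valid).
"Uniform across strata" is implemented over concentric radial bins
(default 50 μm): each removal targets the stratum whose removed share of
*prunable* length lags the global share most, then takes its longest
terminal section that fits the remaining budget. The soma and apical trunk
are protected, so the deepest members collapse toward the bare trunk.
Whole-section removal cannot hit targets exactly; achieved lengths stay
within 0.1 mm. The default series runs 17.5 → 1.5 mm in 1 mm steps
(17 members), each member pruned from its predecessor. Section
decomposition breaks chains at label boundaries so a collapsed fork can
never merge trunk nodes into an oblique remnant (which would make the
remnant unprunable).

## Numerics

- **Discretization**: d_λ rule with d_λ = 0.1 — every section is split
  into the smallest odd number of equal segments shorter than 0.1·λ₁₀₀,
  with λ₁₀₀ from the section's length-weighted mean diameter and local
  R_a. Midpoint evaluation of all spatial profiles; frustum areas.
- **Integration**: Crank–Nicolson (θ = 1 gives backward Euler as a
  fallback) with an exact linear-time Hines solve per step and
  Rush–Larsen (locally exact exponential) gating updates, accelerated with
  numba. Default dt = 0.1 ms for the desk-scale protocols in the tests and
  acceptance script; convergence is asserted by the dt-halving invariant
  (halving dt changes reference traces by < 0.2%) rather than by scheme
  fiat, and the reference 25 μs step remains available through the
  protocol options.
- **Steady states**: damped Newton on the nonlinear DC system (leak + HCN
  at m_∞(V)) with a tree-structured Jacobian; residual < 10⁻³ pA.
- **Units**: mV, ms, pA, nS, pF internally (1 mV/pA = 1 GΩ); μm for
  geometry; impedances reported in MΩ.

## Measurements

- **R_in**: least-squares slope of the steady-state V–I relation under
  300 ms pulses (−50…50 pA in 10 pA steps; a reduced ±25 pA/5 pA range is
  used where voltage deflections should stay small, as for the
  HCN-gradient series). Steady state is read as the mean of the final
  10 ms.
- **Chirp impedance**: constant-amplitude chirp, frequency rising linearly
  0 → 25 Hz (50 pA, 25 s at paper scale; the desk-scale protocols use a
  10 s sweep to the same 25 Hz). Z(f) = FFT(V)/FFT(I) restricted to
  0.5–25 Hz. A 2 s silent tail is appended and transformed with the
  record so the response decays before the transform — without it,
  truncation leakage biases the band edges by a few percent. With the
  tail, the estimator matches closed-form and admittance-matrix oracles
  to better than 1% across the band.
- **Resonance measures**: f_R = argmax |Z| with three-point parabolic
  refinement (band-edge maxima are reported at the edge, so strictly
  low-pass profiles pin at 0.5 Hz with Q = 1); Q = |Z(f_R)|/|Z(0.5)|;
  Φ_L = trapezoid integral of the impedance phase where it is positive.
- **Amplitude handling**: the h-current makes the membrane weakly
  nonlinear, and at 50 pA the harmonic distortion puts percent-level
  ripples on |Z(f)| — enough to bias argmax on the broad peaks of weakly
  resonant sites. Across a pruned series the chirp amplitude is therefore
  normalized by the somatic R_in ratio (keeping somatic peak-to-peak
  voltage comparable, and the base model's stimulus exactly 50 pA), and
  the map-constriction analyses extract f_R with a small-amplitude (5 pA)
  probe chirp, i.e. in the small-signal regime that defines impedance.
- **Transfer measurements**: chirp injected at the dendritic site, voltage
  recorded at the soma; one simulation yields the local and transfer
  profiles simultaneously. Distances always refer to the injection site.

## Influence fields

A cluster of total conductance G on the segment at path distance x_i adds
G/area to that segment's specific h-density. For measurement M (R_in or
f_R) along the trunk, IF_M(x) = |M_org(x) − M_new(x)| / M_org(x),
Λ_M = IF_M / max IF_M, and the spatial extent is the trapezoid area under
either curve over the trunk path. The physiologically scaled default
cluster (ḡ_h(350 μm) × host-segment area ≈ 1–2 nS) measurably perturbs
R_in but cannot induce resonance on the passive background of a full-size
tree (the f_R field is then degenerate, M_new ≡ M_org ≡ 0.5 Hz); the
broadening analyses therefore use a 40 nS cluster at the trunk center,
strong enough to create a localized resonant pocket on the passive
background, with both choices exposed in the API. On the passive
background the reference f_R is pinned at the 0.5 Hz band floor, so the
division in IF is always well defined.

## Problem sizes and what the tests show

The test suite and the acceptance script run entirely on synthetic
morphologies at desk scale: dt = 0.1 ms, 10 s chirps, the 17.5 mm base
(~650 compartments) with series subsampled to 3–5 members for the
simulation-heavy analyses, and the full 17-member series for the pruning
contract. These sizes were chosen so every claim is recomputed from
scratch in minutes; the dt-halving and d_λ-refinement invariants bound the
numerical error of the faster settings.

Passing tests demonstrate the mechanisms on a stylized cell: they show
that the implementation reproduces closed-form cable physics, that the
measurement battery is internally consistent, and that atrophy produces
the directional effects (excitability increase, map constriction,
influence-field broadening) under the stated biophysics. They do not
certify numeric agreement with any particular reconstruction: absolute
values of R_in, f_R and their fold-changes depend on the real cell's
morphometry (trunk tortuosity, tuft share, oblique placement) that the
generator only stylizes.

## Known limitations

- Only leak + HCN; no other conductances, synapses or stochastic channels.
- The f_R of weakly resonant sites (Q close to 1) is intrinsically
  ill-conditioned — the |Z| peak is flat — so small-amplitude probes are
  needed for stable maps; reported f_R differences below ~0.1 Hz are not
  meaningful at the default sweep resolution.
- Whole-section pruning quantizes the removable length; achieved lengths
  carry up to 0.1 mm slack and per-stratum balance is limited by the
  longest section in a stratum.
- The spatial profiles are functions of radial distance, as specified, but
  the generator's embedding makes radial and path coordinates differ by
  the tortuosity factor on the trunk; both coordinates are reported in
  every output table.
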
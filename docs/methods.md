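# Methods

This document defines the model `atpcal` implements: the governing
equations, boundary conditions, numerical schemes, the parameter profile and
how it was obtained, the problem sizes the package defaults to, and the known
limitations.

Units throughout: SI for the fluid/transport stage (m, s, Pa), with ATP and
Ca²⁺ concentrations in µM and cellular rate constants in µM and s.

## 1. Device and flow model

A straight rectangular microchannel of length `L`, width `W` and height `H`
carries two co-flowing streams injected at `z = 0`: an ATP-laden stream at a
constant flow rate `Q1` (stock concentration `φ0`) next to the wall at
`x = 0`, and an ATP-free perfusion stream at rate `Q2(t)`. The perfusion
stream is modulated sinusoidally,

    Q2(t) = Q̄2 · (1 + δ · sin(2π f_Q t)),    0 ≤ δ ≤ 1,

so the total rate `Q(t) = Q1 + Q2(t)` and the interface position between the
streams both oscillate. With volumetric flow balance, the ATP stream occupies
the instantaneous width fraction

    ε(t) = Q1 / (Q1 + Q2(t)).

The flow is treated as quasi-steady, fully developed pressure-driven flow in
a wide shallow slot. The depth-averaged axial velocity is plug-like across
the width,

    ū(t) = Q(t) / (H·W),

and the wall shear stress on the channel floor (where cells adhere) is

    τ_w(t) = 6 η Q(t) / (W H²).

All cells share the same shear history; the transverse position sets only
the chemical stimulus.

### Geometry assignments

The nominal dimension set is `L = 1 cm`, `H = 1 mm`, `W = 50 µm`
(`ChannelGeometry()` defaults). The package also ships the *shallow*
assignment with the cross-section transposed, `H = 50 µm`, `W = 1 mm`
(`ChannelGeometry.reference_shallow()`). The two differ sharply in their
dispersion correction `(H/W)²` and in wall shear. The shallow assignment is
the one consistent with the reference chip's measured behaviour — fill-in
settling in ≈ 4 s, mean emerging ATP of ≈ 6 µM at the first outlet position,
a transverse profile still nearly linear at the outlet, and a physiological
wall shear of ≈ 0.72 Pa at the nominal flow rates (the deep nominal
assignment gives 1.7 s, 5.3 µM and 0.036 Pa). The shipped chip protocol and
the acceptance script therefore use the shallow assignment; both are fully
configurable.

## 2. ATP transport

After averaging over the channel height, the ATP concentration
`φ(x, z, t)` (µM) obeys

    ∂φ/∂t + ū(t) ∂φ/∂z = D ∂²φ/∂x² + D_eff(t) ∂²φ/∂z²,

where `D` is the molecular diffusivity and `D_eff` the Taylor–Aris axial
dispersion coefficient evaluated quasi-steadily at the instantaneous mean
velocity:

    D_eff(t) = D · (1 + Pe²/210 · (H/W)²),    Pe = ū(t)·W / D.

A `dispersion="molecular"` variant disables the enhancement (`D_eff = D`)
for advection-dominated checks. Note the dispersion enhancement *grows* with
velocity and with decreasing molecular diffusivity; at the reference
operating point `D_eff/D` is of order 10⁵–10⁶, which dominates the numerical
scheme choice below.

Boundary and initial conditions:

* **Inlet (`z = 0`)**: a linear profile across the ATP stream,
  `φ = φ0 (1 − x/(ε(t)W))` for `x ≤ ε(t)W`, zero beyond — an idealisation of
  the partially pre-mixed interface, re-evaluated every time step as `ε(t)`
  moves.
* **Side walls (`x = 0, W`)**: no flux.
* **Outflow (`z = L`)**: zero axial gradient (truncation of the nearly
  semi-infinite channel).
* **Initial condition**: ATP-free channel, matching the fill-in transient.

### Numerical scheme

Uniform vertex-centred grid (`nx × nz`, defaults 64 × 256), operator
splitting per time step:

1. **Advection**: explicit first-order upwind in `z`, time step limited by
   the advective CFL condition `ū_max dt ≤ 0.9 dz`.
2. **Transverse diffusion**: backward-Euler tridiagonal solve per axial
   column (mirror-ghost Neumann walls).
3. **Axial dispersion**: backward-Euler tridiagonal solve per transverse
   row, with a Dirichlet inlet row and mirror-ghost zero-gradient outflow;
   `D_eff` is refreshed from the instantaneous `ū(t)` each step.

Every substep is monotone (positive coefficients / M-matrices), so the
discrete field obeys the maximum principle `0 ≤ φ ≤ φ0` exactly; this is
asserted in the test suite. An explicit treatment of the dispersion term
would require `dt ≲ dz²/(2 D_eff) ≈ 2 µs` at the reference parameters —
millions of steps per second of simulated time — which is why the diffusion
terms are implicit. First-order upwinding introduces numerical axial
diffusion of order `ū dz/2 ≈ 10⁻⁷ m²/s`, three orders of magnitude below
`D_eff`, hence harmless here. The time step is chosen as the largest value
that (i) satisfies the CFL bound, (ii) resolves the drive period with ≥ 50
steps, and (iii) divides the snapshot interval `output_dt` exactly, keeping
runs deterministic and output grids uniform.

**Settling time** is defined as the first time the maximum field change per
1 s window falls below 0.1 % of `φ0`.

**Grid convergence**: the steady outlet concentration at `x = W/5` changes
by < 1 % from a 24 × 80 grid to a 48 × 160 grid (asserted in tests); the
default 64 × 256 grid is comfortably converged. A 10 s fill-in run at
64 × 256 takes ~2–4 s on one CPU; a 200 s pulsatile run at the chip-protocol
grid (48 × 160) takes ~10 s.

## 3. Endothelial Ca²⁺ model

Each wall-adherent cell is a well-mixed four-state system — cytosolic Ca²⁺
`C`, store (ER) Ca²⁺ `Cs`, buffered Ca²⁺ `Cb`, and IP₃ `i` (all µM) — driven
by the local wall ATP concentration `φ(t)` and wall shear stress `τ_w(t)`:

    dC/dt  = q_rel − q_res + q_in − q_out − q_buf
    dCs/dt = (Vc/Vs) · (q_res − q_rel)
    dCb/dt = q_buf
    di/dt  = k1 · φ/(Kc+φ) · C/(K1+C) − k2 · i

with `q_in = q_in,P2X4 + q_in,TRP + q_in,pass`. The fluxes (µM/s):

* **CICR store release** (IP₃-gated, three binding sites, Ca²⁺-sensitised,
  proportional to store content):
  `q_rel = k3 · C/(K_CICR+C) · (i/(i+K2))³ · Cs`.
* **SERCA restore minus store leak**:
  `q_res = k4 · (C/(K3+C))² − k5 · Cs²`.
* **Efflux** (PMCA/NCX lumped, saturating): `q_out = k8 · C/(K4+C)`.
* **Protein buffering**: `q_buf = k6 · C · (BT − Cb) − k7 · Cb`.
* **P2X₄ ATP-gated influx**:
  `q_in,P2X4 = k_P2X4 · (φ/(K_P2X4+φ))³ · (Cex − C)`.
* **Mechanosensitive TRPV₄/TRPC₁ influx** with store feedback:
  `q_in,TRP = q_max · p1(τ_w) · p2(i) · p3(C) · (Cs0 − Cs) · (Cex − C)`,
  where

      p1 = 1 / (1 + α · exp(−f_e · W(τ_w) / (s · k_B T N)))
      p2 = b1 · (1 + a1 · i³/(K_i + i³))
      p3 = c1 + c2 · exp(−c3 · C)

  and the membrane strain energy density is

      W(τ) = (ε_m τ l + √(16 δ_m² + ε_m² τ² l²) − 4 δ_m)²
             / (ε_m τ l + √(16 δ_m² + ε_m² τ² l²)),

  with `W(0) = 0` and monotone growth in `|τ|`; `s` is the gating-scale
  factor (the conventional "8" of the 8·kB·T·N normalisation, exposed as a
  parameter since published variants of this gating model disagree on it).
* **Passive influx** `q_in,pass`: a constant calibrated at start-up so the
  unstimulated resting state is an *exact* equilibrium of the assembled
  right-hand side (with the release/restore/buffer terms individually zero
  at rest this reduces to `q_in,pass = q_out(C0)`).

Several of these closures exist in the literature in slightly different
algebraic variants; the forms above are the canonical ones from the
antecedent endothelial ATP + shear models, and each is gated behind a named
`form` switch in `atpcal.calcium` (`q_rel`: `hill3`/`hill1`; `q_res`:
`squared`/`linear`; `strain_energy`: `membrane`) so alternates can be tested
without code changes.

### Resting state

    Cb0 = k6·C0·BT / (k7 + k6·C0)          (buffering equilibrium)
    Cs0 = √(k4/k5) · C0/(K3 + C0)          (restore balances leak)
    i0  = 0                                (no agonist)

Two structural consequences, both covered by tests: the full right-hand side
vanishes at rest to below solver tolerance, and *shear alone cannot perturb
the resting state*, because the TRP influx is proportional to the store
depletion `(Cs0 − Cs)`, which is zero at rest — agonist must first engage
the store before mechanosensitive influx contributes.

### Bookkeeping identity

Store exchange and buffering only move Ca²⁺ between compartments, so
algebraically

    dC/dt + dCb/dt + (Vs/Vc)·dCs/dt = q_in − q_out

holds exactly; the test suite asserts it to rounding precision over random
states (property-based, via hypothesis).

### Numerics

The system is stiff (fast buffering and release against slow IP₃ turnover).
It is integrated with `scipy.integrate.solve_ivp` using BDF, `rtol = 1e-6`,
`atol = 1e-9`, with the stimulus series entering through linear
interpolation and `max_step` capped at 1 s so the solver cannot step over a
drive period. A 300 s run takes well under 1 s. Key outputs (first-peak
time, dominant frequency) were checked to be insensitive to tightening
`rtol` to 1e-8, switching to LSODA, and halving the stimulus and output
grids.

### Parameter profile

The model's rate constants are not pinned by any single published table; the
shipped default profile (`src/atpcal/data/calcium_default.toml`, with
per-parameter comments) was assembled from the physiological ranges used
across this model family and then calibrated *as one consistent set* so
that:

* the resting state is `C0 = 0.1 µM` with `Cs0 = 400 µM`, `Cb0 ≈ 9.2 µM`;
* the validation protocol (sinusoidal ATP peaking at 10 µM at 0.1 Hz,
  constant 0.3 Pa shear) produces a sharp first Ca²⁺ peak near 25 s
  followed by oscillations entrained at the drive frequency;
* under the chip protocol the high-ATP cell responds unimodally while the
  low-ATP pulsatile cells oscillate, and the Ca²⁺ ripple attenuates at a
  faster (0.5 Hz) drive.

During calibration the first-peak time moves in steps locked to the drive
period rather than continuously, so "near 25 s" means the drive-locked value
of ≈ 29 s with the shipped profile. Every parameter is overridable through
`default_params(**overrides)` or the YAML `calcium:` section; only one named
profile is shipped.

## 4. Coupling, classification and sweeps

Coupling is one-way: the transport field is solved once, the wall stimulus
`{φ(t), τ_w(t)}` is sampled (bilinear in space, on the snapshot time grid)
at each observation point — by default `x ∈ {1,2,3,4}·W/5` at `z = L` — and
the Ca²⁺ model is integrated per point. Cells do not feed back on the field.

**Classifier** (`classify_response`): a trajectory is *oscillatory* iff the
post-transient peak-to-peak of `C` exceeds 10 % of the trajectory's global
range *and* a dominant frequency is detected in the periodogram of the
post-transient window; otherwise *unimodal*. The transient cut is the larger
of 25 % of the record and two drive periods. Both thresholds are recorded in
every result.

**Signal metrics**: mean, peak-to-peak and dominant frequency are computed
on the post-transient window (mean-removed periodogram; no dominant
frequency is reported for a numerically constant signal);
the first-peak time uses `scipy.signal.find_peaks` over the full record with
a prominence of 10 % of the global range.

**Frequency/amplitude sweep** (`frequency_sweep`): for each
`(f_Q, δ)` cell the transport solver runs for a 10 s settling interval plus
four drive periods, and the ATP peak-to-peak at the observation point is
measured over the final three periods. A cell whose amplitude still drifts
more than 5 % between the last two periods is flagged `settled=False` rather
than failing the sweep. The sweep reproduces the channel's low-pass
character (ripple non-increasing in `f_Q`) and linear-like amplitude scaling
(non-decreasing in `δ`, ≈ 0 at `δ = 0`).

## 5. Default problem sizes and runtimes (one CPU)

| Task | Size | Wall time |
|---|---|---|
| Fill-in transient, steady flow | 64 × 256 grid, 10 s | ~2–4 s |
| Pulsatile field, 0.1 Hz | 64 × 256 grid, 60 s | ~10 s |
| Chip protocol (transport + 4 cells) | 48 × 160 grid, 200 s | ~13 s |
| Single-cell validation run | 300 s, BDF | < 1 s |
| Full test suite | 74 tests | ~90 s |

## 6. Limitations

* The transport model is depth-averaged with plug axial flow; real
  transverse velocity profiles skew the near-wall concentration slightly,
  and the quasi-steady Taylor–Aris closure is formally valid only when the
  drive period exceeds the transverse diffusion time.
* The interface boundary condition (moving linear ramp) idealises the
  upstream junction mixing; it is accurate only some distance downstream of
  the junction.
* First-order upwinding is diffusive; it is acceptable here only because the
  physical axial dispersion dominates. Do not run the `molecular` dispersion
  variant on coarse grids expecting sharp interfaces.
* The Ca²⁺ parameter profile is a calibrated representative of its model
  family, not a fitted or measured set: quantities that depend on absolute
  rate constants (peak heights, exact latencies) carry substantial
  uncertainty, while structural behaviours (entrainment, low-pass
  attenuation, response-mode pattern, homeostasis) are robust.
* The first Ca²⁺ peak time locks to the stimulus period in discrete steps,
  so small parameter changes move it by roughly a whole drive period at a
  time.
* Cells are independent and do not release ATP or deplete it from the
  channel (no autocrine/paracrine feedback).
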
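# Methods

## Spin dynamics

**CEST.** For N exchanging states the evolution matrix acts on the
3N-vector (x₁..x_N, y₁..y_N, z₁..z_N). Each state contributes a Bloch
block with offset Ω_i = 2π(ϖ_i − carrier)·ν_X (rad/s), R1/R2 on the
diagonal, and the B1 field ω₁ = 2π·b1 about x; the kinetic generator K
(K[j,i] = k(i→j), columns summing to zero) couples like components across
states. The system is homogeneous: no thermal-equilibrium inflow term is
included, so a spin irradiated far off resonance decays as exp(−R1·T_EX).
This matches the I/I0 normalization of CEST data (both I and I0 experience
the same T_EX delay) and keeps the propagation linear. The initial vector
carries the equilibrium populations on z and the observable is
z_obs(T_EX)/p_obs.

The matrix exponential is evaluated per offset through a batched
eigendecomposition (`numpy.linalg.eig` over the offset stack); any member
whose result is non-finite falls back to `scipy.linalg.expm`. Caching
never changes results beyond 1e−12; the propagator agrees with adaptive
ODE integration to a relative 1e−8 (tested on 100 random systems).

**CPMG.** Transverse magnetization is the complex N-vector M⁺ with
generator L = K − diag(R2_i + iΩ_i), offsets relative to the observed
state. π pulses are ideal rotations about x implemented as complex
conjugation. One echo is P·conj(P·M) with P = expm(L·Δ/2); two echoes
combine into the linear operator U = P·P̄·P̄·P, and a train of n pulses is
U^(n/2). The pulse count is T_relax·2·ν_CPMG rounded to the nearest even
integer; a ν_CPMG whose rounding shifts the effective frequency by more
than 1% is rejected with the admissible grid in the message. With
T_relax = 20 ms the natural grid is 50, 100, …, 1000 Hz.
R2,eff = −ln(|M_obs(T)|/p_obs)/T_relax. Finite pulse widths, B1
inhomogeneity and scalar-coupling evolution are not modelled (see
Limitations).

**Units.** Shifts are stored in ppm and converted with
ν_X = |γ_X/γ_H|·ν_H(B0), using γ_N/γ_H = 0.10136767,
γ_C/γ_H = 0.25144953 and the nominal 500/700/800 MHz ¹H frequencies at
11.7/16.4/18.8 T (γ_H·B0 elsewhere). The ¹⁵N gyromagnetic-ratio sign is
immaterial for the ppm-axis geometry and is ignored.

## Exchange models and parameterization

Models are specified by populations plus pairwise exchange rate constants
kex_ij = k_ij + k_ji; microscopic rates follow detailed balance
k_ij = kex_ij·p_j/(p_i+p_j). Fitting uses (populations, kex), never free
one-way rates, which keeps the triangular cycle thermodynamically
consistent. Five topologies are supported: two-state, triangular, linear
on-pathway (E↔I↔B), linear off-pathway (E↔B↔I) and bifurcated (I↔E↔B);
edges absent from a topology carry exactly zero rates.

Internally, minor-state populations are optimized as logit-transformed
variables (simplex-safe), rate constants on a log scale
(bounds 10–2·10⁴ s⁻¹; populations 10⁻⁴–0.2). Per-site parameters are the
major-state shift (CEST only, within ±2 ppm of the assigned dip), the
shift difference Δϖ of the first minor state, the minor–minor difference
Δϖ_BI (so a sign constraint on Δϖ_BI is a one-sided box bound, not a
penalty), R2 (log scale; tied across states or free for the first minor
state), and R1 (tied across states — minor-state R1 is unmeasurable; per
site for CEST, irrelevant for CPMG).

Initialization comes from dip positions (deepest dip → major shift,
deepest remaining local minimum → minor dip) or from caller-supplied
assignments. An optional window (`dw1_window`) keeps the first minor-state
shift within a stated distance of its assignment; this reflects practice
(the B state's shifts are known from prior two-state work) and removes the
relabelling freedom between the two minor states that otherwise creates
spurious χ²-degenerate basins.

## Optimization and uncertainties

Weighted residuals (obs − calc)/σ enter a single joint χ² across all CEST
and CPMG points. `scipy.optimize.least_squares` (trust-region reflective,
`tr_solver="lsmr"`) does the minimization with numerically estimated
Jacobians; because per-site parameters touch only their own site's
residuals, the Jacobian sparsity pattern is declared and finite
differences are grouped, making the cost per iteration nearly independent
of the number of sites. Multi-start (default 10; log-uniform redraws of
the kinetic parameters) guards against local minima; the lowest χ² wins,
ties broken toward slower exchange.

Parameter uncertainties come from the linearized covariance (JᵀJ)⁻¹
mapped to natural units by the delta method. Site-level bootstrap
(resampling sites with replacement, keeping each site's full profile set;
100 trials typical) provides empirical distributions and central 68%
intervals; a Monte-Carlo noise-redraw alternative can be built from the
generator directly. The χ²_red-vs-kex_EI scan fixes the scanned rate at
each grid point and refits everything else, warm-starting from the
nearest solved point.

## Landscape thermodynamics

With E the reference state (T = 284.65 K, R = 8.314 J mol⁻¹ K⁻¹):

* ΔG_EK = −RT ln(p_K/p_E),
* ΔG_E,TS(L,M) = −RT ln(p_L/p_E) − RT ln(k_LM/C) with C = 10⁷ s⁻¹; both
  directions are computed and asserted equal (detailed balance); C shifts
  all barriers by the same constant and cancels in any slope,
* ϕ_I = (k_EI·k_IB/(k_IE+k_IB)) / (k_EB + k_EI·k_IB/(k_IE+k_IB)), the
  steady-state branching fraction of E→B conversions routed through I.
  This equals the first-passage probability that a molecule leaving E
  enters B from I (jump-chain identity b·c/(1−b(1−c))), verified against a
  Markov-chain simulation oracle.
* m_K = −dΔG_EK/d[urea] by weighted linear regression; weights are the
  propagated ΔG uncertainties, with unit weights as fallback and a
  lack-of-fit inflation (×√χ²_red of the regression) when the scatter
  exceeds the stated errors.

Urea titrations are analyzed with reference-anchored shifts: the 0 M fit
determines every chemical shift; titration fits hold shifts fixed and
refit populations, rates and relaxation. Denaturant at these
concentrations does not move the resonances appreciably, and freeing the
shifts would re-open a population/kinetics exchange degeneracy between
the two minor states that the data cannot resolve (Δχ² of only a few over
thousands of points).

## Synthetic data

The generator reproduces the study conditions:

* **Three-state CPMG/CEST simulation study**: linear A↔B↔C with
  kex_AB = 300 s⁻¹, kex_BC = 5000 s⁻¹, p_B = 2.5%, p_C = 0.25%,
  R1 = 1 s⁻¹, R2 = 10 s⁻¹ at every site; 58 ¹⁵N sites; CPMG at 11.7 and
  18.8 T (T_relax = 20 ms, ν = 50–1000 Hz); CEST at 18.8 T with
  B1/T_EX = 17 Hz/450 ms and 35 Hz/400 ms.
* **Surrogate shift set**: the original 58 (Δϖ_AB, Δϖ_AC) pairs come from
  two folding intermediates of one domain and are strongly correlated.
  The surrogate draws |Δϖ_AB| ~ U[1,6] ppm with random sign and
  Δϖ_BC = Δϖ_AC − Δϖ_AB from a 75%/25% mixture of N(0,1 ppm) and a
  ±U[2,6] ppm tail, enforcing that at least 20% of sites have
  |Δϖ_BC| > 2 ppm. Drawing the two shifts independently instead makes the
  hidden state dominate the data and contradicts the reference outcomes
  of the study (two-state fits then land far from kex ≈ 292 s⁻¹).
* **E/B/I scenarios**: triangular kinetics kex_EB = 297, kex_EI = 170,
  kex_BI = 1667 s⁻¹, p_B = 1.5%, p_I = 0.22% (TFE variant: kex_BI = 4000,
  p_B = 2.2%, p_I = 1.8%); 11 ¹⁵N + 4 ¹³C sites by default; the measured
  B1 ladders (¹⁵N 18.1–129.6 Hz, ¹³C 16.2–98.2 Hz) at 16.4 T with
  T_EX = 0.5 s; Δϖ_EB spans ±(1–6) ppm (¹⁵N) and ±(0.5–3) ppm (¹³C);
  Δϖ_BI spans ±3 ppm with |Δϖ_BI| ≥ 0.5 ppm at half the sites (the B-dip
  broadening signature needs it). Intrinsic rates: R2 = 12 (¹⁵N) / 8
  (¹³C) s⁻¹, R1 = 1.0 / 1.5 s⁻¹ — representative values for a 19 kDa
  protein at 11.5 °C.
* **Urea series**: [urea] = 0, 1, 2, 3 M; state and barrier free energies
  shift linearly from the E/B/I reference with m_B = −0.4, m_I = +0.4,
  m_TS,EB = +0.4, m_TS,BI = +1.2, m_TS,EI = −0.2 kJ mol⁻¹ M⁻¹ (the
  landscape-to-model inversion reconstructs populations and rates from
  these free energies).
* **Noise**: Gaussian, σ(I/I0) = 0.005 and σ(R2,eff) = 0.3 s⁻¹ per point
  (attached as the uncertainty); every dataset derives from a single seed
  and serializes byte-identically.

What the generator does **not** emulate: real per-site shift tables
(supplementary-level data; scenario shifts are representative),
B1 inhomogeneity and pulse imperfections, ¹³C–¹³C scalar couplings and
¹H–¹H dipolar effects on the profile shapes, temperature drift, and
peak-picking/intensity-extraction noise structure. Passing tests therefore
demonstrate correctness of the exchange analysis given ideal two-spin-free
profiles, not robustness to those instrumental effects.

## Study problem sizes

The reference studies use 58 sites for the CPMG benchmark, 20 sites for
the CEST benchmark (fits with free minor-state R2 are the most expensive
stage), 15 sites (11 ¹⁵N + 4 ¹³C) for the CPMG-from-triangular
consistency check, and 10 ¹⁵N sites × 4 B1 fields per concentration for
the urea pipeline. Parameter-recovery suites run at 10 sites × 2 B1.
These sizes hold the full acceptance pipeline to a few minutes on one CPU
while keeping every qualitative outcome stable across seeds.

## Known limitations

* Ideal π pulses in CPMG; at ν_CPMG ≥ 1 kHz with real ~40 µs pulses,
  finite-width effects would start to matter.
* The linearized covariance underestimates uncertainties for weakly
  identified parameters (kex_EI sits in a shallow χ² valley; its barrier
  m-value inherits that softness). Bootstrap intervals are the better
  instrument there.
* Two-state label assignment between B and I in triangular fits relies on
  anchored shift assignments; fully blind three-state fitting of sparse
  data can settle in χ²-equivalent relabelled basins.
* No AIC/BIC-style model selection: discrimination is by χ²_red, matching
  the analysis protocol this package reimplements.
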
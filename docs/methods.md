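# Methods

## The model family

`fracml` implements the Morris–Lecar conductance-based neuron in a
*discrete fractional-order* setting.  The classical two-variable model is

    C du1/dt = Im − Ībar(u1, u2),
    du2/dt   = φ ℓ(u1) (w∞(u1) − u2),

with ionic current

    Ībar = WCa r∞(u1)(u1 − FCa) + WK u2 (u1 − FK) + WL (u1 − FL)

and hyperbolic gating r∞ = (1 + tanh((u1−F1)/F2))/2,
w∞ = (1 + tanh((u1−F3)/F4))/2, ℓ = cosh((u1−F3)/(2F4)).  The slow-fast
three-variable extension is dimensionless: the calcium driving force
becomes (u1 − 1), the applied current and the K⁺ half-activation are
modulated by a slow recovery variable, Im(u3) = 0.08 − 0.03 u3 and
F3(u3) = 0.08 − u3, and the slow equation du3/dt = θ(u1 + F0) closes the
loop with θ ≪ 1 (0.003–0.005 in the shipped groups).

Instead of the time derivative, each equation carries a **Caputo delta
difference** of order ϑ ∈ (0, 1]: the fractional sum (falling-factorial
convolution) of the first forward difference on the integer time scale.
The explicit solution of the initial-value problem is a memory
convolution,

    x(n) = x(0) + h^ϑ/Γ(ϑ) · Σ_{λ=0}^{n−1} [Γ(n−λ−1+ϑ)/Γ(n−λ)] f(x(λ)),

which the solver iterates directly.  Every state update therefore
depends on the *entire history* — the defining feature of the fractional
model — and ϑ = 1, h = 1 degenerates to the explicit Euler map.  In an
incommensurate system each component carries its own order and its own
kernel.

### Numerical choices

- **Kernel weights.**  The Γ-ratio weights are generated by the exact
  multiplicative recurrence c₀ = 1, c_j = c_{j−1}(j−1+ϑ)/j.  Direct Γ
  quotients overflow beyond argument ≈170 and are never used; tests
  verify the recurrence against log-Γ evaluation out to hundreds of
  terms, plus the telescoping identity Σ_{j<n} c_j = Γ(n+ϑ)/(Γ(ϑ+1)Γ(n)).
- **Step size.**  The discrete model has no explicit step (h = 1).  The
  solver exposes h with the h^ϑ scaling of the fractional-Euler family so
  that integer-order runs can be validated against a classical ODE
  integration; h = 1 reproduces the discrete model verbatim and is the
  default everywhere.
- **Memory.**  Full memory (quadratic cost) is the default.  Network
  runs default to a short-memory window of L = 500 steps; the truncation
  error decreases monotonically as L grows (tested) and L = n recovers
  the full solution bit-for-bit.
- **Divergence.**  A non-finite state aborts the run with the step index
  (and node index, for networks).  States are never clipped: clipped
  trajectories would silently corrupt bifurcation sweeps.

## Stability theory

Two criteria coexist and both are implemented:

- **Matignon (angular) criterion** — an equilibrium of the linearised
  fractional system is asymptotically stable iff every Jacobian
  eigenvalue satisfies |arg λ| > ϑπ/2.  For a 2D equilibrium with trace
  χ ≥ 0 and determinant ζ > 0 this yields the critical order
  ϑ* = (2/π) arccos(χ/(2√ζ)); χ < 0 is stable for every order and
  ζ < 0 is a saddle for every order.  For the 3D model the critical
  order is (2/π)·|arg| of the unstable complex pair of the characteristic
  cubic λ³ + ϖ1λ² + ϖ2λ + ϖ3.  This is the criterion behind all reported
  thresholds, so it is the default classifier.
- **Discrete-map criterion** — the exact stability region of the
  memory-convolution map at h = 1 adds a modulus bound:
  |λ| ≤ (2 cos((|arg λ| − π)/(2 − ϑ)))^ϑ.  The bound vanishes at the
  Matignon angle, so the discrete map loses stability slightly *below*
  ϑ* whenever |λ| > 0 — visible in the sweeps as a flip marginally below
  the arccos threshold.  The source material prints this bound with a
  leading factor 2; we drop it because the ϑ → 1 limit must recover the
  explicit-Euler interval (−2, 0) on the real axis, and because the
  printed version admits systems whose simulation demonstrably diverges.
  With the corrected constant, predictions agree with long-run simulated
  decay/boundedness on 100% of a 60-system random panel.

For incommensurate rational orders ϑι = wι/σι with H = lcm(σι), the
criterion is the root test on det(diag(ρ^{Hϑ1},…,ρ^{Hϑn}) − (1−ρ^H) J):
stable iff every root lies outside the set
K^ξ = {w : |w| ≤ (2 cos(|arg w|/ξ))^ξ and |arg w| ≤ ξπ/2}, ξ = 1/H.
The determinant is expanded symbolically (sympy) with exact integer
exponents and rooted through the companion matrix; the polynomial degree
is capped (default 600) to keep root-finding well-conditioned.

## Equilibria

2D: steady states solve Im∞(u1) = Im with Im∞(u1) = Ībar(u1, w∞(u1)).
For class-I-type parameters Im∞ has exactly one local maximum and one
local minimum, splitting the axis into three monotone branches; each
branch is searched by bracketed `brentq` after locating the folds from
the analytic derivative on a dense grid (20 001 points).  Depending on
Im this yields 1, 2 (fold), or 3 equilibria; the middle branch always
has ζ < 0 and is a saddle for every order.  Class-II-type parameters
have a monotone Im∞ and a unique equilibrium for every current — the
code detects this automatically.  3D: the slow equation pins u1* = −F0,
u3* is the unique root of a strictly decreasing scalar map (bisection),
and u2* follows from the gating.  Jacobians are differentiated
analytically from the implemented right-hand sides (and tested against
central finite differences) rather than transcribed from printed
matrices, several entries of which are typographic.

## Typographic readings resolved

The source parameter listing and equations contain several defects that
had to be resolved as design choices:

- **2D parameter groups.**  The class-I set is the C = 20 list (studied
  at Im ∈ {40, 45}, with 42/43/50/90 appearing in the time-analysis
  scans); the class-II set overrides WCa = 4.4, F3 = 2, F4 = 30,
  φ = 0.04 and is studied at Im = 100.  This matches the canonical
  class-I/class-II Morris–Lecar literature.
- **3D gating rate.**  Two readings of the cosh factor are possible.
  The textbook argument-scaled form cosh((u1−F3(u3))/(2F4)) makes the
  group-iii Jacobian purely real-spectral (no Hopf transition at any
  order), contradicting every qualitative statement made about that
  group; φ = 0.033 is simply too small.  The amplitude-scaled reading
  ℓ̄ = cosh(u1 − F3(u3))/(2F4) reproduces the full reported spectral
  classification — groups i/ii: positive cubic discriminant, one
  negative and two positive real eigenvalues (saddle of rank two for
  every order); group iii: negative discriminant with an unstable
  complex pair and critical order ≈ 0.752.  It is therefore the 3D
  default; `MLParams3D(rate_scaling="argument")` selects the other
  reading.  The 2D rate keeps the unambiguous argument-scaled form.
- **3D group iii** lists "F0 = 0."; read as F0 = 0.0.

## Networks and the reduced model

The population model couples N two-variable neurons electrically on an
Erdős–Rényi graph (edge probability p = ⟨η⟩/(N−1)); the voltage equation
of node ι receives Wε/deg(ι) · Σ_ȷ c_ιȷ (u1ȷ − u1ι) and the gating
variable is uncoupled.  Isolated nodes (possible at small p) are rewired
to one random partner so the degree normaliser is defined; rewired
indices are recorded on the spec.  Orders are assigned by partition:
first r nodes at ϑ, last s at Φ, node identity = index.  All randomness
(graph wiring, random initial conditions) flows from a single recorded
seed.

The reduced model replaces each synchronised cluster by one
three-variable slow-fast neuron; cluster ϑ is forced by
Wε ℘ε (u1_Φ − u1_ϑ) with ℘ε = s/N, cluster Φ by Wε ℘0 (u1_ϑ − u1_Φ) with
℘0 = r/N, and an optional third cluster by Wε ℘1 (u1_γ − u1_ϑ) with
℘1 = x/N, exactly in the printed sign pattern.  The third-cluster size x
is not specified anywhere; the builder defaults to N/3 and accepts any
value.  The applied current defaults to the slow-variable law Im(u3); a
constant current can be supplied instead.  Note the deliberate asymmetry
inherited from the source: the full network is 2D per node while the
reduced model is 3D per cluster — both are exposed as printed.

## Regime classification

The classifier is deterministic and threshold-based; the source defines
none of these constants, so they are package choices:

| parameter | default | meaning |
|---|---|---|
| transient fraction | 0.5 | leading fraction of the run discarded (fractional transients are long) |
| quiescence amplitude | 1.0 (u1 units) | post-transient peak-to-peak below this is quiescent; ≈1% of the ≈88-unit class-II spiking amplitude at ϑ = 1 |
| spike threshold | range midpoint | detector threshold for local maxima |
| refractory | 3 samples | minimum spike separation |
| burst gap factor | 3 | largest ISI > 3× median ISI ⇒ bursting |
| MMO peak ratio | 0.4 | split point of the peak-height range |

Mixed-mode oscillation additionally requires the small- and
large-amplitude peak families to *interleave in time* (each family
occurring both before and after the other); without this, a slowly
decaying transient ring is misread as MMO.

## What the built-in conditions do and do not show

The package's "study conditions" are the printed parameter groups and
currents, ER networks with N = 100, ⟨η⟩ ≈ 7, r = 65/s = 35, and coupling
sweeps over Wε ∈ [5·10⁻⁴, 1].  Simulated horizons in the shipped tests
are 1 500–4 000 steps (networks use short memory L = 500); these sizes
were chosen so a full analysis reproduces on a laptop-class single core
in minutes.  Passing tests demonstrate internal consistency of the
solver (against brute-force oracles), of the stability theory (against
long-run simulation), and of the qualitative regime transitions; they do
not validate the model against physiological recordings, and the ER
topology with binary electrical coupling omits synaptic dynamics,
conduction delays, and heterogeneity of biophysical constants.

## Known limitations and discrepancies

- Several worked-example values printed in the source could not be
  reproduced under any parameter/typography reading we tried: the
  class-II equilibrium voltage printed as 6.23101 (its second coordinate
  is visibly corrupted in print) — we compute a unique equilibrium at
  u1* = −23.092 for the class-II set at Im = 100 — and the class-II
  critical order printed as 0.89342, against 0.85454 computed from the
  same arccos formula at that equilibrium.  The class-I thresholds
  printed as 0.83241 and 0.96720 are reproduced to ≈2% and ≈1% at
  Im = 50 and Im = 90 respectively (the print leaves the pairing of
  thresholds to currents ambiguous; the stability report scans all
  printed currents so the pairing is transparent).
- The full-memory solver is O(n²) per trajectory and O(N n L) for
  networks; no FFT acceleration is attempted.
- Continuous-time fractional ODE solvers (e.g. Adams–Bashforth–Moulton),
  variable orders, adaptive stepping, weighted/synaptic coupling, and
  two-parameter continuation are out of scope.
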
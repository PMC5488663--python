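# Methods

## The model family

A tissue of cell mass `Z` controls its own size through a signal `y` it
senses. Two laws close the loop:

**Growth law.** Each cell proliferates at rate `λ₊(y)` and is removed at
rate `λ₋(y)`, so the mass obeys

    dZ/dt = Z · (λ₊(y) − λ₋(y)) = Z · λ(y).

Laws are sums of Hill terms `a/(1+(K/y)^n)` (increasing) or
`a/(1+(y/K)^n)` (decreasing) plus constant and linear offsets. The net
rate's zero crossings on a scan interval classify the law: one crossing is
*monophasic*, two is *biphasic* (growth negative at both signal extremes —
an inverse-U).

**Signal coupling.** Either the tissue clears its input (inhibitory,
`dy/dt = μ(M − Z·y)`, steady state `Z·y = M`) or it secretes it
(activating, `dy/dt = μ(a·Z − y)`, steady state `y = a·Z`). The paper-style
toy circuits all use the inhibitory form with `M = 25`, `μ = 0.25`. The
activating law has no printed equation anywhere; the linear relaxation form
used here is the simplest law with the right sign and a unique steady
state.

Fixed points are the zeroes of `λ` combined with the coupling relation.
Stability follows from the sign pattern of `λ` around the root together
with the coupling sign: with inhibitory coupling, extra mass lowers the
signal, so `λ` *increasing* through the root is stable. A biphasic
inhibitory circuit therefore has a stable set point `y_ST` and a higher
unstable threshold `y_UST`; the dimensionless gap

    δ = (y_UST − y_ST)/y_ST

is the circuit's *dynamic stability* — the relative perturbation range it
tolerates before a runaway collapse.

**Variants.** A logistic cap multiplies growth by `(1 − Z_tot/K_cap)`; a
sensing delay makes the growth law read `y(t − τ_d)`. Neither moves the
zeroes of `λ`, so fixed-point locations in `y` — and hence every
conclusion drawn from them — are unchanged; tests verify this and that
invasion fates are preserved.

## Mutant invasion

A mis-sensing clone with fold factor `k` reads the shared signal as `k·y`
(activating `k > 1`; an inactivating mutant described by an attenuation
factor `f` has `k = 1/f`). All clones contribute to one signal balance;
clone `i` grows at `λ(kᵢ·y)`. The selection coefficient of a rare clone is
`λ(k·y_ST)`, its initial per-capita growth rate at the resident steady
state. For an inhibitory biphasic circuit the *advantageous window* —
folds with positive selection — is `(1, y_UST/y_ST) = (1, 1+δ)`; a
monophasic circuit whose growth keeps rising with the signal has an
unbounded window: *any* activating mis-senser invades and drags the signal
below the set point.

**Frequency dependence.** Selection on strong mutants depends on who sets
the signal. The fraction grid in `frequency_dependence` (and
`germline_vs_somatic` in the beta-cell module) interpolates between the
two homogeneous steady tissues: total mass `T(f) = (1−f)·Z_ST +
f·Z_ST_mut` split `(1−f)/f`, signal at its quasi-steady value for `T(f)`,
where `Z_ST_mut` is the steady mass of a pure mutant tissue (for
inhibitory coupling `k·Z_ST`: the mutant holds the signal at `y_ST/k`).
The `f = 0` end is an adult wild-type tissue in which a somatic clone
appears; the `f = 1` end is the tissue a germline mutant develops around
its own mis-read set point. This choice was genuinely open — the
alternative of pinning total mass and signal at the wild-type steady state
makes every majority-mutant tissue collapse outright (the mutant then
senses `k·y_ST`, far past its own unstable threshold) and admits no
persistence branch at all. With the interpolation the outcome is monotone
in `f` and the elimination/persistence threshold is located by bisection.

Clone introductions are instantaneous mass resets, not birth processes;
a clone counts as eliminated when it falls below 10⁻³ of its introduction
mass within the 200-time-unit classification horizon.

## Evolutionary stability

Tissue compartments of `N` cells accumulate mis-sensing mutants through
division errors. A mutant whose proliferation/removal ratio is
`ν = λ₊/λ₋` fixes in a Moran compartment with probability
`ρ = (1 − 1/ν)/(1 − ν^(−N))` → `1 − 1/ν` for large `N`. Advantageous
mutants (sensed signal inside the window, relative width δ) arise at rate
`N·τ⁻¹·δ·μ₀` per compartment, so the probability that a compartment is
still clean at time `t` is

    ζ(t) = exp(−N·τ⁻¹·δ·μ₀·(1 − 1/ν)·t).

`τ⁻¹` is the per-cell division rate (so `λ₊ = τ⁻¹` and the recovery rate
from a perturbation is `λ₊ − λ₋ = τ⁻¹(ν−1)/ν` — the response-time side of
the tradeoff). All rates are per day; a 70-year life is 25 550 days.
`δ·μ₀` is the per-division probability of producing an advantageous
mutant, treated as constant across the window.

The stochastic Moran simulator is the brute-force check: birth
proportional to fitness, uniform death, constant `N`, one generation =
`N` steps = `1/τ⁻¹` time units, vectorised over replicates and
bit-reproducible per seed. With recurrent mutation (`u` per wild-type
birth) mutant-free stretches are jumped with geometric waiting times, and
secondary mutations during an ongoing sweep are neglected (they would
found an indistinguishable concurrent lineage; the error is O(u)). A
replicate's invasion time is the *arrival* time of the lineage that
eventually fixed, which is the event ζ(t) counts. Checked against
`1 − ζ(t)` within three binomial standard errors at five checkpoints for
three parameter sets scaled to desk size (N ≤ 150, u ≥ 2×10⁻⁴, 2000
replicates) — small enough to run in seconds, large enough that the
large-N factor `1 − 1/ν` is accurate to < 1%.

The δ↔ζ tradeoff table evaluates, per circuit: δ from the fixed points,
the advantageous-window width `k_max − 1` (= δ), and ζ(t) with the other
compartment parameters held fixed. Widening δ buys dynamic stability and
costs evolutionary stability exactly log-linearly.

## Beta-cell application

Beta cells sense glucose through glucokinase (GCK), Hill kinetics
`activity(y) = yⁿ/(yⁿ + Kⁿ)` with `K = 8.4 mM`, `n = 1.8`; at the 5 mM
set point GCK runs at ≈ 28% of maximum. Net growth is the calibrated
parabola

    λ(ŷ) = s·(ŷ − 5)·(10 − ŷ)   [per day, ŷ = sensed mM]

with the stable set point at 5 mM, the glucotoxic unstable point at
10 mM (δ = 1), and one free scale `s = 10⁻³ mM⁻²·day⁻¹` chosen to give
slow adult beta-cell dynamics while eliminating a six-fold mutant within
about three weeks. Glucose is fast relative to cell mass and is solved at
quasi-steady state from an input/clearance balance with insulin action
proportional to total GCK flux,

    u₀ = c·y·Σᵢ Zᵢ·activity(kᵢ·y),

calibrated so a wild-type tissue at reference mass sits at exactly 5 mM.
Mis-sensing applies to both the secretion and the growth arm (both are
downstream of GCK flux).

The conditional knock-in converts 25% of the mass to a `k = 6` mutant at
day 0 (the ~3-day induction ramp of the underlying experiment is not
modelled). The mutants sense ≈ 23 mM, die at ≈ 0.24/day, and are purged
to far below 5% of the induced mass by day 22. Glucose dips to ≈ 3.87 mM
and then relaxes back to 5 mM monotonically — but on the *wild-type
regrowth* timescale: the wild type itself loses ≈ 15% of its mass while
glucose is below 5 mM, and with `s = 10⁻³` its recovery rate near the set
point is ~2×10⁻³/day, so glucose re-enters the 2% band around 5 mM only
after roughly a year. A faster return would require a larger `s` and
correspondingly faster beta-cell turnover.

## Stem-cell application

Stem cells divide at `λ₊`; a division self-renews with probability
`p_r(y)` or differentiates; differentiated cells are removed at `λ₋` and
emit the signal, `y = c·Z_d`. Steady state requires `p_r = ½`. The
monophasic law `p_r = 1/(1+y)` crosses ½ once (y = 1); the biphasic law
`p_r = 1/(1+y) · 1/(1+(0.2/y)⁴)` also suppresses renewal at *low* signal
and crosses ½ twice (stable ≈ 0.997, unstable ≈ 0.224). Defaults
`λ₊ = 1`, `λ₋ = 0.5`, `c = 1` make the printed state (Z_s, Z_d) = (0.5, 1)
the monophasic fixed point. A sensing-dead mutant (senses y/16) reads
"too little tissue" forever: under monophasic control it expands without
bound and excludes the wild type; under biphasic control its sensed
signal sits below the low crossing and it is eliminated — unless
introduced at large mass, in which case its differentiation flux floods
the niche, raises `y` into the range it mis-reads as normal, and it
persists (the same frequency dependence as above, realised through
introduced mass because stem-cell tissue mass is not conserved).

## Synthetic scenarios

The stochastic schedule generator emulates the mutational input of a
compartment: Poisson clone arrivals at rate `N·τ⁻¹·μ₀` and fold-effects
from a mixture dominated by strong effects — point masses at
`k = 1/16` (sensing loss) and `k = 8` (locked-on receptor), weights
0.4/0.4, plus a 0.2-weight log-normal mild component centred on `k = 1`
(σ = 0.35) — reflecting that breaking a sensor has a much larger
mutational target than tuning it. These are modelling choices, not fits.
What the generator does *not* emulate: real mutational spectra per gene,
cell-intrinsic fitness effects unrelated to sensing, or more than one
concurrent resident genotype; passing tests show the circuit logic, not
mutation-rate realism.

## Numerics

- Integration: stiff-capable adaptive LSODA with `rtol 10⁻⁹`,
  `atol 10⁻¹²` (mass and signal timescales differ by > 10× in the
  beta-cell model). The delay variant uses fixed-step RK4 with linear
  history interpolation (step ≤ τ_d/20).
- Steadiness: largest relative state derivative < 10⁻⁸ per unit time,
  ignoring populations below 10⁻⁹ of the initial total mass (an
  exponentially dying clone would otherwise hold the per-capita rate
  finite forever). Collapse: total mass < 10⁻⁶ of its initial value.
- Root finding: 1000-point log-spaced scan of `λ` on `[10⁻², 10²]`,
  each sign change refined by Brent bisection; roots within 10⁻⁶ merged;
  roots at scan boundaries flagged.
- Quasi-steady glucose: bracketed Brent solve of the balance; the upper
  bracket expands ×10 as mass vanishes (glucose diverges in a collapse).
- Degenerate inputs: `y ≤ 0` raises a domain error; `Z = 0` is absorbing;
  `δ` is undefined (raises) unless exactly one stable and one unstable
  point exist.
- Problem sizes: Moran oracle checks use N ∈ {20, 50, 100} × 10⁴
  replicates (fixation) and N ≤ 150 × 2000 replicates (invasion curves);
  these sizes keep binomial standard errors well below the effects being
  checked while the whole suite runs in well under a minute of Moran time.

## Configs and outputs

One TOML (or JSON) file fully specifies a run, including the seed;
serialization is to JSON (round-trip tested). Trajectories are TSV with
`#`-prefixed metadata lines and 9-significant-digit floats, plus a JSON
sidecar with the outcome, final state, fixed points and per-clone fates.
Identical seeds give byte-identical outputs.

## Known limitations

- The activating-coupling signal law and the beta-cell quasi-steady
  glucose balance are reconstructions; only their sign structure and
  calibration identities (set points 5/10 mM, δ = 1) are constrained.
- No spatial structure, progenitor hierarchies, explicit insulin
  dynamics, meals, or insulin resistance; no clonal interference beyond a
  single advantageous type in the Moran model; no de novo mutation inside
  the deterministic runs.
- Bifurcation analysis is limited to root scanning on an interval; fixed
  points outside `[10⁻², 10²]` signal units are not searched by default.
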
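# Methods

## The estimator

`fretcorr` computes FRET correlation functions from within-burst photon
pairs. Each detected photon carries an indicator E (1 for acceptor, 0 for
donor). For every burst, all ordered pairs (i, j) with t_i ≤ t_j are binned
by lag τ = t_j − t_i into the four type histograms N_AA, N_DD, N_AD, N_DA
(the first letter is the earlier photon), and

g_E(τ) = (1−⟨E⟩)² N_AA/N + ⟨E⟩² N_DD/N − ⟨E⟩(1−⟨E⟩)(N_AD+N_DA)/N

with N the all-pair histogram and ⟨E⟩ the raw acceptor fraction pooled over
all selected bursts (computed once, not per burst: the per-burst estimate
would be biased by the small per-burst photon number). Normalising the pair
fractions by ⟨E⟩², (1−⟨E⟩)² and ⟨E⟩(1−⟨E⟩) gives the correlation ratios
f_XY used as a photobleaching diagnostic; the convention for two-sided plots
is f_AD at positive and f_DA mirrored to negative lags.

The key property is diffusion suppression: both N_XY(τ) and N(τ) are
modulated by the molecule's path through the Gaussian beam, but the
modulation cancels in the ratio, so g_E reflects colour (FRET) dynamics
only. The estimator assumes stationarity of the conformational process
within bursts and that all pairs of a lag bin are exchangeable across
bursts.

Conventions and edge cases: a photon is never paired with itself; two
distinct photons with equal timestamps fall in the first lag bin, ordered
by their position in the stream; bins that receive no pairs are reported as
missing (NaN), not zero, and are excluded from fits; only donor-excitation
(Dex) photons enter pair histograms. For nanosecond (nsFCS-style) analysis
an option skips pairs recorded on the same physical detector, removing
dead-time and afterpulsing artifacts.

Pair counting uses a sorted two-pointer sweep that stops at the largest lag
of interest — output-sensitive O(n + P) per burst with P the number of
pairs inside the lag window, instead of enumerating all n(n−1)/2 pairs. A
brute-force enumerator is kept as an independent oracle and the two are
required to agree bin-by-bin in the tests.

## The forward simulator

**Diffusion.** Particles perform a radial random walk in a sphere of radius
R = 3 µm centred on the detection volume:
r(t+Δt) = r(t) + 2DΔt/r(t) + Δr, Δr ~ N(0, 2DΔt). The 2DΔt/r drift makes
the 1-D radial walk equivalent to isotropic 3-D diffusion; the angular
coordinates integrate out because the beam profile is radially symmetric.
Defaults: D = 50 µm²/s (a medium-sized protein), Δt = 1 µs (0.5 µs for the
triplet scheme, whose rates are faster). A step that would cross the origin
is reflected (r → |r|); the Euler discretisation biases the stationary
density only within a few step lengths (~0.01 µm) of the origin, a volume
fraction below 10⁻⁴.

**Replenishment.** A particle is removed when it first leaves the sphere.
Every T_new = 1000 Δt, a Poisson(n_new) batch of new particles is inserted
with radii drawn from P_new(r) ∝ r² c_new(r), where c_new is the Fourier
series solution of the diffusion equation for a sphere refilling from a
constant boundary concentration over one period. The series is truncated
when the term envelope drops below 10⁻¹² (it converges like
exp(−Dn²π²t/R²)); n_new has a closed form that the tests check against
numerical quadrature to 10⁻⁶. Sampling uses an inverse CDF tabulated on
4096 points (P_new has no closed-form inverse). The scheme holds the mean
occupancy at n0 = (4/3)πR³c0; at the default c0 = 50 pM, n0 ≈ 3.4.

**Kinetics.** Conformational or photophysical states evolve as a
continuous-time Markov chain, dp/dt = Kp (column convention). Within each
time step the generator is frozen at K(r(t_k)) = K0 + I(r)K1 — the
intensity-scaled part carries photobleaching or triplet crossings — and
transitions are drawn exactly (Gillespie within the step), so rates up to
k·Δt ≈ O(1) incur no first-order bias. The recorded state of a step is the
state at its beginning. For position-independent generators a fast path
simulates global dwell times and fills state runs directly.

**Emission.** Per step, photon counts are Poisson with means
a_i ε_i I(r) Δt (acceptor), d_i (1−ε_i) I(r) Δt (donor), with
I(r) = exp(−2r²/w0²), w0 = 0.4 µm. Brightness pairs (a_i, d_i) encode the
γ factor (a/d) and are scaled so the equilibrium-averaged total detected
rate at the beam centre is λ_tot = 0.4 MHz. Direct acceptor excitation adds
α a_i I(r) for acceptor-intact states; crosstalk reassigns each photon's
channel with probability β_DA (donor→acceptor) or β_AD (acceptor→donor);
backgrounds are uniform Poisson streams over the whole record (2 kHz donor,
1 kHz acceptor by default). Arrival times are uniform within a step —
consistent with the piecewise-constant intensity, and irrelevant above the
coarse-grained timescale. With pulsed interleaved excitation (PIE), an
acceptor-excitation photon stream with per-state rate (total Dex
rate)/γ_PIE is added for acceptor-intact states, and nanotimes are the
pulse offsets plus optional Gaussian IRF jitter folded into the 50 ns
period. Intensity and emission work is skipped beyond r = 3.75 w0, where
the excitation probability per step is below 10⁻¹².

**Default imperfections** (the "realistic" instrument): γ = 1.15,
β_DA = 0.05, β_AD = 0.003, α = 0.048, backgrounds 2/1 kHz. The ideal
instrument (γ = 1, everything else zero) is used where model-based fits are
benchmarked, so that apparent and corrected efficiencies coincide.

**Photobleaching.** The four-state scheme {D, DA1, DA2, A} combines
conformational exchange DA1↔DA2 at rate k (default 3·10⁻³ µs⁻¹) with
intensity-proportional bleaching: the acceptor bleaches from state i at
k_A ε_i (→ D) and the donor at k_D (1−ε_i) (→ A), with
k_A = k_D = 8·10⁻⁴ µs⁻¹ at the beam centre — bleaching proceeds from the
excited state that the FRET efficiency populates. Initial state
probabilities (0.1, 0.4, 0.4, 0.1).

**Coarse-grained triplet photophysics.** Nanosecond singlet kinetics are
folded into per-state emission rates over the four µs-scale states
{SS, TS, ST, TT} (donor/acceptor singlet-or-triplet manifolds); TT is dark.
S→T crossing rates scale linearly with the excitation rate
(k_ex = 0.08 ns⁻¹ at the centre, following the beam profile), T→S rates are
constant — so the scheme maps onto the same K0 + I(r)K1 machinery. The
bundled rate constants (triplet lifetime 3 µs, crossing rate 0.02 µs⁻¹ at
full excitation) are illustrative values representative of green/red
organic dye pairs, not a fitted characterisation of a specific pair;
measured constants can be supplied through `CGPhotophysicsModel`.

**Reproducibility.** Every particle draws its track, state path and photon
stream from independent substreams spawned from the master seed, so a run
is bit-reproducible and one particle's trajectory does not depend on how
many others exist.

## Burst processing

Bursts are maximal photon runs with inter-photon gaps below 50 µs that
contain at least `min_photons` photons (default 100; the likelihood
benchmarks use 50 and the bleaching scheme 75). The gap criterion is the
simplest reproducible rule for the burst searches that practice describes
only loosely. Corrections are applied in the community-standard order:
background (rate × duration) first, then spectral crosstalk in both
directions, then acceptor direct excitation — via α n_AA when PIE data
exist, else the proxy α(n_DD + n_DA) — and γ only in the efficiency
denominator, Ẽ = n_DA/(γ n_DD + n_DA). Negative intermediate counts are
floored at zero and flagged. Donor-only bursts end up at Ẽ < 0 after the
direct-excitation correction, which is what makes them excisable on the Ẽ
axis; with PIE they are removed by the stoichiometry window
S = (n_DD+n_DA)/(n_DD+n_DA+γ_PIE n_AA) ∈ [0.25, 0.75], and mid-burst
acceptor bleaching by the burst asymmetry α_PIE = ⟨t_Dex⟩ − ⟨t_Aex⟩ with
|α_PIE| ≤ 0.1 ms (0.05 ms as the stricter option). Correlation-ratio
diagnostics are computed after donor-only removal; the bleaching signature
(rising f_DD, falling f_AA, f_AD/f_DA asymmetry) is otherwise masked by the
donor-only population.

## Model-based counterpart

**Likelihood.** The photon-by-photon log-likelihood of a burst is the
matrix product of per-photon detection operators V_A = diag(a_i ε_i + b_A),
V_D = diag(d_i(1−ε_i) + b_D) interleaved with propagators
exp((K−N)τ) (N = diag of total rates), seeded with p_eq and closed with a
summation vector. The propagated vector is renormalised to unit sum after
every photon with log-accumulation — products over hundreds of photons
would otherwise underflow. The general n-state path uses the
eigendecomposition of K−N; the two-state fitting path uses the closed-form
propagator in a compiled kernel. Fits optimise (log k, logit ε₁, logit ε₂,
log n) with bounded L-BFGS and five seeded restarts; the reported labels
are ordered ε₁ < ε₂. The BIC is R ln T − 2ℒ with T the total photon count
across bursts — the information-bearing length of the data (the
alternative, total duration, only shifts all BICs by a constant for fits on
the same data).

**Recoloring.** Goodness of fit is assessed by redrawing photon colours:
a state trajectory of the fitted chain is simulated at the original
detection times (exact transition probabilities between photons) and each
photon becomes an acceptor with probability ε(state). Ten recolorings give
a mean ± SD band for histograms and correlation functions; a hidden-state
(non-Markov) system shows up as a systematic long-lag excess of the data's
g_E over the recolored band, quantified in the tests as the z-score of the
summed excess over lags 0.3–1.2 ms.

**Analytic theory.** For diagonal detection matrices the pair correlations
are g_XY(τ) = 1ᵀV_X e^{Kτ} V_Y p_eq (the later photon acting last), and the
measured g_E follows by the same combination as the estimator with the
analytic ⟨E⟩. For two-state models without background this reduces exactly
to closed forms in which g_E is g_ε times a weakly τ-dependent factor —
verified to 10⁻¹² against the matrix route. These closed forms quantify the
robustness of relaxation times to brightness imbalance.

**Apparent relaxation times of analytic curves** are read off by least
squares on ln g over the lags where the curve exceeds 1% of its initial
value, i.e. equal weight per decade of decay. This is the natural reading
for a function that is exponential up to a weak amplitude distortion; an
unweighted linear-space fit concentrates all weight at the earliest lags,
where the brightness-induced second harmonic lives, and roughly triples the
apparent timescale distortion. The result is stable for cutoffs between
0.1% and 1%. With this definition, the maximum deviation of the apparent
relaxation time is ≈ 5.9% for detection-factor imbalance γ ∈ [0.1, 10] and
≈ 8.9% for state-dependent brightness over two decades (equal populations,
ε = 0.1/0.9).

**Error bars for fitted decay times** come from a burst-resampling
bootstrap: pairs within one burst are strongly correlated, so per-pair
shot-noise weights understate the uncertainty by large factors. Bursts are
resampled with replacement, ⟨E⟩ recomputed per resample, and the spread of
refitted log relaxation times is the quoted σ.

## Problem sizes

The test suite and acceptance script simulate 30–180 s of experiment per
scenario (one to two hundred up to ~1300 bursts), the package's choice of
statistics at which every asserted effect is resolved: rate recovery across
k ∈ [5·10⁻⁵, 0.1] µs⁻¹ within the bootstrap error, the static-heterogeneity
plateau at (E₂−E₁)²/4 with its concentration-induced decay (fitted decay
times ~15 ms at 50 pM falling monotonically toward ~3.5 ms at 500 pM), the
photobleaching asymmetry and its two-fold reduction by PIE filtering, the
triplet decay of the coarse-grained scheme, and a residual diffusion
artifact below 0.002 for a single-state emitter. The slowest rate in the
scan runs at 25 pM, where the multi-molecule decorrelation (which affects
any estimator at high concentration) does not overlap the 10 ms
conformational decay.

## What the simulator does and does not emulate

It emulates Poisson photon statistics above the fluorescence-lifetime
timescale, diffusion through a radially symmetric Gaussian volume,
state-dependent brightness, crosstalk, direct excitation, background, PIE,
intensity-dependent photobleaching and coarse-grained triplet blinking. It
does not emulate photon antibunching (no sub-lifetime physics), anisotropic
(elongated) confocal volumes — the aspect-ratio factor appears only in the
nsFCS fit model — detector dead time and afterpulsing (handled at analysis
time by the same-detector pair exclusion), polarisation, or dye saturation
beyond the coarse-grained level. Tests passing on these simulations
therefore validate the estimator and the fitting machinery under the model
assumptions; they do not certify behaviour under photophysics the generator
omits, most notably uncharacterised dye dark states whose rates are not
supplied.

## Known limitations

* The radial simulation cannot represent different detection volumes for
  donor and acceptor; their residual effect on g_E is not reproduced here.
* Apparent relaxation times carry an O(τ_D/T) finite-burst-length bias
  (a few percent when the relaxation time approaches the burst duration).
* The likelihood fitter ships with a two-state model family; the likelihood
  and recoloring engines accept arbitrary kinetic models, but multi-state
  fitting templates (and their identifiability analysis) are not provided.
* CG triplet amplitudes depend on the supplied photophysical constants; the
  bundled defaults reproduce the qualitative fast decay with amplitude
  below 0.02, not a specific dye pair's numbers.
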
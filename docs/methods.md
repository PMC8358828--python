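# Methods

`tddcs` simulates time-domain diffuse correlation spectroscopy (TD-DCS)
measurements of layered tissue and ranks time gates by their ability to
monitor deep (cerebral) blood flow. This note records the model, the
defaults and the judgment calls.

## Physical model

**Geometry.** The head is a laterally infinite slab of plane layers.
The packaged default has five: skin (4 mm), skull (7 mm), CSF (3 mm),
gray matter (4 mm) and semi-infinite white matter, so the
surface-to-cortex distance is 14 mm, typical of an adult forehead. Only
the 14-mm total is anatomically constrained; the 4/7/3 split is a
configurable choice. A reduced two-layer slab (10 mm scalp-like layer
over semi-infinite brain-like medium) is used for the qualitative gate
studies, and a homogeneous semi-infinite medium stands in for the liquid
phantom. Optical properties (μa, μs′ per wavelength at 765 and 1064 nm)
are literature values; skull absorption is 1.22× skin; every layer uses
g = 0.9 and n = 1.4, with transport scattering μs = μs′/(1−g).

**Transport.** A custom Monte Carlo kernel launches a pencil beam at the
origin, samples exponential steps per layer, deflects by
Henyey–Greenstein, and applies Fresnel reflection only at the exterior
surface (internal indices are equal). For every packet that exits inside
the detector the per-layer path length L_i (mm) and per-layer momentum
transfer Y_i = Σ(1−cos θ) are recorded. Absorption is **never** applied
during transport: packets carry unit weight and the factor
exp(−Σ μa,i L_i) is applied analytically afterwards, so one transport
run serves every absorption and flow scenario. Packets exceeding a
time-of-flight cap (default 5000 ps) are dropped; the absorption-weighted
fluence beyond the cap is negligible for the packaged media. Random
numbers come from a per-photon splitmix64 stream keyed by (seed, photon
index), so results are reproducible and independent of chunking.

**Detector.** The physical probe is a 1-mm circular detector 10 mm from
the source. Because the slab is laterally symmetric, an annular detector
(|r − sd| ≤ radius) has identical path-length statistics while
collecting ≈ 2π·sd/diameter (~60×) more photons; the heavy test and
reproduction runs use the ring, and analytic comparisons then use the
annulus-integrated diffusion solution. The disk remains the default.

**IRF and gating.** Instrument response functions are delta, Gaussian
(FWHM), Gaussian-plus-exponential-tail mixtures (standing in for
red-enhanced detectors with charge-diffusion tails), or measured
two-column histograms. Each IRF is shifted so its mode is at 0 ps;
apparent time of flight = tissue ToF + one inverse-transform draw per
photon. The overall TPSF is the absorption-weighted histogram of
apparent ToFs (10-ps bins by default; the peak is located after a 3-bin
moving average to stabilize the argmax under Monte Carlo noise). A time
gate is [peak + start, peak + start + width) on apparent ToF; gated
photons keep their *tissue* path and momentum-transfer histories.

**Correlation.** For a gated photon set,
G1(τ) = Σ_n w_n exp(−2k0²τ Σ_i Y_{n,i} D_i) with w_n the absorption
weights and D_i the per-layer Brownian diffusion coefficients (the
blood-flow index, BFi); ⟨Δr²⟩ = 6Dτ. g2 = 1 + β|g1|² (Siegert). The
coherence factor β of a gate follows from its fluence-weighted
path-length distribution P(L) and the laser coherence length Lc:
β = ΣΣ P(L)P(L′)exp(−2((L−L′)/Lc)²). For a transform-limited Gaussian
pulse, Δν = 0.441/FWHM and Lc = (c0/n)/(πΔν) — 4.6 cm at 300 ps; the
variant that first deconvolves a 90-ps detector response is available
but not the default, matching the non-deconvolved figure. Fixed Lc
values of 5 cm (unshaped) and 4 cm (shaped pulses) are appropriate when
emulating measured systems.

**Noise.** Per-lag σ(τ) of the g2 estimate follows the Koppel-form
photon-correlation noise model with prefactor √(T/t) (the only
dimensionally consistent reading; the middle speckle term is grouped per
the standard form and pinned by a unit test). Γ is extracted by a line
fit of ln g1 over lags with g1 > 0.3 — the model needs a single decay
rate although the multi-path g1 is not purely exponential. The
correlator bin width defaults to T = 1 μs with a multi-tau-style
pseudo-logarithmic lag grid up to 1 ms; noise is drawn independently per
lag. Defaults emulate a 1-s integration repeated 120 times (a 2-minute
measurement), with total detected rates of 600 kcps (765 nm) and 4 Mcps
(1064 nm) at the regulatory power limits.

**Inversion.** Homogeneous-equivalent (μa, μs′) come from fitting the
TPSF to the time-resolved semi-infinite diffusion reflectance
(extrapolated boundary; internal-reflection parameter A(1.4) ≈ 2.95) in
log space over the window from the 50% rising edge to the 1% falling
tail. Log residuals weight the decades of the decay evenly; a
linear-scale fit is dominated by the peak, where transport and diffusion
theory disagree most at a 10-mm separation. Gated g2 curves are then
fitted for (BFi, β) against g1 evaluated on Monte Carlo histories of the
homogeneous medium re-gated through the same IRF/gating pipeline —
Levenberg–Marquardt in log-parameter space from a 2×2 grid of starts
(BFi ∈ {1e−6, 1e−5} mm²/s, β ∈ {0.3, 0.6}); the least-residual start
wins. The fit uses the lags where the noiseless g2 keeps ≥ 1% of its
contrast, capped at 1 ms. Per-photon decay coefficients are binned into
≤128 weighted atoms for speed; the compression is exact in the
uncompressed limit and tested against the direct sum.

**Metrics.** Intrinsic (deep-flow) and superficial (scalp crosstalk)
sensitivities are computed from noiseless fits of the baseline and
20%-perturbed conditions; CNR divides the brain-flow contrast by the
standard deviation of 120 noisy baseline fits, with the coefficient of
variation floored at 0.1 (physiological noise observed in vivo — applied
to the baseline series); FoM = CNR/(superficial sensitivity/100), with
the superficial denominator floored at 1% so noise-level crosstalk
cannot produce unbounded FoM (floored cells are flagged). Per-cell RNG
substreams make the grid reproducible cell by cell; cells with fewer
than 200 gated photons are masked.

## What the synthetic data does and does not emulate

The slab generator reproduces the layered optics, the 14-mm (or +3 mm
thickened) extracerebral depth, the baseline dynamics (skin 1e−6, brain
6e−6 mm²/s, static skull/CSF) and the canonical 20% perturbations. It
does **not** reproduce curved anatomy, probe wrapping, voxelized
MRI-derived geometry, heterogeneous layer boundaries, or measured
instrument IRFs — so passing tests demonstrate the *mechanics and
qualitative physics* of gate optimization (sensitivity grows with gate
start, β falls with gate width, tailed IRFs leak early photons and cap
sensitivity, thickening lowers FoM without moving the optimal gate), not
the absolute sensitivity or FoM values a full head model would give.
Desk-scale photon budgets (10⁶–10⁷ launched versus billions for a
production study) were chosen so a full run completes on one CPU in
minutes; they leave a few-percent Monte Carlo scatter in per-gate
sensitivities.

## Numerical choices and degenerate inputs

* Transport: exterior index 1.0; specular entry loss ignored (scale-free
  since absorption is analytic); CSF-like layers use their (near-zero)
  μs′ directly with no void-region special casing — a documented
  limitation at very low scattering.
* TPSF fitting requires ≥ 20 informative bins; flat or empty TPSFs raise
  instead of returning garbage. Recovered properties outside broad
  physical bounds are rejected.
* Empty gates (below the configurable member minimum) raise an explicit
  empty-gate signal; sweep cells inherit it via the mask.
* β computations require P(L) normalized to 1e−6; Lc = ∞ is the
  full-coherence sentinel.
* The noise model guards ΓT over/underflow with expm1/clamping; σ > 0
  for all finite parameters.
* Fits flag non-convergence and parameter-bound pinning rather than
  failing a whole series; a corrupted curve yields one flagged element.

## Known limitations

* At a 10-mm separation with μs′ρ ≈ 4 (the phantom), transport and
  diffusion theory genuinely disagree near the TPSF peak; recovered
  homogeneous-equivalent μa carries a ~20% bias there (the high-scatter
  head-like case recovers within ~5–10%). This is a property of the
  diffusion approximation, not of the kernel — at μs′ρ ≥ 10 the
  Monte Carlo/diffusion ratio is flat within statistics.
* The homogeneous fitting model inherits whatever bias the TPSF property
  fit has; sensitivities are ratios of fitted BFi values and are largely
  insensitive to it.
* Lag–lag noise correlations are ignored (independent Gaussian noise per
  lag), consistent with the additive-noise model being emulated.
* Gated-detector turn-on transients, dead time and afterpulsing are out
  of scope.
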
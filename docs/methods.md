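# Methods

This note documents the models implemented in `protongate`, the
conventions and defaults that matter, what the synthetic generators do
and do not emulate, and the numerical choices made where the design was
genuinely open.

## Water-wire shortest path

A frame's water oxygens form an undirected graph. The edge cost between
oxygens at distance r is

    w(r) = 1 + exp(α·(r − r₀)),   r₀ = 3.0 Å,  α = 5.0 Å⁻¹,

chosen to be ≈ 1 for hydrogen-bonded pairs (r < r₀, the typical O–O
separation of hydrogen-bonded water) and to grow steeply beyond. Only
the qualitative shape of this cost is fixed by the physics; the
exponential-barrier form above is this package's default, registered in
`EDGE_WEIGHT_FORMS` so alternatives can be plugged in. A virtual SOURCE
node connects to every water with the cost of its *minimum* distance to
any source atom (both carboxylate oxygens of the donor glutamate are
source atoms, so the nearer one sets the cost); a virtual SINK connects
via the distance to the destination point (the midpoint when the sink
selection resolves to two atoms). Pairs beyond r_cut = 8 Å get no edge,
except that the direct SOURCE–SINK edge is always added when the graph
would otherwise be disconnected, so S stays finite and frames remain
comparable. Minimum-image distances are used for orthorhombic boxes
only; triclinic boxes are rejected.

S is the minimum total edge weight SOURCE→SINK (Dijkstra; all weights
exceed 1). Equal-weight routes are broken toward the lexicographically
smallest node sequence (SOURCE < water indices < SINK) for determinism.
log S is the natural logarithm, stated in output metadata. A small S
(log S ≈ 2 for a six-edge hydrogen-bonded chain) means a connected,
proton-hoppable wire; one broken gap of ~6 Å raises log S by α·Δr ≈ 15.
The wet-fraction statistic is simply the fraction of frames below a
user-chosen log S threshold placed between the two modes.

## Gate distances and the softmin

Per frame, the gate metric between two side chains is the minimum over
all hydrogen–hydrogen distances (exact, self-pairs excluded), or the
smooth softmin used by CV engines:

    plumed_min:  β / ln Σᵢ exp(β/dᵢ)
    exp_softmin: −(1/β) ln Σᵢ exp(−β·dᵢ)

Both approach the hard minimum as β → ∞ and are evaluated with the
maximum exponent subtracted (no overflow). β carries the same units
convention as the distances: β = 500 is sharp for nm-scale distances;
Å-scale users should rescale (β ≈ 5000 for equivalent sharpness), and a
warning is emitted when β/min(d) < 20. Hydrogens are identified by the
element field when present, else by the leading letter of the
digit-stripped atom name.

Trajectory series report mean ± SD (ddof = 1) along the trajectory;
pairwise comparisons use Welch's two-sided t-test with the conventional
star labels (* p < 0.05, ** p < 0.01, *** p < 0.001). Two zero-variance
series with unequal means are reported at the machine floor with a
degeneracy flag rather than a spurious finite p.

## ZZ-exchange rate

For symmetric two-site exchange at rate k with shared longitudinal
relaxation R₁ and reference intensity I₀, the auto and cross peak
intensities at mixing delay t are ½(1 ± e^(−2kt))·e^(−R₁t)·I₀. The
composite ratio

    I_AB·I_BA / (I_AA·I_BB − I_AB·I_BA) = (1−ε)²/(4ε),  ε = e^(−2kt)

is scale-free and relaxation-free, and equals k²t² to second order in
kt (relative error 0.33% at kt = 0.1, ~3% at kt = 0.3). The fitter
pools all residues' ratios ("composite"; a per-residue-then-average
mode is provided for comparison) and fits ratio = k²t² by least
squares. Points whose fitted k·t exceeds 0.5 are excluded once and the
fit repeated — the small-kt model is a truncation, and the cap bounds
its bias below ~5% while the 2% intensity noise dominates. Quartets
with a non-positive denominator (exchange too fast for the delay) are
excluded with a logged reason. Uncertainty is reported two ways, since
either convention appears in practice: the nonlinear-fit covariance SD
and, when ≥ 4 residues are present, a residue-level bootstrap SD
(200 resamples).

## Global titration fit

In the NMR fast-exchange limit each titrating site moves a resonance
along the population-weighted average shift. With Hill coefficient
fixed at 1 (standard single-site protonation):

    δ(pH) = δ_end + Σⱼ Δδⱼ · 10^(pKaⱼ−pH) / (1 + 10^(pKaⱼ−pH)).

The global model shares one or two pKa values across every
residue/nucleus curve; each curve keeps its own endpoint and
amplitudes. Because the amplitudes enter linearly, they are profiled
out exactly (weighted linear least squares per curve), and the search
runs over the pKa values alone: a multi-start grid (4.5–9.0, step 0.5,
ordered pairs) followed by Nelder-Mead refinement in an ordered
(pKa₁, log-gap) parameterization that prevents label switching. A final
full Levenberg-Marquardt pass over all parameters supplies the
covariance-based pKa uncertainties. Residuals are weighted by the
per-point error when given, else by per-nucleus defaults (0.01 ppm ¹H,
0.05 ppm ¹⁵N). A fit landing on the grid boundary is flagged in the
diagnostics.

Model comparison between the 1- and 2-pKa fits uses the
extra-sum-of-squares F-test (p < 0.05 prefers the richer model) plus
AIC, and requires byte-identical input data (checksummed).
pKa-sensitivity classification pools nuclei per residue as
√(Δδ_H² + (w·Δδ_N)²) with nitrogen weight w = 0.2 — the usual
chemical-shift-perturbation convention, exposed in the call — and
labels residues low_only / high_only / both / insensitive against a
minimum composite amplitude (default 0.05 ppm).

## Umbrella sampling, WHAM and the PMF pKa

The transport coordinate is x = d_OC · e_PT: the vector from the nearer
donor carboxylate oxygen to the center of excess charge, projected onto
the unit transport direction (the unit vector is checked, never
silently normalized).

WHAM bins all window samples on a common grid (default bin width
0.1 Å over the sampled range — fine enough to resolve kcal-scale
features without empty-bin fragility) and iterates the standard
self-consistent equations for the unbiased density and per-window free
energies f_i until max|Δf_i| < 10⁻⁸ kcal/mol (default; max 10⁵
iterations, non-convergence raises with the Δf history). W(x) =
−kT·ln ρ(x) is anchored to min 0 over sampled bins; empty bins are NaN.
Adjacent windows sharing < 5% histogram overlap trigger a warning —
poor overlap is the dominant error source in stitched PMFs, and the
per-link stitching error accumulates as a random walk along the
window chain. Per-bin uncertainties come from a contiguous 5-block
analysis (each window's sample sequence split in order, WHAM per block
on the shared grid, SD across re-anchored block PMFs).

The PMF is defined up to an additive constant, so all comparisons are
shape comparisons after anchoring. The pKa conversion removes the
constant explicitly: with W_bulk the mean PMF over a bulk reference
range (default the outermost 2 Å of the sampled range, where a
transport PMF plateaus),

    K = C° · π·r_cyl² · ∫_site exp(−[W(x) − W_bulk]/kT) dx,
    pKa = log₁₀ K,

integrated by the trapezoid rule over the site range. C° = 1/1661 Å⁻³
is the standard concentration. r_cyl (default 2.5 Å) is the radius of
the cylinder sampled orthogonally to the transport axis; it is a
stated convention, not a fitted quantity — the square-well closed form
K = C°·π·r_cyl²·L·e^(W0/kT) shows the dependence explicitly
(≈ ±0.3 pKa units per factor of two in r_cyl). kT defaults to
0.616 kcal/mol (310 K, a typical membrane-simulation temperature).

## Assay processing

Pyranine traces are normalized to their first recorded value; the
divisor is kept in metadata. Paired no-gradient traces are subtracted
pointwise on the transport grid (linear interpolation when grids
differ; refusal when spans differ by > 10%), preserving the nonzero
first point — it carries the pH change that occurs in the acquisition
dead time. The leak time course is fit to burst + A·(1 − e^(−rate·t))
with rate ≥ 0; the burst is modeled as an instantaneous offset because
the dead time is short compared with the fitted kinetics (a modeling
choice — no functional form for the burst phase is implied by the
data). A flat trace yields an unidentifiable rate and is flagged, not
rejected. Calibration of fluorescence to absolute pH is deliberately
not implemented (it requires a calibration curve); outputs stay in
normalized units.

SSME current traces are baseline-corrected by the mean current over the
final 100 ms of buffer equilibration before perfusion (half-open window:
the sample at perfusion onset belongs to the transport phase) and
integrated by the trapezoid rule over the perfusion window; nA·s = nC.
Replicate groups are compared with raw pairwise Welch two-sided t-tests
(matching the usual reporting convention); Holm correction is available
behind a flag.

## Synthetic generators

Every generator draws from one explicit `numpy.random.default_rng`
stream per call and records its ground truth in table `attrs`/JSON
sidecars or trace metadata — never in the data columns. Identical
configurations are byte-identical after serialization, and zero-noise
outputs satisfy their closed-form models to ≤ 10⁻¹² relative error.
Noise models: multiplicative Gaussian for peak intensities (intensity
errors scale with signal), additive Gaussian for chemical shifts and
assay traces.

Preset conditions:

- `zz_low_pH` / `zz_high_pH`: true rates 4 and 17 s⁻¹; 5 and 4
  residues; 8 delays spanning 0.01–0.2 s and 0.005–0.1 s; R₁ =
  1.5 s⁻¹; 2% multiplicative noise. The noise level is a plausible
  synthetic choice (peak-intensity noise is not otherwise determined);
  it sets the recovered-rate uncertainty scale.
- `tpp_titration`: true pKa 5.6 and 7.1; 12 residues × (¹H, ¹⁵N) on a
  12-point pH grid 4.5–9.0; noise 0.01 ppm H / 0.05 ppm N; amplitude
  design 4 residues low-only, 4 high-only, 4 both, alternating sign,
  with ¹⁵N amplitudes ~6× ¹H (typical CSP magnitudes).
- `pmf_toy`: double-well truth W(x) = h·(u²−1)², u = (x−5)/5, barrier
  h = 3 kcal/mol at x = 5, minima at 0 and 10 Å; 21 windows 0–10 Å,
  κ = 40 kcal/mol/Å², 2000 i.i.d. samples per window, kT =
  0.596 kcal/mol. Samples are drawn by inverse-CDF on a 10⁻³ Å grid so
  they are exactly Boltzmann-distributed and independent, which makes
  recovery tolerances analyzable. Note the window spacing is ~4σ of
  the biased distributions (σ = √(kT/κ) ≈ 0.12 Å), i.e. adjacent
  histograms overlap by only ~4% — the stitching-noise regime the
  overlap warning flags; recovery RMSD at these conditions is
  ~0.1–0.25 kcal/mol depending on the random draw.
- `wt_leak` / `d107_leak` (pyranine): leak rates 0.0012 vs 0.008 s⁻¹,
  amplitudes 0.15 vs 0.35, bursts 0.02 vs 0.06, noise SD 0.002·F₀, 30
  min at 5 s sampling — a slow-leaking wild type versus a
  fast-leaking truncation mutant, with the no-gradient pair flat at F₀.
- `wt_ssme` / `d107_ssme`: biexponential perfusion currents
  (τ = 0.05/0.4 s) with ~3× amplitude ratio between constructs and the
  analytic transported charge recorded.

What the generators emulate is the statistical structure of each
measurement, not the physics behind it: chains of water oxygens with
wet/dry gap states rather than real trajectories (no lipids, no
protein, no hydrogen-bond angles); intensity quartets and shift curves
rather than spectra (no lineshapes, no peak picking); i.i.d. Boltzmann
samples rather than correlated MD (real umbrella data adds
autocorrelation, which inflates WHAM errors relative to the synthetic
case); and smooth burst+exponential traces rather than instrument
artifacts. Passing recovery tests therefore certify the estimators —
that the fits extract what the models put in, at realistic noise —
not the simulation or measurement physics upstream of them.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic
data at the preset sizes above (hundreds of frames, tens of peak
quartets, 24 titration curves, 21 × 2000 umbrella samples), which this
package treats as its reference conditions for recovery statements;
everything completes in a few minutes on one CPU.

## Known limitations

- The edge-cost function reproduces the qualitative specification of
  the water-path metric (≈ 1 below r₀, rapid growth above), not any
  particular prior implementation of it.
- Whether a source with two donor oxygens should use the minimum
  distance or the midpoint is a convention; the minimum is implemented
  (both oxygens connect to the virtual node).
- Eq.-style k²t² fitting is a small-kt method: rates are recoverable
  only where delays satisfy k·t ≲ 0.5 after exclusion, and the
  high-rate regime leans on the shortest delays.
- The 1-D PMF pKa depends linearly on the assumed orthogonal sampling
  area (π·r_cyl²); absolute pKa values inherit that convention even
  though PMF-offset invariance is exact.
- No MBAR, no 2-D WHAM, no binary trajectory formats (XTC/DCD), no
  lineshape or liposome-physics modeling; CEC positions are inputs,
  never computed from electronic structure.
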
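# Methods

This note records the models, conventions, default parameters and numerical
choices behind each module, and what the synthetic-data round trips do and
do not demonstrate.

## Mass bookkeeping

Every mass is the dot product of an elemental composition with one of two
atomic-mass tables: IUPAC 2021 standard atomic weights (average scale) or
principal-isotope masses (monoisotopic scale). In-chain DNA residues are
nucleoside-5′-monophosphates minus water; a 5′-OH terminus removes one HPO₃
from the chain, a 5′- or 3′-phosphate keeps/adds it, and one water closes
the chain. Peptides are residue compositions plus water, with the
C-terminal amide as −O +N +H. Shipped modification deltas are elemental
formulas: 8-bromo-dG (+Br −H on dG), the C8-alkyne (octadiynyl) handle
(+C₈H₈ on dC), azido-lysine (−NH₂ +N₃, i.e. +N₂ −H₂). The registry is
extensible at run time.

Conventions that matter:

* Default scale **average**; the scale is an explicit argument everywhere.
  Vendor-quoted theoretical masses for the study strands mix conventions
  (one strand matches the average-scale value to 0.02 Da, another sits
  ~1 Da off on either scale), so the test suite requires agreement within
  1.5 Da on at least one scale and never tighter.
* Negative-mode ESI only: m/z = (M − z·m_H⁺)/z with m_H⁺ = 1.007276 Da
  (monoisotopic) or 1.00739 Da (average-scale convention). No adducts, no
  isotope envelopes.
* Sequences 5′→3′, positions 1-based inclusive; synthetic oligos default to
  5′-OH/3′-OH (vendor chemistry).

## DNase I digestion and footprinting

DNase I hydrolysis yields 5′-phosphate/3′-OH products, so every internal
fragment end carries that chemistry while ends coinciding with the parent
termini inherit the parent chemistry; cutting adds exactly one water, and
the fragment masses satisfy mass(left)+mass(right) = mass(whole)+mass(H₂O)
for every split (tested exhaustively on a 10-mer).

Peak assignment predicts m/z for every (fragment, charge) pair with z in
1..6 (configurable) and retains candidates within a signed ppm tolerance,
default 25 ppm — appropriate for a QTOF-class instrument. Fragments with
identical elemental composition are indistinguishable at any charge; such
isobars form an ambiguity group and an assigned peak's area is split
equally among its candidate fragments. This equal split is a known
limitation: on a uniform digest it redistributes a few percent of profile
mass between bonds (the test suite bounds this smearing at 0.04 per bond).
Because bound and free samples smear identically, log2 ratios are much less
affected than the profiles themselves.

The per-bond profile deposits each internal fragment end's area on the bond
whose cleavage produced it (bond p lies between residues p and p+1); the
per-length profile aggregates by fragment size, the analogue of a gel
ladder axis. Protection scores are log2((bound+ε)/(free+ε)) with pseudocount
ε = 1/(10·n_bonds); the protected window is the longest maximal run of
bonds below −1.0 with at least 3 bonds, ties broken by the more negative
mean. With the study's target strand the GCRE half-site occupies strand
positions 5–10, i.e. backbone bonds 5–9.

Footprinting is single-strand resolved; duplex-level interpretation is the
union of per-strand windows. Chromatographic peak picking and vendor raw
formats are out of scope — peak lists (m/z, area) are the input contract.

## DSC analysis

**Progress baseline.** Linear fits to the pre- and post-transition flanks
give C_p,f(T) and C_p,u(T); the baseline interpolates between them weighted
by the running normalized integral of the excess signal, iterated to a
relative change < 10⁻⁶ (≤ 50 iterations; non-convergence raises with the
iteration trace). ΔC_p is reported as C_p,u − C_p,f at the excess peak.
The default transition window is the detrended-peak temperature ± 12 K;
analyses of traces with low-temperature satellite components use an
explicit, wider window so that all transition heat lies inside it.

**Two-state fit.** The excess trace is fit to
C_p,exc = ΔH(T)²·θ(1−θ)/(RT²) by trust-region least squares with bounds
(T_M inside the data range, ΔH_M ∈ (10, 1000) kcal/mol, ΔC_p ∈ (−5, 5)
kcal mol⁻¹ K⁻¹), initialized at the peak temperature with the calorimetric
integral as the enthalpy guess. Boundary solutions raise. The model is
unimolecular: duplex dissociation is strictly bimolecular, but the
covalently tethered conjugate and the matched free duplex are both treated
with the unimolecular equations, which is what the melting-parameter
bookkeeping here assumes throughout; a concentration-dependent bimolecular
variant is a known omission. The analytic dθ/dT equals the van 't Hoff
expression θ(1−θ)ΔH/(RT²) (finite-difference checked to 10⁻⁶).

**Gaussian deconvolution.** The excess trace is decomposed into K ∈ 1..5
Gaussians parameterized by (center, σ, area), fit by bounded least squares
from three deterministic initializations (area-quantile centers with equal
areas; greedy residual peeling; sequential one-component refinement) plus
seeded jittered restarts, keeping the lowest-cost solution; components are
returned sorted by center and their heats are the areas. Deconvolution is
well-posed only when the trace is approximately a Gaussian mixture: a
strictly two-state transition is *not* a sum of Gaussians (its sech²-like
peak has heavier tails), and fitting Gaussians to such an idealized sharp
peak will split the main transition rather than isolate a small shoulder.
The deconvolution round trips therefore run on component-resolved traces
(below), and the module reports components by center order without
attaching biological labels.

**Extrapolation.** ΔS_M = ΔH_M/T_M, ΔH(T) = ΔH_M + ΔC_p(T−T_M),
ΔS(T) = ΔS_M + ΔC_p ln(T/T_M), ΔG(T) = ΔH(T) − T·ΔS(T), so ΔG(T_M) = 0
identically. ΔC_p is in kcal mol⁻¹ K⁻¹ (the per-kelvin reading is the only
one that reproduces the 298 K table of the study systems). Temperatures
are Kelvin internally, Celsius at the I/O boundary. Molar normalization of
raw signals uses C_p,molar = signal·M/(c·V) with the study's cell volume
0.299 mL available as the default.

## CD analysis

Difference spectra divide each spectrum by its concentration (mg/mL) before
subtracting (conjugate − reference); grids and temperatures must match
exactly — there is no silent interpolation. No mean-residue-ellipticity
conversion is applied; raw mdeg are used throughout, so concentrations
enter only here.

Melting: the 220 nm trace (configurable) is smoothed with a centered
5-point moving average (edge windows truncate), differentiated by central
differences, and T_m is the temperature of the extremal |derivative|, ties
broken toward lower temperature. The extremum is refined to sub-grid
resolution by a quadratic fit over ±3 points, because a 1 °C sampling grid
otherwise quantizes the estimate to whole degrees. "No transition" is
flagged when the extremum falls inside the smoothing skirt of a boundary or
when the derivative lacks contrast (peak < 3× median |derivative|, the
signature of a linear or flat trace). Reversibility compares heating and
cooling T_m with an inclusive default tolerance of 1.5 °C.

## Synthetic data

One integer seed fans out into named substreams (thermogram, CD heating,
CD cooling, digest, spectrum), so generators are individually reproducible
and adding one does not perturb the others; identical (seed, config) pairs
are byte-identical.

**Thermograms** follow C_p(T) = (b₀+b₁T) + progress(T)·ΔC_p + excess(T) +
N(0, σ²), where the excess is the analytic two-state peak (shared code with
the fitting module — a single source of truth) plus any configured Gaussian
components, and progress is the enthalpy-weighted running integral of the
excess (equal to the van 't Hoff θ for a pure two-state trace up to the
small ΔC_p(T−T_M)/ΔH_M correction). Defaults are the study conditions:
free duplex (66.8 °C, 183 kcal/mol, 2.0 kcal mol⁻¹ K⁻¹) and conjugate
(68.8 °C, 246, 1.4), noise σ = 0.05 kcal mol⁻¹ K⁻¹, 269 points over
25–92 °C. For deconvolution studies the transition can instead be emulated
as its resolved components (`component_thermogram_config`): ends relaxation
/ peptide helix / core duplex at (58 °C, 2.5 K, 30 kcal/mol), (64 °C, 2 K,
8), (68.8 °C, 1.5 K, 208) for the conjugate — centers separated by ≥ 2σ so
the mixture is identifiable, areas summing to the calorimetric enthalpy,
with the peptide component's center and heat being the reported study
values and the ends component a realistic choice the study does not
quantify. The free-duplex analogue is ends + core (56 °C, 2.5 K, 25) +
(66.8 °C, 1.5 K, 158).

**CD melts** are a logistic sigmoid (midpoint 64 °C, width 2.5 °C,
amplitude 15 mdeg rising from a −20 mdeg folded baseline) sampled 0–90 °C
at 1 °C with Gaussian noise of 2% of the amplitude; heating and cooling are
generated independently, with an optional hysteresis offset on the cooling
midpoint. Spectra are weighted canonical band templates (B-DNA: +275/−245
nm; α-helix: −208/−222/+192 nm) plus noise.

**Digests** sample 10⁴ parent molecules, each receiving 0/1/2 cuts with
probabilities 0.2/0.5/0.3; cut bonds are drawn proportionally to per-bond
propensities (uniform null — the enzyme's true sequence preference for this
construct is unknown) times an attenuation factor (default 0.05) inside the
protection mask (bonds 5–9 for the GCRE-bound conjugate). Two-cut draws are
independent, with coinciding bonds collapsing to a single cut. The implied
fragment census conserves molecules, then ionizes: charge states drawn from
a z = 1..6 distribution peaked at z = 3–4 (plausible ESI behavior for
10–17-mers; the study reports none), predicted m/z perturbed by N(0, 5 ppm),
areas given log-normal noise at CV 0.2.

What passing round trips show — and what they do not: recovery of planted
parameters demonstrates the estimators are correct and unbiased under the
generators' assumptions (linear baselines, Gaussian/log-normal noise,
known charge distributions, uniform cleavage null). Real instrument data
add scan-rate smearing, non-linear baselines, retention-time structure,
sequence-dependent nuclease preference and detector saturation, none of
which the generators emulate; agreement on synthetic data does not certify
accuracy on such data.

## I/O and reporting

CSV dialects: thermograms `temp_C,cp` (or `temp_K,cp_molar`), peak lists
`mz,area[,rt]`, melts `temp_C,ellipticity,direction`, spectra
`wavelength_nm,temp_C,ellipticity`. Molecule documents are JSON/YAML;
FASTA with placeholder letters (e.g. X for the alkyne-dC) is resolved
through a JSON sidecar. The run configuration is a strict schema (unknown
keys rejected); every report embeds the resolved configuration and its
SHA-256 hash, so identical inputs and seed reproduce identical files. All
temperatures are Celsius at the boundary, energies kcal/mol, masses Da.
Logging goes to stderr; machine-readable results go to files or stdout.

## Problem sizes

Default analyses run in seconds: 269-point thermograms, 91-point melts,
10⁴-molecule digests (≈ 150 fragments, ≈ 400–600 peaks per sample), and
20-replicate recovery studies, sizes chosen as representative of the
single-sample experiments they emulate.
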
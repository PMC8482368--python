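# Methods

## The measurement this package models

Histone lysine acetylation turns over continuously: acetyltransferases load
acetyl groups from the acetyl-CoA pool onto lysine ε-amines and deacetylases
remove them. Switching cells from unlabeled to [U-¹³C]-glucose converts the
acetyl-CoA pool (partially) to the ¹³C₂ form, so newly deposited acetyl groups
are 2.0067 Da heavier than pre-existing ones. Chemically acetylating all
*unmodified* lysines at the protein level with ¹³C₄,D₆-acetic anhydride before
tryptic digestion makes every peptide species fully acetylated and therefore
chemically equivalent — identical retention and ionization — while remaining
mass-distinguishable. Each modifiable lysine thus carries one of three acetyl
states:

| state | acetyl | net addition | Δm vs light |
|---|---|---|---|
| light  | endogenous, pre-switch  | C₂H₂O            | 0 |
| heavy  | endogenous, post-switch | ¹³C₂H₂O          | +2.0067 Da |
| chem   | chemical (= unmodified in vivo) | ¹³C₂D₃H₋₁O | +5.0255 Da |

A peptide with *n* modifiable lysines occurs as 3ⁿ isotopologues. Because the
label chemistry is symmetric across sites, species sharing a label multiset
are isobaric at MS1 — C(n+2, 2) resolvable channels (6 for the two-site
H3(18-26) peptide KQLATKAAR, 15 for the four-site H4(4-17)) — and positional
isomers are resolved from site-containing b/y fragment ions.

## Mass model

Masses are computed from hard-coded IUPAC monoisotopic values (proton
1.00727647 Da). Labeled atoms (¹³C, ²H) are tracked separately from the
unlabeled backbone throughout. Theoretical precursor and fragment m/z agree
with all published instrument readings of the H3(18-26) species within 10 ppm
(instrument calibration accounts for the few-mDa offsets; the tests assert
the 10 ppm band rather than equality). b ions are residue sums + proton,
y ions add water; the N-terminal amine of tryptic peptides is unmodified
because derivatization precedes digestion (a flag covers protein N-termini).

## Natural isotope abundance correction

Each channel receives signal from natural-isotope satellites of lighter
channels — dominantly the ¹³C₂ satellite at +2.00671 Da, which coincides
exactly with the light→heavy channel spacing. For each channel's species we
compute the exact satellite spectrum of its *unlabeled* atoms (multinomial
over ¹³C, ²H, ¹⁵N, ¹⁷O, ¹⁸O, ³⁴S; default abundances 0.0107, 0.000115,
0.00364, 0.00038, 0.00205, 0.0429, configurable). Labeled positions carry no
natural variation; sub-unity label purity can be modeled as additional
satellites at negative offsets. Satellites are attributed to channels when
their exact neutral mass falls within `coalescence_tol × charge` of a channel
mass (default 3 mDa on the m/z axis, mirroring a ±3 ppm EIC window at
m/z ≈ 540 — it encodes instrument resolution and is exposed in config). This
yields a per-species ("skewed") correction matrix, lower-triangular in
ascending-mass order, inverted exactly by forward substitution (NNLS fallback
for non-triangular designs). Inversion divides by each species' monoisotopic
fraction, so corrected totals represent full species signal; noise-driven
negative solutions are clamped to zero with a logged warning. Correction is
applied at MS1 only.

## Positional-isomer resolution

For an isobaric group, every fragment (series, index) partitions the members
into mass classes according to how many member-specific sites the fragment
spans. Class-level relative intensities give linear equations
Σ_{m∈class} f_m = I_class/ΣI; stacked over both series and weighted by
fragment intensity, they are solved on the probability simplex. For two-member
groups this reduces to the intensity ratio of the member-unique diagnostic
ions (e.g. b3 at 414.26 vs 417.28 for the heavy-K18/heavy-K23 pair), and
per-series estimates plus their dispersion are reported (inconsistent b/y
evidence flagged above 0.15 absolute). For the four-member single-heavy
H4(4-17) group only the terminal-site members have strictly unique ions; the
class system nevertheless determines all four fractions (b2 → K5, y2 → K16,
b5/y6 → the pairwise sums), which the tests verify exactly on noise-free
input. MS2 intensities are assumed proportional to precursor-species
contribution; no fragment-efficiency calibration is attempted. Groups whose
fragments are all zero (heavy species before label addition) are split
uniformly and flagged unresolved — their MS1 abundance is itself noise-level
there.

## Kinetics

**Label-exchange fits.** Per site and occupancy class, the heavy fraction
f = H/(H+L) is fitted with f(t) = p·(1 − e^(−kt)) (scipy `curve_fit`,
σ from the covariance; t½ = ln 2/k, reported in minutes, k in 1/h). Under
first-order site kinetics p equals the acetyl-CoA heavy plateau λ and k the
site's deacetylation rate. Because all sites draw on one acetyl-CoA pool, a
second stage pools the plateau across every fit by inverse variance and
refits k with p pinned at that shared λ̂: when a slow site's curve stays far
from saturation the free (p, k) fit is ridge-degenerate and the constrained
fit is substantially more stable. Both sets of estimates are reported; rates
and summary half-lives use the shared-plateau columns. For the fully
acetylated class, the pre-existing (all-light) fraction among all fully
acetylated species starts at exactly 100% and is fitted with
r(t) = 100·e^(−kt) (intercept pinned).

**Turnover.** Abundance-corrected turnover is k·A (%/h), with A the mean
relative abundance of the species class over the time course. The published
example values (half-lives 383/549/220 min with abundances 28.4/5.0/14.2%
giving 3.07/0.38/2.69 %/h) reproduce within 1%.

**Reaction network.** In vivo species are strings over {U, L, H} per site
(3ⁿ nodes). Acetylation edges point U→H (the post-switch substrate pool),
deacetylation edges L→U and H→U. Edges whose substrate contains a heavy label
are not estimable by initial-flux fitting — those substrates are absent at
t = 0. For two sites this gives 18 reactions, 8 estimable, with the
conventional labels a1–a4, d1–d3.

**Initial-flux rates.** A first-order rate is an early-time slope divided by
the substrate abundance at t = 0 (OLS intercept). The window is the first 4
time points restricted to t ≤ 4 h (configurable). Three estimator choices
matter:

1. *Known intercepts are pinned.* Heavy products are exactly absent before
   the switch, so product slopes are fitted through (0, 0); light-retention
   ratios start at exactly 100%. This removes the influence of the t = 0
   measurement, which for heavy channels is pure noise.
2. *Deacetylation fluxes use ratios.* The decay of a light species is
   measured as its fraction of its occupancy class (class totals are constant
   at steady state), which cancels common-mode intensity noise; multiplying
   by A₀ restores the flux in %/h so that υ = flux/(A₀·λ̂) as in the slope/
   substrate definition. For a substrate with several light sites only the
   total deacetylation rate is identified (site attribution of the products
   is ambiguous), reported as the d3-style total.
3. *Plateau correction.* Post-switch acetylation still deposits light acetyl
   with probability 1 − λ, so at the pre-switch steady state the net initial
   slope of every estimable species is exactly λ·(rate)·A₀. Raw flux/A₀
   therefore estimates λ·υ. The model divides by the fitted λ̂ (passing
   `label_plateau=1.0` reproduces the raw definition). With λ̂ ≈ 0.4 this is
   a 2.5× effect.

Fits are per replicate with mean ± SD reported (pooled fitting behind a
flag). For context-dependent (cooperative) rates the deacetylation estimator
inherits the initial-flux method's confounding between deacetylation and
further acetylation of the same substrate; for non-interacting sites it is
exact in the window → 0 limit.

## Simulator

First-order mass-action kinetics over the 3ⁿ states; per-site acetylation and
deacetylation rates with optional per-context overrides. Before t = 0 the
system sits at the steady state of the all-light network (solved from the
generator's null space; sites with a > 0 and d = 0 are rejected as
absorbing). At t = 0 the acetyl-CoA heavy fraction steps to λ∞ (default 0.4,
matching the observed ≈40% label-exchange plateau; an exponential ramp-in is
available but off by default); propagation uses the matrix exponential.
Defaults are the reference two-site experiment: the published H3(18-26) rates
a = (0.0036, 0.019)/h and d = (0.032, 0.059)/h as ground truth,
context-independent, 3 replicates, 2% multiplicative log-normal noise
(mean-preserving) with an optional additive floor (default 0), seed 0.

The time grid (0, 0.5, 1, 2, 6, 12, 24) h — 7 points over 24 h — was chosen
so the initial-flux window stays short relative to 1/k for rates up to
0.1/h (keeping linearization bias within a few percent) while the later
points cover the exponential bend for the growth fits.

Measurement synthesis maps in vivo states to observed labels (unmodified →
chemical acetyl), sums isobaric members into MS1 channels, convolves channels
with their natural isotope patterns via the same matrix the correction stage
inverts, emits per-class fragment intensities proportional to member
abundance (b/y ion yields 1.0/0.8), and applies seeded noise. Everything is
reproducible bit-exactly from (config, seed).

**What the simulator does not emulate:** histone protein turnover (synthesis
and degradation of the backbone), acetyl-CoA pool kinetics beyond the λ(t)
step, chromatin-context heterogeneity, chimeric MS2 spectra, incomplete
chemical derivatization, and retention-time or ionization drift. Passing the
recovery tests therefore demonstrates correctness of the computational
pipeline under the stated noise model, not robustness to every feature of
real LC-MS data.

## Numerical choices and degenerate inputs

- Isobaric grouping: single-linkage on precursor m/z, 5 mDa default gap.
- Fragment tolerance 10 ppm; fractions renormalized to sum exactly to 1;
  apportionment conserves group abundance exactly.
- Growth fits require ≥ 4 distinct time points, decay fits ≥ 3; flux windows
  ≥ 3 points. Label fractions with H+L = 0 are dropped with a log entry; a
  constant decay series is flagged "no measurable decay" (t½ = ∞) rather
  than fitted.
- Zero-total intensity groups are flagged missing, never propagated as NaN
  percentages.
- Correction matrices with adjacent channels closer than the coalescence
  tolerance are rejected as unresolvable designs.

## Known limitations

- Estimator variance at the reference conditions is irreducible for the
  smallest rates: heavy-channel intensities inherit absolute noise from the
  ¹³C₂ satellites of abundant light channels, so across random noise
  realizations occasional recovery errors up to ~17% (rates) / ~11%
  (half-lives) occur; the documented reference experiment uses the fixed
  default seed.
- Site-specific rates for multiply acetylated species beyond the estimable
  set require MSn-resolved isomers and are out of scope; only the total
  deacetylation of the fully acetylated class is reported.
- The initial-flux linearization biases rates downward by the curvature of
  the window (a few percent at the defaults); no correction is applied, as
  in the original approach.
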
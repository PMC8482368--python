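# cometchem

Site-specific histone lysine acetylation and deacetylation kinetics from
combined metabolic and chemical stable-isotope labeling LC-MS/MS data.

## The problem

Histone acetylation is maintained by opposing acetyltransferase and
deacetylase activity, but a static acetylation level says nothing about how
fast it turns over. Switching cells to [U-¹³C]-glucose labels the acetyl-CoA
pool, so newly deposited acetyl groups become 2.0067 Da heavier than
pre-existing ones; chemically acetylating all remaining unmodified lysines
with ¹³C₄,D₆-acetic anhydride (+5.0255 Da vs a light acetyl) before digestion
makes every tryptic peptide species fully acetylated and chemically
equivalent — same retention, same ionization — while keeping all label states
mass-resolvable. A peptide with *n* modifiable lysines then appears as 3ⁿ
isotopologues whose time courses encode, per site, the acetylation rate *a*,
the deacetylation rate *d*, the label-exchange half-life t½ = ln 2/*k*, and
the abundance-corrected turnover *k·A*.

This package is for mass spectrometrists and systems biologists running such
dual-label experiments. It takes exported EIC peak tables (CSV) and computes:

1. **mass model** — all 3ⁿ isotopologues with exact precursor/fragment m/z
   and their MS1-isobaric grouping (9 species / 6 channels for H3 18-26;
   81 / 15 for H4 4-17);
2. **correction** — natural isotope abundance correction with a per-species
   (skewed) matrix, inverted exactly;
3. **isomer resolution** — splitting isobaric positional isomers (K18ac vs
   K23ac, H4 K5/K8/K12/K16) by site-diagnostic b/y fragment intensities;
4. **kinetics** — exponential label-exchange fits
   f(t) = p·(1 − e^(−kt)) and r(t) = 100·e^(−kt), turnover k·A, and
   acetylation/deacetylation rates υ = initial flux / substrate abundance
   over the reaction network;
5. **simulator** — a forward model (first-order mass-action over the 3ⁿ
   states, natural-isotope convolution, seeded noise) so the entire pipeline
   is testable end to end without instrument data.

## Worked example

Simulate the reference two-site experiment — H3(18-26) with literature rates
a = (0.0036, 0.019)/h, d = (0.032, 0.059)/h as ground truth, a 40%
acetyl-CoA label plateau, 7 time points over 24 h, 3 replicates, 2% noise —
and run the full pipeline on it:

```python
from cometchem import run_pipeline
from cometchem.simulator import default_h3_config, simulate_dataset

cfg = default_h3_config()          # seed 0
ds = simulate_dataset(cfg)         # raw MS1/MS2 channel tables
res = run_pipeline(cfg.peptide, ds.ms1, ds.ms2)
print(res.results.summary())
```

Output (abridged):

```
peptide: H3_18_26   acetyl-CoA heavy plateau: 0.382

Site half-lives (growth fits, f = H/(H+L)):
species_class site   p_mean  k_shared_per_h_mean  t_half_shared_min_mean
    K18+K23ac  K18 0.379799             0.034265             1213.925592
    K18+K23ac  K23 0.388112             0.064165              648.562753
        K18ac  K18 0.390142             0.034491             1206.646553
        K23ac  K23 0.396952             0.065095              639.266172

Reaction rates (initial flux / substrate, plateau-corrected):
reaction          kind  site substrate  rate_per_h_mean  rate_per_h_std
      a1   acetylation   K18        UU         0.003634        0.000101
      a2   acetylation   K23        UU         0.018615        0.000542
      a3   acetylation   K23        LU         0.019584        0.000196
      a4   acetylation   K18        UL         0.003746        0.000041
      d1 deacetylation   K18        LU         0.033104        0.001122
      d2 deacetylation   K23        UL         0.059380        0.002119
      d3 deacetylation total        LL         0.094508        0.001520
```

Reading it: the fitted plateau (0.382) recovers the 0.4 heavy fraction of the
acetyl-CoA pool; each site's half-life matches ln 2/d (1300 min for K18,
705 min for K23) within 10%; every estimated rate matches its generating
value within a few percent (d3 estimates the *total* deacetylation of the
doubly acetylated species, d1 + d2 = 0.091/h here, since its site-resolved
products are indistinguishable). Residue-level detail, free-fit (p, k)
columns and per-replicate values are in `res.results.growth_fits`,
`.turnover` and `.rates`.

The same stages are available as a CLI:

```bash
cometchem masses --peptide H3_18_26 --charge 2        # species table as CSV
cometchem simulate --seed 9 --out-dir sim/
cometchem run --ms1 sim/ms1_raw.csv --ms2 sim/ms2_raw.csv --out-dir out/
```

with `correct`, `resolve`, `fit` and `rates` exposing the individual steps.

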
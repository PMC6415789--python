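# Methods

## The screening model

For one treatment, the screen consumes exactly four amplicon samples:
heavy and light gradient fractions from a ¹³C-substrate incubation and the
same two fractions from a parallel ¹²C control. For each taxon *g* and
isotope stratum *s*, the 2×2 table is (G_H, nG_H; G_L, nG_L) — reads of *g*
versus all other reads in the heavy and light sample — and the stratum odds
ratio is OR(s) = (G_H/nG_H)/(G_L/nG_L).

The null hypothesis is homogeneity, OR(¹²C) = OR(¹³C): a taxon whose DNA
density is driven only by GC content bands identically in both gradients.
The alternative of interest is OR(¹³C) > OR(¹²C) ("labelled"); the mirror
direction ("unlabelled", light-enriched in the ¹³C gradient) arises
compositionally when labelled DNA leaves the light fraction, and is reported
with an explicit direction column rather than discarded.

Homogeneity is tested with the Breslow-Day statistic. With stratum margins
r₁ = G_H + nG_H (heavy-sample total), c₁ = G_H + G_L (taxon total) and
N the stratum total, the fitted heavy count ã under the Mantel-Haenszel
pooled odds ratio R̂ = Σ a·d/N / Σ b·c/N solves

    R̂ = ã (N − r₁ − c₁ + ã) / ((r₁ − ã)(c₁ − ã)),

taken as the root of the quadratic lying in the admissible interval
(max(0, r₁+c₁−N), min(r₁, c₁)); the quadratic is solved in the numerically
stable form (large-|b| root first, companion root by Vieta). The statistic

    X² = Σ_s (a_s − ã_s)² / Var_s,
    Var_s = (1/ã + 1/(r₁−ã) + 1/(c₁−ã) + 1/(N−r₁−c₁+ã))⁻¹

is referred to χ² with (strata − 1) = 1 degree of freedom. The Tarone
adjustment (subtracting (Σ(a−ã))²/ΣVar) is available behind a flag and off
by default; at the read depths of amplicon data the two are numerically
indistinguishable. Both forms, and the MH pooled OR, are cross-checked in
the test suite against an independent bisection root search and against
statsmodels' stratified-table implementation.

Raw counts enter the test directly. The statistic conditions on the
per-sample totals, so unequal depths between samples are handled without
rarefaction, and power increases with total reads — the practical reason
this design needs only four sequenced samples per treatment.

### Zero cells

Taxa absent from one fraction produce zero cells, where the odds ratio and
the Breslow-Day internals are undefined. The default policy is
Haldane–Anscombe: when any cell of a stratum's 2×2 table is zero, 0.5 is
added to all four cells of that stratum, consistently for the OR, the MH
pooled OR and the Breslow-Day fit, keeping every tested taxon finite without
discarding rare taxa. A `strict` policy that raises instead is available for
auditing. Because a corrected stratum has all cells ≥ 0.5, degenerate
margins cannot occur under the default policy.

### Multiplicity

Family-wise error over the n taxa tested in one treatment is controlled by
Holm's step-down rule: p-values sorted ascending (ties broken by OTU id for
reproducible ranks), the k-th rejected iff p(k) < α/(n+1−k) — strict
inequality — and rejection stops at the first failure. n is the number of
taxa actually tested: all-zero rows are skipped, and an optional `min_total`
filter (default 0 = test everything) can exclude tiny-count taxa whose
Breslow-Day statistic is unstable. Report stars (*, **, ***) are
Holm-adjusted decisions at α = 0.05, 0.01, 0.001 respectively.

### Direction and ties

A significant taxon is `labelled` iff OR(¹³C) > OR(¹²C), `unlabelled` iff
OR(¹³C) < OR(¹²C); exact equality (measure-zero with continuity-corrected
counts) yields `none`, since no direction is evidenced.

## The synthetic-data generator

The generator emulates the data-generating process the screen assumes,
with ground truth attached:

- **Community**: n_taxa (default 500; capacity runs use 12,000) with
  relative abundances drawn lognormal(μ=0, σ=1.5) and normalised — a
  long-tailed rank-abundance curve in which the top taxa sit at a few
  percent and most taxa are rare, typical of 16S surveys. A fraction
  (default 5%) of taxa, chosen uniformly, carries excess ¹³C
  (default atom excess 1.0, matching fully labelled substrates).
- **Density**: ρ = 1.660 + 0.098·GC + 0.036·atom_excess g mL⁻¹ — the
  standard linear dependence of CsCl buoyant density on GC content, plus
  the full-label shift of ≈0.036 g mL⁻¹. Per-taxon GC is uniform on
  [0.40, 0.50] by default. This window is a deliberate modelling choice:
  sequencing fixed heavy/light fractions at 1.725/1.700 g mL⁻¹ presumes a
  community whose unlabelled DNA bands near the light fraction and whose
  labelled DNA reaches the heavy window. With the density model above,
  unlabelled DNA of GC 0.40–0.50 bands at 1.699–1.709 g mL⁻¹ (the light
  bin) and fully labelled DNA at 1.735–1.745 g mL⁻¹, leaving detectable
  Gaussian tail mass in the 1.72–1.73 g mL⁻¹ heavy bin. Taxa with GC well
  above ~0.51 would, when fully labelled, band *above* the sampled heavy
  window and vanish from both sequenced fractions — a real failure mode of
  two-fraction SIP that the default community deliberately avoids (see
  Limitations).
- **Gradient**: 12 uniform bins spanning 1.66–1.78 g mL⁻¹; each taxon's
  DNA spreads as a Gaussian (σ_ρ = 0.006 g mL⁻¹) around its mean density,
  truncated and renormalised on the gradient range. The bins containing
  1.725 and 1.700 g mL⁻¹ are "sequenced".
- **Sequencing**: each of the four samples is an independent multinomial
  draw (default depth 50,000 reads) from the abundance-weighted,
  per-fraction renormalised composition. The ¹²C samples are generated with
  every atom excess forced to zero, so the generative compositions of
  labelled and unlabelled taxa are identical in the control by
  construction.

All randomness flows through numpy SeedSequence spawning; identical seeds
give byte-identical experiments.

A refractive-index helper converts AR200-style refractometer readings to
CsCl density via the standard linear calibration ρ = 10.8601·η − 13.4974,
accepting readings in [1.33, 1.46] and warning when the implied density
falls below the gradient working range.

### What passing tests do and do not show

On these simulations the screen achieves ≈5% per-taxon type-I error under
the null (measured over taxa with expected heavy count ≥ 10, where the
χ² asymptotics apply), power ≈ 1 for fully labelled taxa above 0.5%
relative abundance at 50,000 reads/sample, and essentially zero false
`labelled` calls after Holm correction. Real data differ in ways the
generator does not model: partial and heterogeneous atom enrichment,
PCR/chimera artifacts, replicate-level biological variance (the generator
mirrors the pooled-replicate design, one sample per isotope×fraction),
cross-feeding (isotope flow through secondary consumers is
indistinguishable from primary assimilation), and communities whose GC span
exceeds the window above. Passing calibration here validates the statistics
under the stated model, not the wet-lab pipeline.

## Enzyme activities

Plate-reader fluorescence of MUF-conjugated substrates (α-glucoside,
β-cellobioside, β-xyloside) is converted to activities in four steps: OLS
standard curve over the protocol's seven MUF concentrations (0, 0.5, 1.0,
1.5, 2.0, 3.5, 7.5 μM; the fit refuses non-positive slopes), point-wise
inversion to μM (optionally blank-subtracted; negative back-calculated
concentrations are retained so zero-activity series stay unbiased), OLS
slope of concentration against time rescaled to μM h⁻¹ (default window =
full series; an optional maximum-slope sliding window handles
substrate-depletion curvature), and unit conversion: μM h⁻¹ × assay volume
(default 200 μL: 50 μL sample + 50 μL substrate + 100 μL buffer) → mol h⁻¹,
divided by qPCR-derived 16S gene copies and expressed in amol h⁻¹ copy⁻¹
(1 amol = 10⁻¹⁸ mol). The substrate-ratio profile, the device for comparing
enzymatic repertoires between habitats, is invariant to the per-copy
normalisation factor. Converting filter-concentrated samples back to
per-mL-groundwater units requires the concentration factor as config input.

## Carbon budget

Polysaccharide carbon is counted on the anhydro-sugar residue at natural
isotope abundance (C₆H₁₀O₅, 162.14 g mol⁻¹, 6 C): 150 mg of glucan —
whether starch or a 75 + 75 mg (hemi)cellulose mix — carries 5.55 mmol C.
(Using a ¹³C-enriched monomer mass ≈ 168 g mol⁻¹ would not reproduce that
figure, so natural abundance is the default basis.) Mineralization percent
is 100·TIC/C_added; background correction subtracts the no-substrate
control mean; the two-treatment comparison uses Welch's t-test computed
from summary statistics (mean, SD, n=5 replicates) with
Welch–Satterthwaite degrees of freedom, the pooled-variance Student form
behind a flag.

## Numerical and design notes

- Breslow-Day quadratic: R̂ = 1 degenerates to the linear solution
  ã = r₁c₁/N; tiny negative statistics from float cancellation are clamped
  to zero.
- Screen ordering is fully deterministic: calls sorted by raw p ascending,
  ties by OTU id; Holm ranks follow that order.
- Equality with the Holm threshold is a non-rejection (strict inequality).
- Per-taxon testing is the default granularity; aggregate-then-test at a
  chosen taxonomic rank can be performed by summing counts per group before
  screening.
- The mothur `shared` dialect accepts any `label` value, requires unique
  Group names, and validates `numOtus` against the actual OTU columns.
  Counts must be integers; fractional input is rejected, not rounded.
- Problem sizes in the validation suite — four 500-taxon null experiments
  (≈2,000 taxon-tests), twenty 500-taxon power experiments, one
  12,000-taxon capacity screen, all at 50,000 reads/sample — were chosen to
  estimate the calibration and power quantities with adequate precision at
  desk scale.

## Known limitations

- The two-fraction design cannot see fully labelled high-GC taxa whose DNA
  bands above the sampled heavy window; such taxa may be missed or called
  light-enriched. Sequencing more fractions (qSIP-style) is the remedy and
  is out of scope here.
- The screen detects isotope incorporation, not its trophic route;
  cross-feeders are not distinguished from primary degraders.
- Atom-fraction-excess quantification (how labelled a taxon is) is not
  attempted; the output is a direction and a significance, per taxon.
- Tiny-count taxa have unstable Breslow-Day statistics even with continuity
  correction; the `min_total` filter exists for analysts who prefer to
  exclude them, at the cost of changing the Holm family.
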
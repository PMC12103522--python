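# Methods

## The model class

A metabolism-and-expression (ME) model extends a stoichiometric metabolic
model with the machinery that produces its catalysts.  The package represents
this as a growth-rate-parameterized linear system: each reaction entry
`(metabolite, a, b)` contributes a stoichiometric coefficient `a + b·μ` at
growth rate μ (1/h).  Two coupling motifs cover the expression economics:

* **Enzyme usage + dilution.**  A catalyzed reaction consumes its enzyme with
  coefficient `−μ/k_eff` per unit flux: sustaining flux v requires enzyme in
  proportion `v/k_eff`, and that enzyme pool is diluted by growth at rate μ.
  At steady state, translation must resupply exactly `μ·v/k_eff`.
* **Machinery usage.**  A translation reaction consumes ribosome capacity
  with coefficient `−μ·L/c_ribo` (protein length L in aa, ribosome capacity
  `c_ribo` in aa/(h·ribosome)) and mRNA with `−μ/k_mrna`.  The ribosome is
  itself translated, closing the autocatalytic loop.

At fixed μ the model is a pure linear feasibility problem

    S(μ)·v = 0,   lb ≤ v ≤ ub,   v_growth = μ,

solved with HiGHS (through `scipy.optimize.linprog`) at a primal/dual
feasibility tolerance of 1e-9.  Well-posed models of this class are feasible
on an interval [0, μ*]: raising μ only tightens the expression couplings, so
feasibility is monotone non-increasing in μ.  `maximize_growth` exploits
this with plain bisection (default bracket [0, `mu_max_hint`], convergence
tolerance 1e-6 1/h, deterministic).  Monotonicity is a property of the
*models*, not the solver; the generators are tested for it, and an optional
coarse-grid check flags violations.  `grid_max_growth` provides a
bisection-free oracle: a coarse pass brackets the feasibility boundary and
an exhaustive fine grid (default step 1e-4) locates the largest feasible
point inside it.

Downstream analyses reuse the same fixed-μ LP: flux variability analysis
(FVA) minimizes/maximizes each reaction's flux at μ fixed to a configurable
fraction of the optimum (default 1.0); knockout essentiality closes a gene's
translation reaction and probes feasibility at μ = 1e-3 (bounds restored
afterwards); `strip_expression` deletes expression-subsystem reactions and
all `b` terms to produce the metabolism-only (M) analog — a relaxation, so
its optimum always dominates the ME optimum.

Numerical notes: double precision with tolerance 1e-9 replaces the
quad-precision tolerances used for genome-scale models of this kind; the toy
models here are small and well-conditioned, and the tolerance is a config
knob.  An FVA range computed at a bisected μ* carries residual slack of
order `bisect_tol/(dμ/dv)`; comparisons between models therefore use
bisect_tol 1e-9 and a flux tolerance of 1e-6.  Degenerate alternate optima
are returned as the solver's vertex solution; model comparisons rely on FVA
ranges, never on a particular flux vector.

## The toy cell and why it overflows

`make_minicell` builds the smallest system that exhibits proteome-limited
overflow.  Metabolism: substrate uptake; a high-yield respiration branch
(yield 0.10 gDW/mmol, two isozymes with k_eff 20 and 6 h⁻¹, 400 aa each); a
low-yield overflow branch (0.05 gDW/mmol, k_eff 12 h⁻¹, 160 aa) that
secretes a by-product; a biomass drain defining μ.  Expression: one
mRNA/protein pair per enzyme with transcription and translation costs in
biomass-precursor units (0.01 per aa translated, 0.0005 per nt transcribed),
and a shared self-replicating ribosome (7500 aa, 60000 aa/(h·ribosome)).

The overflow switch needs one more ingredient.  With two independent
branches, the maximum-growth curve μ*(U) is the upper envelope of two
concave curves and acquires a *convex* kink where the branches cross — not
the smooth saturation seen in real organisms.  The cell therefore caps the
translation flux of the primary respiratory enzyme (default 0.075 model
units), a coarse stand-in for the membrane real estate available to the
respiratory chain.  Through the protein balance this becomes a
growth-rate-dependent respiration capacity `k_eff·cap/μ`: as growth
accelerates, respiratory capacity shrinks, excess substrate is diverted to
the proteome-cheap overflow branch, and secretion rises gradually.  Because
the cap sits on an *expression* reaction it vanishes in the stripped analog,
which grows linearly (μ = yield × uptake) and never secretes.  With default
parameters the overflow threshold falls near uptake 6 mmol/gDW/h and growth
plateaus near 0.30 h⁻¹; the respiration/overflow effective-yield crossover
is placed above the operating range so the scanned curve stays strictly
concave.

Seeded variants (`random_minicell_params`) jitter all rates ±20%,
re-drawing until the mechanism-enabling ordering holds (respiration: higher
yield *and* higher proteome cost `L/k_eff` than overflow).

`make_benchmark_cell` appends accessory pathways (default 30), each a fixed
small demand flux (log-normal, median e^-2.5 ≈ 0.08 mmol/gDW/h, sdlog 1.0)
catalyzed by its own enzyme (k_eff log-normal, median e^3 ≈ 20 h⁻¹, sdlog
0.8; length uniform 100–600 aa) in its own subsystem.  The ME translation
flux for pathway i is `μ·d_i/k_eff,i` — allocation shaped by demand *and*
catalytic efficiency — while the stripped analog sees only `d_i`.

## Simulated sequencing counts

`simulate_counts` draws paired RNA-Seq/Ribo-Seq gene×sample tables:

* **Abundance spectrum.**  Hierarchical log-normal: each pathway draws a
  shared log-abundance (sdlog 1.8 between pathways) emulating operon-level
  co-regulation in bacteria; genes add residual noise (sdlog 0.5).  The
  combined spread puts ≥4–6 orders of magnitude between the least and most
  expressed genes at default depth, matching deep bacterial profiling.
* **TE.**  Each gene's translational efficiency is its pathway's planted
  multiplicative effect (default 1.0) times log-normal gene noise
  (sdlog 0.1).
* **Counts.**  Negative binomial with variance m + 0.05·m² around mean
  `abundance × depth × replicate factor` (depth 5e6; per-replicate library
  factors log-normal, sdlog 0.1); RNA and Ribo are sampled independently
  given the latent abundances.  Three replicates per assay by default.

Everything is reproducible bit-for-bit from `(design, seed)`; the generating
truth (abundances, per-gene TE, expected pathway classes, depth factors) is
returned and serialized alongside every dataset.

What the generator does **not** emulate: positional footprint structure,
rRNA contamination, batch effects shared between assays, length biases, and
compositional coupling beyond the CPM closure.  Passing tests demonstrate
the statistical machinery recovers planted effects under this idealized
noise model, not that it would on any particular real library.

## Omics analysis

CPM is `count/sample total × 1e6` per sample.  Replicate QC computes
pairwise Pearson correlations and Welch t-tests on log10(CPM+1) within each
assay; it passes when every off-diagonal PCC exceeds 0.9 and no t-test
rejects at α = 0.05.  A gene's TE is its mean Ribo CPM over replicates
divided by its mean RNA CPM; genes with zero mean in either assay are
excluded (no pseudocounts), so TE is positive wherever reported.

Pathway prioritization ranks all included genes by mean CPM within the RNA
dataset and, separately, within the Ribo dataset (average ranks on ties),
then compares a pathway's Ribo ranks against its RNA ranks with one-tailed
Mann–Whitney U tests (exact null for combined n ≤ 25 without ties,
otherwise the tie- and continuity-corrected normal approximation — scipy's
`mannwhitneyu`).  A pathway is "up" iff mean TE ≥ 1 and right-tailed
p < 0.05, "down" iff mean TE ≤ 1 and left-tailed p < 0.05, else "ns".
Raw p-values drive classification; BH-adjusted columns are emitted for
transparency.  Pathways with fewer than 3 included genes are flagged, not
dropped.  Replicates are averaged before ranking (symmetric in replicates
and makes ranks well-defined); a per-replicate ranking mode was considered
and rejected for the default because it triples rank noise without changing
the statistic's meaning.

**Calibration caveat.**  Because both rankings are driven by the same latent
abundances, a gene's RNA and Ribo ranks are strongly paired; the unpaired U
statistic concentrates far inside its nominal null distribution, so under a
TE-null simulation the right-tailed test rejects essentially never
(measured 1e-4 over 10⁴ pathway-tests) rather than at the nominal 5%.  The
test is thus conservative as a detector — its rejections are trustworthy,
its nominal level is not attained — and its power for coherent pathway-level
effects remains high: a planted 2× TE effect on a 10-gene pathway is
recovered as "up" in ~97% of runs, with the mean estimated pathway TE over
200 runs inside [1.85, 2.15] (interval frozen from a prior Monte-Carlo
calibration).  The small downward bias on estimated TE comes from the CPM
closure: planting extra Ribo signal in one pathway deflates every other
gene's Ribo share.

## Model-vs-omics benchmark

Gene-level signals (CPM, translation fluxes) and reaction fluxes are summed
by annotated subsystem as absolute values (signed sums could cancel within a
subsystem); ids without a subsystem are reported, never silently dropped.
Profiles are compared on the log10(f+1) scale by OLS (y on x, 95% CIs from
the fit covariance) and Pearson correlation.  Because model fluxes and CPM
live on incommensurable scales — and log10(f+1) is linear for f ≪ 1 but
logarithmic for f ≫ 1 — each profile is first rescaled to parts-per-million
of its total (`normalize_per_million`), mirroring the CPM convention, so the
transform acts in the same regime on both sides.  Per-sample profiles can be
stacked (repeated subsystem rows) so one regression uses all replicates.

In the coupled scenario, simulated footprint abundances are the ME
translation fluxes times log-normal noise (sdlog 0.3).  The ME profile
tracks the footprints nearly perfectly (PCC ≈ 0.96–0.99); the stripped
analog's reaction-flux profile misses the k_eff dimension of proteome
allocation and correlates substantially worse (PCC ≈ 0.0–0.95 depending on
the keff draw, always below the ME profile in 12/12 tested seeds).

## Problem sizes and determinism

Default problem sizes — toy cells of 14 reactions (plus 4 per accessory
pathway), omics designs of 1000 genes × 50 pathways × 3 replicates, 100
null runs × 100 pathways for calibration, 200 runs for effect recovery, 25
seeded cells for the bisection/oracle comparison — were chosen so every
analysis is exact enough to separate mechanism from noise while the whole
suite and the acceptance script each complete in a couple of minutes on one
CPU.  One seed fans out to per-stage child seeds via `numpy.SeedSequence`
spawn keys, so stage-level reruns reproduce pipeline runs exactly; all
randomness flows through `numpy.random.Generator`.

## Known limitations

* Coefficients are affine in μ; hyperbolic ribosome-efficiency couplings
  (elongation rate saturating in μ) are out of scope.
* Double-precision LP; quantities within ~1e-9 of a bound are not resolved,
  unlike quad-precision solvers used for genome-scale ME models.
* The omics simulator is per-gene i.i.d. given the hierarchy; no shared
  technical noise between assays, so replicate QC failures must be injected
  deliberately (e.g., permuting a replicate).
* The rank test's conservatism under the shared-abundance null (above) is
  inherited from the method itself, not corrected here.
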
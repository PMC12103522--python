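# meomics

Growth-coupled **m**etabolism-and-**e**xpression modeling with paired
RNA-Seq/Ribo-Seq **omics** analysis, exercised end-to-end on synthetic study
systems.

Constraint-based metabolic models (M-models) predict flux distributions from
stoichiometry and uptake bounds alone, which lets them overestimate growth
and miss by-product secretion.  ME-models add the expression machinery —
every enzyme must be transcribed and translated, ribosomes must replicate
themselves, and the whole proteome is diluted by growth — which caps growth
mechanistically and makes proteome allocation a prediction rather than an
input.  This package implements that model class at desk scale, the
statistics used to interrogate proteome allocation from sequencing data, and
the benchmark that connects the two.  It is written for systems-biology
practitioners who want the mechanisms and the statistics testable without a
genome-scale reconstruction.

## What is inside

| module | what it does |
|---|---|
| `meomics.me_core` | μ-parameterized stoichiometric models: coefficients `a + b·μ`, LP feasibility at fixed μ (HiGHS), growth maximization by bisection, FVA, knockout essentiality, substrate scans, stripping expression to an M-analog |
| `meomics.synthetic_data` | toy cells engineered to show proteome limitation and overflow; negative-binomial paired RNA/Ribo count simulator with planted pathway-level TE effects and full generating truth |
| `meomics.omics` | CPM normalization, replicate QC (PCC + Welch t-tests), translational efficiency `TE = Ribo CPM / RNA CPM`, pathway prioritization by one-tailed Mann–Whitney U on cross-dataset ranks |
| `meomics.benchmark` | subsystem aggregation, log10(f+1) transform, OLS + Pearson correlation between model predictions and omics profiles |
| `meomics.io_cli` / `meomics.cli` | versioned JSON model format, counts/pathway TSV, run configuration, the end-to-end pipeline with checksummed manifest, and the `meomics` subcommand CLI |

The model solved at each fixed μ is the feasibility problem
`S(μ)·v = 0, lb ≤ v ≤ ub, v_growth = μ`; the maximum growth rate is the
largest feasible μ, found by bisection.  Enzyme usage enters the
stoichiometry as `−μ/k_eff` per unit flux (usage plus dilution), ribosome
usage as `−μ·L/c_ribo`.  See `docs/methods.md` for the full model and every
numerical choice.

## Worked example

```
$ python analysis/02_growth_and_overflow.py --seed 1
max growth at uptake 10.0: mu* = 0.2792 1/h (expression-coupled) vs 1.0000 1/h (stripped analog)
overflow secretion starts between uptake 5.26 and 6.32 (threshold ~ 5.79 mmol/gDW/h)
growth saturates: marginal gain falls from 0.0868 to 0.0018 per unit uptake
```

The expression-coupled cell grows at 0.28 h⁻¹ where its metabolism-only
analog predicts 1.0 h⁻¹: expression costs, not substrate supply, limit
growth.  Scanning uptake shows the signature of overflow metabolism — zero
by-product secretion until uptake ~6 mmol/gDW/h, then steadily increasing
secretion as the capped respiratory proteome saturates — while the analog
grows linearly and never secretes.

```
$ python analysis/06_translational_prioritization.py
rna: replicate QC PASS (min pairwise PCC 0.981)
ribo: replicate QC PASS (min pairwise PCC 0.983)
1 pathway(s) translationally prioritized up:
  pw000: TE = 2.10, right-tailed p = 1.62e-04
1 pathway(s) prioritized down:
  pw001: TE = 0.55, left-tailed p = 5.07e-03
```

The simulator planted a 2.0× TE effect on `pw000` and 0.5× on `pw001`
(`analysis/05_simulate_omics.py`); the rank tests recover both, and the 48
unperturbed pathways stay non-significant.

```
$ python analysis/07_benchmark_models.py --seed 1
expression-coupled model vs simulated footprints: PCC = 0.975 (p = 8.82e-22, n = 33 subsystems)
stripped analog vs simulated footprints:          PCC = 0.023 (p = 8.99e-01)
the expression-coupled model outperforms the stripped analog
```

When footprint abundances track the ME model's proteome allocation, the
ME translation-flux profile correlates near-perfectly with subsystem-level
footprint CPM; the stripped analog cannot see how catalytic efficiency
shapes allocation and correlates far worse.

The numbered scripts under `analysis/` run the whole story in order
(01 models → 02 growth/overflow → 03 FVA → 04 essentiality → 05 omics →
06 prioritization → 07 benchmark); `meomics run-all --seed 0 --outdir out`
produces the same artifacts as one pipeline with a checksummed manifest.

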
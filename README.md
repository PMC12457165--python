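# selindex

Genomic selection for working-dog breeding programs: GBLUP breeding values,
multi-trait selection indices, and cross-validated predictive evaluation.

Guide-dog schools breed from closed colonies and decide, dog by dog, who
enters the breeding program. `selindex` implements the full analysis such a
program needs to move from pedigree intuition to marker-based selection:

* a **liability-threshold population simulator** (gene-dropped genotypes,
  parent trios, binary/ordinal/continuous traits with set heritabilities,
  and a training-success outcome correlated with the traits),
* **SNP quality control** (variant/sample call rate, exact Hardy–Weinberg
  test, minor-allele-frequency filter),
* the **additive genomic relationship matrix** (single-ratio construction
  G = MMᵀ / Σ 2pⱼ(1−pⱼ)) with principal-component covariates,
* **REML/GBLUP**: for y = Xβ + u + e with u ~ N(0, σ²g G), a single
  eigendecomposition reduces restricted likelihood maximization to a 1-D
  search over h² = σ²g/(σ²g+σ²e) (the *pseudo-heritability*), yielding
  genomic estimated breeding values (gEBVs) and holdout predictions,
* **selection indices**: trainer categories condensed to ordinal scores,
  direction-aware normalizations
  (negative |xₘₐₓ−x|/xₘₐₓ, positive x/xₘₐₓ, neutral 1−|x−1|),
  correlation-weighted Behavior and Health Scores, the Dental/Ocular/Dermal
  /Health Counts, and the combined
  Total Score = w_health·(Health Score) + w_behavior·(Behavior Score),
* **five-fold cross-validated evaluation** with the metric family matched to
  trait type: MCC and AUROC for binary traits, Kendall's τ-b and Spearman's
  ρ for ordinal traits, Pearson R and NMSE for continuous scores.

## A worked example

```sh
python examples/03_selection_indices.py
```

```
Pace 'High average'  -> 2
Rating '3+'          -> 3
Soundness 'Sound'    -> 2

Behavior Score: strong 1.054, weak 0.133 (each normalized trait x |correlation with success|, summed)
Health Score with atopic dermatitis + mandibular distocclusion: -0.205
category counts (dental, ocular, dermal, total): (1, 0, 1, 2)
Total Score (strong dog, those diagnoses): 0.337
```

The strong candidate's Behavior Score approaches the sum of the trait
weights (every normalized trait near its optimum); the two diagnoses each
contribute their negative correlation with success (−0.1 and −0.105) to the
Health Score; the Total Score blends the two indices with the default
weights w_health = 0.02, w_behavior = 0.324.

A cross-validated GBLUP run (`python examples/04_gblup_cross_validation.py`):

```
gait: pseudo-h2 0.650 (simulated 0.5); corr(gEBV, true BV) = 0.762
gait 5-fold CV: Pearson R 0.311, NMSE 0.930 (1.0 = no better than the mean)
panosteitis 5-fold CV: AUROC 0.534, MCC -0.025 (MCC stays near 0 while the linear predictor rarely crosses 0.5)
```

The remaining scripts in `examples/` cover population simulation, QC + GRM
construction, and the behavior-score fixed-effect uplift when predicting
training success.

## Command line

A thin CLI wraps the library for shell pipelines:

```sh
selindex simulate --out-prefix work/geno --seed 1
selindex qc --in work/geno --out work/clean
selindex grm --in work/clean --out work/grm --pcs 3
selindex index --pheno work/geno.pheno.csv --out work/scored.csv
selindex evaluate --pheno work/scored.csv --grm work/grm --k 5 --seed 1 --out work/report
selindex run --config run.yaml        # all stages from one config
```

Exit codes: 0 success, 2 configuration error, 3 data error.

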
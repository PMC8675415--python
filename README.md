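# brainvar

Tools for mega-analysis of **sex differences in the variability of regional
brain structure** across the lifespan. Many human traits show greater male
than female between-subject variance; `brainvar` implements the full
statistical pipeline used to test this in multi-cohort structural MRI data —
subcortical volumes, cortical surface area, and cortical thickness on the
Desikan-Killiany parcellation — together with a synthetic cohort generator
with known ground truth, so every stage can be validated end-to-end without
access to restricted subject-level data.

The pipeline, per measure class (14 subcortical / 68 area / 68 thickness
measures):

1. **Harmonization** (`brainvar.harmonize`). Two-step covariate adjustment of
   each measure *y*: an OLS fit on cohort indicators plus a cubic age
   polynomial, then random-forest regression of the residuals on scanner
   field strength and segmentation-software version. The residuals
   *r*ᵢ = *y*ᵢ − *ŷ*ᵢ feed all downstream stages. Sex is never a covariate.
2. **Mean and variance tests** (`brainvar.varstats`). Pooled-SD Cohen's *d*
   (positive = male larger) with Student t-tests; the variance ratio
   *T* = Var♂/Var♀ and its log; a permutation test that reassigns sex labels
   among the residuals (*B* = 10,000 by default),
   *p* = Σ_b I(*T*_b > *T*)/*B* one-sided or |ln *T*_b| ≥ |ln *T*| two-sided;
   Benjamini–Hochberg FDR within each measure class; and the Pearson
   correlation between the log-VR and *d* vectors.
3. **Shift functions** (`brainvar.shiftfn`). After aligning group means, the
   decile difference function *D*(*q*) = *Q*(*q*|♂) − *Q*(*q*|♀) with
   Harrell–Davis quantile estimates and stratified-bootstrap 95% CIs.
   A positive slope of *D* in *q* (negative at low deciles, positive at high
   ones) means greater male spread at **both** tails.
4. **Dispersion across age** (`brainvar.ageint`). |*r*ᵢ| regressed on
   age × sex (linear) and age² × sex (quadratic), FDR on the interaction term:
   does the sex gap in spread change over the lifespan?
5. **Anatomical correlations** (`brainvar.homogeneity`). After sex-specific
   standardization, per-sex inter-regional Pearson matrices *M*ᵢⱼ and *F*ᵢⱼ,
   their difference, per-edge two-sided permutation tests on the Fisher-z
   difference, and a 1-df chi-square on the directional counts of significant
   edges.

## Worked example

Simulate eight cohorts (6,400 subjects, staggered age windows inside 1–90 y,
~52% female) with the package's default subcortical effect sizes — per-region
Cohen's *d* 0.41–0.92 and log VR 0.12–0.36, a variance gap that narrows with
age, and stronger female inter-regional correlation — then run everything:

```python
from brainvar.cli_pipeline import PipelineConfig, run_all, report

cfg = PipelineConfig(
    seed=1, outdir="demo", classes=("subcortical_volume",),
    simulate={"n_cohorts": 8, "n_per_cohort": 800},
    recipe={"n_trees": 100, "min_leaf": 50},
    B=2000, n_boot=200,
)
run_all(cfg)
print(report("demo"))
```

prints (about 40 s):

```
# brainvar report

## subcortical volume

- 14 of 14 measures show FDR-significant mean sex differences
- 14 of 14 measures show FDR-significant variance differences (male/female variance ratio)
- correlation of log VR with d: r(12) = 0.47, p = 0.0926
- shift functions: 14 greater_male_variance
- dispersion-by-age interactions (FDR): order 1: 0, order 2: 0
- anatomical correlations: of 91 edges, 0 stronger in males, 91 stronger in females (chi2(1, N=91) = 91.000, p = 1.44e-21)
```

Reading it: every simulated volume shows the injected male mean advantage and
male variance excess; all shift functions classify as greater male variance
(wider male distribution at both tails); the injected age-declining variance
gap produces consistently negative sex-by-age coefficients but is too subtle
to reach FDR significance at n = 6,400 (it is reliably detected at
n = 20,000 — see the acceptance suite); and the female-stronger correlation
structure dominates all 91 region pairs. The same subcommands are available
from the shell via `brainvar simulate|run|harmonize|vartest|report`.

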
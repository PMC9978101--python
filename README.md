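# dcnet

Degree-centrality analysis of resting-state functional brain networks.

`dcnet` is for researchers who study group differences in resting-state fMRI
connectivity — here, healthy controls (HC), subclinical depression (SD) and
major depressive disorder (MDD) — using graph-theoretic nodal statistics. It
implements the full analysis chain from ROI time series to discriminative
biomarkers:

1. **Preprocessing** — discard the first 10 volumes; compute framewise
   displacement FD(t) = Σₚ |Δparamₚ(t)| (rotations as arc length on a 50 mm
   sphere); exclude subjects with < 3 min of scan surviving FD > 0.2 mm
   scrubbing, or motion > 2 mm / rotation > 2°; scrub flagged volumes; regress
   the 24-parameter motion model plus the parcellation-mean signal; band-pass
   0.01–0.08 Hz (zero-phase Butterworth).
2. **Network construction** — Pearson correlation between every pair of the
   g = 246 parcel time series; binarize at sparsity S by keeping the
   K = round(S·g(g−1)/2) strongest correlations (sweep S = 0.05…0.40 in steps
   of 0.01, 36 networks; reporting threshold S = 0.30). Degree centrality of
   node i is C_D(N_i) = Σ_j d_ij (i ≠ j).
3. **Group inference** — per node, the ANCOVA-style model
   DC ~ group + age + sex + education + mean FD; F test of the group factor
   with Bonferroni correction across nodes, then covariate-adjusted pairwise
   t tests (MDD–HC, SD–HC, MDD–SD) on the significant set.
4. **Discrimination** — ROC analysis of each flagged region's DC
   (AUC, DeLong 95% CI, p for AUC = 0.5, Youden cut-off with
   sensitivity/specificity in %), and a composite index from unpenalized
   logistic regression z_i = a₀ + Σ_j a_j X_ij, P_i = 1/(1+e^(−z_i)).

Because clinical rs-fMRI data of this kind cannot be redistributed, the
package ships a first-class **synthetic cohort generator**: multi-group ROI
time series with modular covariance, AR(1) temporal structure, realistic
motion traces (drift + spikes), Table-style phenotypes, and *planted*
hub-connectivity effects with known ground truth, so every stage of the
pipeline is verifiable by parameter recovery.

## Worked example

```python
from dcnet import CohortSpec, EffectSpec, weakest_hub, generate_cohort
from dcnet import clean_subject, nodewise_anova, posthoc_pairwise
from dcnet.network import build_dc_table
import pandas as pd

probe = CohortSpec(n_per_group={"HC": 2, "SD": 2, "MDD": 2}, g=60, T=200, seed=101)
hub = weakest_hub(probe)                      # node 14 ("BNA-015") for this seed
spec = CohortSpec(
    n_per_group={"HC": 30, "SD": 30, "MDD": 30}, g=60, T=200, seed=101,
    effects=(EffectSpec("MDD", hub, 20, 0.3),),   # +0.3 hub-partner coupling in MDD
)
records, truth = generate_cohort(spec)

series, rows = {}, []
for rec in records:
    clean, qc = clean_subject(rec, tr_seconds=2.5)
    if clean is not None:
        series[rec.subject_id] = clean.series
        rows.append({"subject_id": rec.subject_id, "group": rec.group,
                     "age": rec.age, "sex": rec.sex,
                     "education": rec.education, "mean_fd": qc.mean_fd})
pheno = pd.DataFrame(rows)

dc = build_dc_table(series, 0.30)             # 90 x 60 degree table, rows sum to 2K
anova = nodewise_anova(dc, pheno)
print(anova[anova.significant].head(3))
print(posthoc_pairwise(dc, pheno, ("MDD", "HC"), nodes=["BNA-015"]))
print(posthoc_pairwise(dc, pheno, ("SD", "HC"), nodes=["BNA-015"]))
```

The effect is planted as a strengthened module around the hub, so the ANOVA
flags the hub together with its partner neighborhood (21 of 60 nodes here):

```
                 F         p_raw        p_bonf  significant
node
BNA-001  21.728363  2.577214e-08  1.546328e-06         True
BNA-005   8.404931  4.742885e-04  2.845731e-02         True
BNA-008  22.517029  1.540750e-08  9.244502e-07         True
```

The pairwise tests at the hub confirm the planted contrast — elevated in the
affected group, null in the unaffected comparison:

```
                t     p_raw    p_bonf  significant direction
node
BNA-015  4.740134  0.000016  0.000016         True    MDD>HC
                t     p_raw    p_bonf  significant direction
node
BNA-015 -0.540723  0.590922  0.590922        False     SD<HC
```

The same analysis runs from the shell:

```bash
dcnet run-all --config run.yaml --seed 101   # simulate -> prep -> network -> stats -> roc
```

writing motion QC, the DC table, ANOVA/post-hoc tables, ROC reports and a
reproducibility manifest into the configured output directory.

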
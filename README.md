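# crcpod

Cross-cohort gut-microbiome screening and probability-of-disease (POD)
modelling for colorectal-cancer (CRC) risk.

## What this is for

Family members and close cohabitants of CRC patients carry elevated CRC
risk, and their stool microbiomes may show early, disease-like shifts.
`crcpod` is a reusable implementation of the analysis workflow used to
quantify that risk from species-level metagenomic profiles: given
MetaPhlAn-style relative-abundance tables from several case/control
cohorts, it screens each cohort for differentially abundant species
(two-tailed Wilcoxon rank-sum, α = 0.05, unadjusted), pools the hits into
a biomarker panel restricted to species detected in the target cohorts,
trains one random forest per screening cohort on the panel, and scores
new individuals with the **POD index**

> POD(x) = (number of trees voting "disease" for profile x) / T,

the fraction of T randomly constructed decision trees classifying the
sample as diseased — a bounded proxy for the ratio of an individual's
likelihood of disease to their likelihood of health. Model transfer is
quantified by the AUC of POD against case/control labels in held-out
cohorts, AUC = P(POD_case > POD_control) + ½·P(tie).

Supporting stages: percent→proportion normalization with an optional
pseudo-count (1e-05) log10 transform; alpha diversity (Shannon −Σpᵢ ln pᵢ,
Simpson 1 − Σpᵢ², observed species, Gini); PCoA on Bray-Curtis
(Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)), Jensen-Shannon distance (base-2, square root),
Pearson and Spearman (1 − r) dissimilarities; Spearman correlation of taxa
with covariates such as red-meat intake; and the demographic-table
statistics (exact two-sided Fisher, Student's t, Pearson chi-square,
one-way ANOVA, percentage summaries). A synthetic multi-cohort generator
with planted differential species, per-cohort batch effects and a linked
binary diet covariate makes every stage testable without any downloads.

## Worked example

Two simulated cohorts sharing 20 planted differential species among 200
(4-fold case/control shift, cohort-specific batch effects); screen the
"external" cohort, train on it, score the other:

```python
import numpy as np
import crcpod as cp

cfgs = [cp.SyntheticConfig(cohort=c, n_taxa=200, n_diff=20, effect_fold=4.0,
                           n_case=100, n_control=100)
        for c in ("external", "zhengzhou")]
coll, truth = cp.simulate_multi_cohort(cfgs, shared_planted=True, seed=7)
ext_t, ext_m = coll.cohorts["external"]
zz_t, zz_m = coll.cohorts["zhengzhou"]
y_ext = cp.case_control_labels(ext_m)

screen = cp.wilcoxon_screen(ext_t, y_ext, alpha=0.05, cohort="external")
panel = cp.overlap_biomarkers([screen], cp.detected_taxa([zz_t]))
model = cp.train_forest(ext_t, y_ext, panel, n_trees=500, seed=7)
imp = cp.mda_importance(model, ext_t, y_ext, seed=7)

pod = model.pod(zz_t)
y_zz = cp.case_control_labels(zz_m).to_numpy()
print("significant taxa:", int(screen.significant.sum()))
print("panel size:", len(panel))
print("OOB error:", round(model.oob_error, 4))
print("top biomarker:", imp.idxmax(), round(imp.max(), 4))
print("median POD cases:", round(np.median(pod[y_zz]), 3),
      "controls:", round(np.median(pod[~y_zz]), 3))
print("cross-cohort AUC:", round(cp.roc_auc(pod, y_zz).auc, 4))
```

Output:

```
significant taxa: 33
panel size: 33
OOB error: 0.0
top biomarker: s__Taxon_0196 0.0345
median POD cases: 0.742 controls: 0.201
cross-cohort AUC: 1.0
```

33 of 200 species pass the screen (the 20 planted ones plus closure
side-effects and a few false positives); the forest separates the training
cohort perfectly out-of-bag, the top mean-decrease-accuracy biomarker is a
planted species, and the model transfers to the second cohort: cases score
a median POD of 0.74 versus 0.20 for controls, AUC 1.0 at this effect
size. Weakening `effect_fold` toward 1 drives the AUC to 0.5.

The same flow is available from the shell:

```bash
crcpod simulate --config cohorts.yaml --out data/
crcpod diff --table data/abundance_external.tsv --metadata data/metadata_external.tsv --out screen.tsv
crcpod overlap --screen screen.tsv --detected-table data/abundance_zhengzhou.tsv --out panel.tsv
crcpod train --table data/abundance_external.tsv --metadata data/metadata_external.tsv \
             --panel panel.tsv --trees 500 --seed 7 --out model.json
crcpod score --model model.json --table data/abundance_zhengzhou.tsv --out pod.tsv
crcpod evaluate --scores pod.tsv --metadata data/metadata_zhengzhou.tsv --out eval.json
```

or end-to-end from one YAML config with `crcpod run`, which writes
screens, panel, serialized models, POD scores, `eval.json` and a hashed
manifest, byte-identically across reruns of the same seed.

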
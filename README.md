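# glandstab

Stability-informed gland histomorphometry for multi-site H&E
histopathology.

Classifiers built on quantitative tissue morphology often fail to
transfer between hospitals: fixation, staining and scanning differences
shift feature distributions site by site, and features selected only for
discriminability on pooled training data can owe their apparent signal
to exactly those shifts. `glandstab` is a toolkit for measuring that
problem and selecting around it. It

* extracts a fixed **242-feature** vector per annotated region of
  interest — global gland-graph architecture (51), gland shape (100),
  gland orientation disorder (39), gland sub-graphs (26) and Haralick
  texture (26);
* quantifies each feature's **preparation-induced instability (PI)**:
  the fraction of site pairs in which the feature's distribution differs
  significantly (two-sided Wilcoxon rank-sum, α = 0.05) between the
  sites' non-cancerous regions, and the within-site baseline **latent
  instability (LI)** from random half-splits;
* gates feature selection on stability: FS_sd^θ selects from features
  with PI < 0.25 only, FS_d^θ from all features, for selectors
  θ ∈ {SFS, WLCX, mRMR, ROC};
* evaluates cross-site generalization by **hold-one-site-out**
  validation with κ ∈ {LDA, QDA, SVM, RF} classifiers on the top-5
  selected features;
* provides Macenko-style **stain normalization**, lumen-based **gland
  segmentation**, a gland-removal **perturbation experiment**, and a
  **synthetic-data subsystem** (H&E-like ROIs with ground-truth glands
  and site effects; multi-site feature tables with known
  discriminative/unstable structure) so the entire pipeline runs and is
  tested without any clinical data.

For a feature f with values x_s at site s, exact-mode PI is

    PI(f) = #{(s, t) : p_ranksum(x_s, x_t) < α} / C(m, 2)

over the C(m, 2) unordered pairs of m sites. The stability gate admits f
iff PI(f) < 0.25 computed on the training sites' non-cancerous regions
only; selection, training and the gate never see the held-out site.

See `docs/methods.md` for the full model description, parameter defaults
and design choices.

## Worked example

Run the bundled synthetic multi-site experiment — a Gleason-grading
analogue with 4 sites × 40 task regions (plus 20 non-cancerous regions
per site for the instability step), in which the apparently strongest
features carry 3σ site shifts and only moderate stable features carry
real signal:

```sh
glandstab run --demo --seed 0 --outdir demo_out
```

This writes `features.csv`, `instability.csv`, `report.csv` and
`summary.txt`, and prints the selector × classifier grid (excerpt):

```
selector classifier          FS_sd           FS_d  % improvement
sfs      lda        0.81 (0.08)   0.74 (0.14)            9.18
wlcx     lda        0.80 (0.10)   0.63 (0.19)           27.38
mrmr     lda        0.82 (0.04)   0.75 (0.13)            9.83
roc      lda        0.80 (0.10)   0.63 (0.19)           27.38
...
```

Each cell is the mean (std) held-out-site AUC over the four
hold-one-site-out folds; `% improvement` is 100·(AUC_sd − AUC_d)/AUC_d.
Under this seed the stability-gated variant wins 14 of the 16
(selector, classifier) cells: the ungated selectors keep picking the
site-confounded features, whose training separation evaporates on the
held-out site.

The same machinery is available from Python:

```python
from glandstab.synthetic import make_demo_table
from glandstab.stability import preparation_instability
from glandstab.evaluation import hold_one_site_out

table, truth = make_demo_table(seed=0)
pi = preparation_instability(table[table["class"] == "noncancer"]).pi
report = hold_one_site_out(table, "gleason", "wlcx", "lda",
                           gated=True, seed=0)
print(pi.sort_values(ascending=False).head(), report.mean_auc)
```

Other CLI entry points: `glandstab simulate roi|table`, `segment`,
`normalize`, `extract`, `stability`, `select`, `evaluate`.

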
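# laterec

Discovery and validation of **late-recurrence gene signatures** in breast
cancer expression compendia.

Roughly a third of node-negative breast-cancer patients relapse more than
five years after treatment. These late recurrences are thought to reflect
escape from tumor dormancy, and the classical clinical predictors (grade,
size, basal-like subtype) are prognostic for *early* but not *late*
relapse. `laterec` implements, as a tested library + CLI, the analysis
chain needed to mine multi-study microarray compendia for genes whose
prognostic effect is confined to the late window, and to link them to
stromal activation in the tumor microenvironment:

1. **Harmonization** — merge studies on a common probe set and remove
   cross-study artifact: the structure of invariant control probes is
   captured by their first *k* principal components (defaults 40 / 15) and
   regressed out of every probe.
2. **Receptor calls & subtypes** — ER/PR/HER2 from the bimodal
   maximum-likelihood cutoff anchored on partially observed IHC labels
   (cutoff = prior-weighted density crossing of the two fitted normals),
   then Luminal A/B, HER2 type, TNBC by the receptor rules.
3. **Time-window Cox screen** — for each probe, univariable Cox fits
   (Efron ties, Wald tests) under three censoring constructions: overall,
   *early* (events at/after the 5-year boundary censored) and *late*
   (events before it censored); probes are classified early- or
   late-associated at p < 0.001 with direct/inverse direction.
4. **Subgrouping** — two-way centroid-linkage hierarchical clustering
   (correlation distance) of the selected probes over samples into
   subgroups G1–G4 and gene clusters C1–C4, with Kaplan–Meier/log-rank
   subgroup survival and Fisher/odds-ratio enrichment tables
   (Woolf logit 95% CIs).
5. **Stromal signature** — in paired epithelium/stroma tumors, per-probe
   Welch t of the late-like subgroup's stroma vs the rest at BH FDR <
   0.05; the selected set is summarized as SPC1, its anchored first
   principal component.
6. **Epithelial signature** — the three-filter cascade (r with SPC1 >
   0.25; upregulated in the late-like subgroup's epithelium at FDR < 0.05;
   directly recurrence-associated at Cox p < 0.01) yields the epithelial
   late-recurrence signature and its metagene EPC1, validated against
   metastasis-timing groups (early <5y, late ≥5y, event-free ≥15y) by
   exact Mann–Whitney and ANOVA.

Because the original multi-GEO compendium is not redistributable, the
package ships a first-class **synthetic cohort generator**
(`laterec.synthetic`) that emulates the structure each stage assumes —
batch factors visible in control probes, bimodal markers with partial IHC,
a piecewise-exponential hazard in which planted early/late gene programs
act only before/after the boundary, discrete prognostic subgroups, and
paired compartments sharing a latent stromal factor — with every planted
quantity recorded for recovery testing. See `docs/methods.md` for the
full model and parameter table.

## Worked example

Run the whole pipeline on a synthetic cohort at the default study
conditions (4 studies × 200 bulk tumors + 46 epithelium/stroma pairs,
1000 probes, seed 45):

```bash
laterec run --out run45 --seed 45
laterec report --run-dir run45
```

or equivalently in Python:

```python
from laterec import CohortSpec, PipelineConfig, run_pipeline
run_pipeline(PipelineConfig(cohort_spec=CohortSpec(seed=45),
                            out_dir="run45", seed=45))
```

Selected numbers from `run45` (your machine will reproduce them exactly —
the run is bit-deterministic given the seed):

* `subgroup_survival.tsv` — the four expression subgroups separate
  survival under every censoring scheme; e.g. the late-window log-rank
  chi-square is 156.9 (p = 8.4e-34), confirming that the screen-selected
  probes carry late-recurrence structure.
* `cascade.tsv` — the three-filter cascade selects 40 probes; all of them
  are the generator's planted stroma-coupled late-program genes
  (Jaccard 1.0 against the planted set).
* `validation_summary.json` — the EPC1 score separates metastasis-timing
  groups: median −2.21 in patients event-free ≥15 years, −0.88 for early
  metastasis, +4.08 for late metastasis; ANOVA across
  time-of-metastasis bins p = 2.9e-20; the late-enriched gene-cluster
  metagene agrees with EPC1 at Pearson r = 1.00.

Interpretation: tumors destined for late relapse carry a coherent
expression program that (a) is invisible to the early-window screen, (b)
defines its own subgroup in the two-way clustering, and (c) is mirrored by
an activation signature in the paired stroma — exactly the structure the
generator plants, recovered end to end.

Single stages are available as `laterec synth`, `laterec harmonize`,
`laterec call-receptors`, `laterec screen`, and `laterec run --from
<stage> --to <stage>` for partial reruns on cached outputs.

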
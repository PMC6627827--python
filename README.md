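# bonemet

Prediction of bone-metastasis risk in breast cancer from a
phenotype-conditioned **gene dependency network**: network inference by
conditional mutual information, biomarker mining by structural
controllability, and patient classification with a nearest-centroid model,
evaluated by survival analysis, AUC and MCC.

## The method

Bone is the most common metastatic site in breast cancer, and the clinically
established horizon for calling a patient high-risk is relapse within five
years. Given an expression matrix (genes × patients), a clinical table
(metastasis-free time, event status) and a protein–protein interaction (PPI)
scaffold, the pipeline runs six stages:

1. **Preprocess** — expression is binarised per gene at its median; patients
   are labelled high-risk (bone metastasis within 5 years), low-risk
   (metastasis-free beyond 5 years) or excluded (censored early). Candidate
   ordered gene pairs are restricted to PPI edges, both orientations.
2. **Dependency network** — for a candidate pair (modulator *B*, dependent
   *A*), patients are sorted by *B*'s continuous expression and the score

   CMI(A|B) = I_high(A; risk) − I_low(A; risk)

   is the difference of mutual information between *A*'s binarised
   expression and the risk label in the top and bottom 35% tails of *B*. A
   two-sided permutation test (1000 permutations of *B*, p-value with +1
   pseudocount) keeps pairs with p < 0.05 as directed edges *B* → *A*.
   Degree distributions are checked for scale-free shape by log–log
   regression.
3. **Driver mining** — a directed network is structurally controllable from
   a minimal driver set of size N − |maximum matching|, computed in the
   bipartite split representation (out-copy/in-copy per gene). Because
   maximum matchings are not unique, the matching is resampled under 500
   random node orderings; genes present in **every** sampled minimal driver
   set become biomarker candidates.
4. **Signature** — candidates are refined by a two-sided Welch t-test on
   continuous expression between high- and low-risk training patients;
   genes with p < 0.002 form the signature.
5. **Centroid classifier** — class centroids c⁺, c⁻ over the signature give
   the weight vector w = c⁺ − c⁻ and midpoint c = (c⁺ + c⁻)/2; a sample s
   is scored by γ = ⟨s − c, w⟩ and called high-risk iff γ > 0 (equivalent
   to nearest-centroid assignment; γ is the continuous risk score).
6. **Evaluation** — Kaplan–Meier curves with the log-rank test compare
   predicted risk groups on metastasis-free time; ranking quality is the
   Mann–Whitney AUC of γ, thresholded quality is accuracy and the Matthews
   correlation coefficient.

A fully seeded synthetic-cohort generator (`bonemet.synth`) plants
modulator→dependent dependencies inside a preferential-attachment PPI
scaffold, together with consistent survival times, so every stage is
testable without external downloads.

## Worked example

```python
import bonemet as bm

cfg = bm.SynthConfig(n_genes=150, n_patients=800, n_planted_pairs=10,
                     effect_size=0.5, seed=1, split_fractions=(0.5, 0.5, 0.0))
scaffold = bm.synth.generate_scaffold(cfg)
expr, clinical, truth = bm.synth.generate_cohort(cfg, scaffold)

pipe = bm.PipelineConfig(n_perm=200, runs=100, seed=1,
                         split_fractions=(0.5, 0.5, 0.0))
res = bm.run_pipeline(expr, clinical, scaffold, pipe)

stats = res.network_stats
print(f"network: {stats.n_edges} edges over {stats.n_nodes} genes "
      f"(mean degree {stats.mean_out_degree:.3f})")
print(f"planted pairs recovered: "
      f"{len(set(truth.pairs) & set(res.network.edges))}/{len(truth.pairs)}")
print(f"matching size {res.driver_freq.matching_size}, "
      f"minimal driver set {res.driver_freq.driver_set_size}, "
      f"{len(res.driver_candidates)} genes in every driver set")
print(f"signature: {res.signature.genes}")
m = res.metrics["test"]
print(f"held-out test set: AUC={m['auc']:.3f} accuracy={m['accuracy']:.3f} "
      f"MCC={m['mcc']:.3f} log-rank p={m['logrank_p']:.4f}")
```

prints

```
network: 47 edges over 53 genes (mean degree 0.887)
planted pairs recovered: 10/10
matching size 34, minimal driver set 19, 15 genes in every driver set
signature: ['G0021', 'G0062', 'G0018', 'G0064', 'G0029', 'G0119']
held-out test set: AUC=0.688 accuracy=0.642 MCC=0.227 log-rank p=0.0406
```

All ten planted dependencies are recovered as network edges; the minimal
driver set (19 of 53 genes) narrows to 15 genes required in every sampled
matching, six of which are differentially expressed and form the signature.
The classifier then separates held-out patients (AUC 0.69) into risk groups
with significantly different metastasis-free survival (log-rank p = 0.04).

The same pipeline is available from the shell:

```sh
bonemet simulate --config synth.yaml --outdir cohort/
bonemet run-all --expr cohort/expression.tsv --clinical cohort/clinical.tsv \
        --ppi cohort/scaffold.tsv --outdir run/
```

Each stage (`preprocess`, `network`, `drivers`, `select`, `train`,
`predict`, `evaluate`) can also be run separately on TSV/JSON artifacts;
`run/manifest.json` records every parameter and seed needed to reproduce a
run bit for bit.

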
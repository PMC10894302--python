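# transdx

Transdiagnostic symptom profiling and drug-class recommendation for
mental-health questionnaire cohorts.

Conventional psychiatric diagnoses group patients by category (depression,
anxiety, ...), yet symptom profiles cut across those categories and
self-reported diagnoses often disagree with scale-based ones. `transdx`
implements a clinical-decision-support pipeline that works directly from
questionnaire responses:

1. **Profiling.** Mixed-type items (eight symptom categories A–H plus age
   and sex) are one-hot/numerically encoded and standardized, then
   clustered two ways: k-means with Euclidean distance (k chosen by the
   mean silhouette s̄ = mean over subjects of (b−a)/max(a,b)), and Louvain
   community detection on a k-nearest-neighbor patient similarity graph
   (Minkowski p = 2, default k_nn = 100, greedy maximization of modularity
   Q = Σ_c [L_c/m − (d_c/2m)²]).
2. **Characterization.** Each cluster is explained by its diagnosis
   composition (emitted as Sankey-ready flow tables), by L1-penalized
   one-vs-rest logistic regression reporting features with coefficient
   β > 0.2, and by category index scores (items min–max scaled to [0, 1]
   and averaged within category).
3. **Recommendation.** Two engines rank the psychotropic drug classes
   AD / AP / MS / SH (antidepressants, antipsychotics, mood stabilizers,
   sedative–hypnotics). The *cluster* engine recommends the classes with
   the highest prescription probability among a cluster's labeled members.
   The *network* engine grows each subject's neighborhood on the
   similarity graph ring by ring until it contains at least 20 subjects
   with prescription history, then ranks classes by prescription count
   (competition ranking: ties share a rank, so a top-3 recommendation can
   hold more than three classes).
4. **Scale-based diagnosis.** A rule engine maps clinical scale scores to
   diagnoses (defaults: depression at HAMD ≥ 7; anxiety at HAMA ≥ 10 or
   PDSS ≥ 8; bipolar at MDQ ≥ 7 or HCL-32 ≥ 12) and quantifies
   inconsistency against self-reported diagnoses.

Real questionnaire cohorts of this kind are access-controlled, so the
package ships a synthetic-cohort generator with known latent structure
(groups, category elevations, group-conditional prescription
probabilities) that exercises and validates every stage end to end.

## Worked example

Run the full pipeline on a synthetic cohort of 1,000 subjects with four
strongly separated symptom groups:

```sh
$ transdx run --preset separable-4 --n 1000 --seed 7 --out demo
{
 "kmeans_ari_vs_truth": 1.0,
 "kmeans_k": 4,
 "kmeans_silhouette": 0.22808796418823,
 "louvain_ari_vs_truth": 1.0,
 "louvain_modularity": 0.7454351168588693,
 "louvain_n_communities": 4,
 "louvain_resolution": 0.5,
 "louvain_silhouette": 0.22808796418823
}
report	demo/report.json
```

Silhouette selection picked k = 4 and the Louvain sweep settled on four
communities; both partitions match the planted grouping exactly
(adjusted Rand index 1.0 against the generator's latent groups, which the
pipeline never sees). The modularity Q ≈ 0.75 reflects four well-separated
communities on the 100-NN graph. `demo/` also holds the audit tables
(k → silhouette, resolution → (communities, Q, silhouette)), cluster
characterization tables, per-subject recommendations from both engines and
`evaluation.json`; in this run 10.4% of subjects carried prescriptions and
the network engine's recommendations overlapped the actually prescribed
classes for 98.1% of labeled subjects.

The same stages are available individually (`transdx simulate / load /
profile / characterize / recommend`) and as library functions
(`transdx.fit_kmeans`, `transdx.build_knn_graph`,
`transdx.network_based_recommend`, ...).

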
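# icam — collective multi-label classification on attributed networks

`icam` predicts ranked sets of labels for the unlabeled nodes of a
partially labeled, attributed network. The motivating application is
protein function prediction from protein–protein interaction (PPI)
networks: a protein's direct interaction partners tend to share its
biological functions, so the interaction graph carries signal that
per-protein attribute features alone do not — and vice versa. The same
setup fits any homophilous network whose nodes carry feature vectors and
(possibly several) class labels, e.g. co-authorship graphs with
research-area labels.

The method targets the **label-deficiency regime**: when few nodes are
labeled, classic iterative classification (ICA) with a local supervised
classifier starves, because most nodes have no labeled neighbor. `icam`
replaces the local classifier with transductive random walks that
propagate the scarce label information through *all* nodes, labeled and
unlabeled.

## The model

Given a graph G(V, E) over m nodes with attribute vectors x_i ∈ X_A,
label sets Y_i over c classes known only on V^K ⊂ V:

1. **Channels.** For a feature set (attributes X_A, or relational features
   X_R), build the Gaussian affinity a_ij = exp(−‖x_i − x_j‖² / 2σ²),
   keep each node's k strongest affinities (symmetrized k-NN graph), and
   column-normalize into a Markov transition matrix P.
2. **Restart walk.** With seed matrix Q, where column d is the uniform
   distribution over labeled members of class d (q_id = 1/l_d), iterate

       U ← (1 − α) P U + α Q,     0 < α < 1

   to its unique fixed point. Column d of U scores every node's relevance
   to class d; α (default 0.95) sets how strongly the walk is pulled back
   to the labeled seeds, and makes the iteration a contraction with ratio
   1 − α.
3. **Collective loop.** Bootstrap with the attribute channel (U_A), harden
   its scores into provisional labels, then repeat: aggregate relational
   features X_R[i, d] = #\{neighbors of i currently labeled d\}, solve the
   relational channel U_R on a kernel over X_R, and fuse the channels
   under conditional independence, p(Y|x, r) ∝ p(Y|x) p(Y|r) / p(Y)
   (with the walk scores acting as class-conditional likelihoods, this
   reduces to s_id ∝ U_A[i,d] · U_R[i,d] · p_d). Stop when the hardened
   labels stabilize or after n iterations.

Evaluation uses the four standard multi-label ranking criteria —
coverage, ranking loss, one-error and 1 − average precision, all
"smaller is better" — plus ROC AUC for binary tasks.

## Worked example

No external data is needed; the package generates homophilous multi-label
networks with controllable signal:

```sh
icam synth --m 300 --c 4 --homophily 0.08 --p-out 0.005 --attr-sep 3 \
           --labeled-frac 0.5 --seed 7 --out demo
# wrote 300 nodes / 1624 edges to demo (nodes.tsv, edges.tsv, ...)

icam run --edges demo/edges.tsv --nodes demo/nodes.tsv \
         --features demo/features.tsv --labels demo/labels_observed.tsv \
         --classes 4 --out demo/scores.tsv
# wrote scores for 300 nodes (150 unknown) to demo/scores.tsv; outer iterations: 10

icam eval --scores demo/scores.tsv --truth demo/labels_truth.tsv --classes 4
```

prints, for the 150 held-out nodes:

```json
{
  "coverage": 0.3333333333333333,
  "ranking_loss": 0.021666666666666667,
  "one_error": 0.02,
  "one_minus_avg_precision": 0.015740740740740722,
  "n": 150,
  "n_excluded": 0
}
```

Read: on average all true labels of a node sit within the top 1.33 ranks
(`coverage` 0.33 over a 0-based depth); 2.2% of (true, false) label pairs
are ordered wrongly; the top-ranked label is wrong for 2% of nodes. The
same run through the attribute channel alone (`--n-iter 0`) gives
coverage ≈ 0.74 and one-error ≈ 0.23 — the relational channel supplies
most of the accuracy once labels start propagating.

`icam baseline-ica` runs the one-vs-all kNN ICA baseline, and
`icam experiment` repeats seeded train/test splits over a method grid and
writes long-format and mean ± sd summary tables. The same functionality
is available in Python via `icam.fit_predict`, `icam.generate`,
`icam.evaluate` etc.

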
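# stitchgat

Joint assessment of suturing sub-skills with a masked graph-attention layer
over a prior sub-skill relationship graph.

## What this is for

Automated suturing skill assessment usually scores each technical sub-skill
in isolation. But the six sub-skills of a stitch — needle repositioning
(RP), needle hold ratio (HR), needle hold angle (HA), needle driving
smoothness (DS), wrist rotation (WR) and wrist rotation at needle
withdrawal (WRnw) — are correlated parts of one coordinated motion, and
some of them (hold angle in particular) are hard to judge from their own
sub-phase alone. `stitchgat` is for surgical-data-science researchers who
want to exploit those relationships: it fuses per-sub-skill clip features
with instrument kinematics and refines them through a graph-attention
layer whose edges encode the known sub-skill associations, producing all
six skill calls per stitch simultaneously.

## The model

Each sub-skill is a node of a fixed 6-node graph with undirected edges
HR–HA, HA–DS, HA–WR (plus self-loops). A node's input
`x_i ∈ R^1808` concatenates a 128-d clip feature from a per-sub-skill
sequence encoder (stage 1) with its flattened camera-relative kinematic
sequence (24 frames × 70 pose scalars). One masked graph-attention layer
updates each node from its graph neighbourhood:

```
h_i  = W x_i + b,                        e_ij = a᷆ᵀ LeakyReLU(A [h_i ‖ h_j] + c)
α_ij = exp(e_ij) / Σ_{k: A_ik=1} exp(e_ik)          (zero off the graph)
h'_i = ELU( Σ_{j: A_ij=1} α_ij h_j ),    logit_i = head_i(W_o h'_i)
```

and the loss is the sum of the six per-node cross-entropies. The learned
α ∈ [0,1] are interpretable association strengths; two ablations — weights
fixed to one instead of learned α, and kinematics zeroed — isolate the
contribution of attention and of kinematic fusion. Evaluation is
leave-one-institution-out: train on four medical centers, test on the
fifth, report per-sub-skill AUC mean ± std across folds. A downstream
module associates per-domain skill scores with 3-month continence recovery
via uni- and multivariable logistic regression.

Because the clinical VR dataset is restricted, the package ships a
synthetic cohort generator that plants the same statistical structure
(surgeons nested in institutions, graph-structured cross-sub-skill label
dependence, per-institution shifts, kinematic streams, an outcome table)
so every stage is testable and the joint-vs-independent contrast is
reproducible end to end. See `docs/methods.md` for the full model and
design rationale.

## Worked example

```python
from stitchgat.experiment import quickstart_config, run_experiment

report = run_experiment(quickstart_config(seed=1))
for arm in ("independent", "joint", "no_attention", "no_kinematics"):
    row = report["summary"][arm]["MEAN"]
    print(f"{arm:>14}: AUC {row['mean']:.3f} +/- {row['std']:.3f}")
print("HA attention row (held-out inst_A):",
      [round(v, 2) for v in report["attention"]["inst_A"][2]])
assoc = report["outcome_association"]
print(f"continence model AUC: {assoc['multivariable_auc']:.3f} "
      f"(n={assoc['n_cases']} cases)")
```

prints

```
   independent: AUC 0.782 +/- 0.009
         joint: AUC 0.649 +/- 0.023
  no_attention: AUC 0.625 +/- 0.034
 no_kinematics: AUC 0.754 +/- 0.025
HA attention row (held-out inst_A): [0.0, 0.24, 0.27, 0.24, 0.25, 0.0]
continence model AUC: 0.677 (n=200 cases)
```

The quickstart cohort is deliberately tiny (5 institutions × 5 surgeons ×
8 stitches) so the whole four-arm experiment runs in seconds; at this
scale the high-capacity joint model overfits and the logistic independent
baseline wins. The regime the method targets is the study-shaped cohort
(5 × 8 × 25 = 1000 stitches) with planted cross-sub-skill signal, where
the joint model's held-out hold-angle AUC exceeds the independent
baseline's by a wide margin (see the acceptance run below). The attention
row for HA shows mass only on itself and its three graph neighbours —
non-edges are exactly zero.

The same pipeline is scriptable from the shell:

```bash
stitchgat simulate --seed 3 --out data/            # synthetic cohort
stitchgat kinprep  --cohort data/ --out aligned.npz
stitchgat joint    --cohort data/ --features data/features.npz --out joint/
stitchgat evaluate --seed 3 --out report/          # four arms, LOIO CV
stitchgat associate --scores scores.csv --outcomes data/outcomes.csv --out tables/
stitchgat run-all  --seed 3 --out full/
```

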
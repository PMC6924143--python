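# odnscreen

Machine-learning screening of CpG oligodeoxynucleotide (ODN) TLR9
agonists. Synthetic single-stranded ODNs containing unmethylated CpG
motifs activate Toll-like receptor 9 and are of interest as vaccine
adjuvants and immunotherapeutics; finding good ones by synthesis and
cell-based assay alone is slow and expensive. `odnscreen` is a
ligand-based virtual-screening library for this problem, aimed at
computational chemists and immunology groups who have a panel of
activity-assayed ODNs and want to rank new candidate sequences.

## What it implements

* **Featurization** of 24-mer-scale DNA sequences: positional motif
  fingerprints (every (substring, start) token of length 2–6 whose
  occurrence rate differs by ≥ 10 percentage points between activity
  groups, encoded as presence bits), nucleotide counts, motif-distance
  descriptors d2_1 = p2 − p1 + n (with n the number of nucleotides before
  the latter occurrence; similarly d3_1, d3_2), and rigid-body features of
  a 2D graphical sequence embedding (center of mass μx, μy; principal
  moments of inertia I11 ≥ I22; radius of gyration Rg with
  Rg²·N = I11 + I22).
* **Leakage-safe feature pipeline**: near-zero-variance (SD < 0.3),
  linear-combination and pairwise-correlation (|r| > 0.85) filters plus
  centering/scaling, fit on training data only.
* **Imbalance-aware ensemble**: 20 repetitions of random down-sampling of
  the majority class, per-repetition 80/20 stratified splits and k-fold
  partitions, one 500-tree random forest per repetition with
  cross-validated mtry tuning, and a mean-probability consensus with
  ranked top-n candidate selection. Gradient boosting, shrinkage
  discriminant analysis, RBF-SVM and neural-network baselines share the
  protocol for benchmarking.
* **Evaluation**: sensitivity, specificity, balanced accuracy
  Ba = (Se + Sp)/2, Matthews correlation coefficient and precision, with
  undefined-denominator flagging and per-(family, k) aggregation.
* **Motif statistics**: position-free containment-rate differences between
  activity groups and two-sided Mann–Whitney U tests of each motif's
  effect on the activity score (exact null for small tie-free samples).
* **Synthetic data**: seeded uniform-random ODN libraries and a
  planted-motif-effect activity simulator providing ground truth for
  end-to-end validation.

See `docs/methods.md` for the model details and design rationale.

## Worked example

```python
from odnscreen import motif_positions, distance_descriptors

S1 = "TATGCGTTCGTACTTGATCTGAC"
S2 = "TGCTTTCTTGTCGTGCGGGCTGT"
for name, seq in (("S1", S1), ("S2", S2)):
    pos = motif_positions(seq, "CG")
    print(name, pos, pos[1] - pos[0], distance_descriptors(seq, "CG")[0])
```

prints

```
S1 [5, 9] 4 12
S2 [12, 16] 4 19
```

Both sequences carry their CG pair 4 nucleotides apart, yet their d_CG2_1
descriptors differ (12 vs 19) because the n term — the number of
nucleotides before the second occurrence — pins the pair to its absolute
position, which is what makes the descriptor discriminative.

A full train-and-screen run (`python examples/02_train_and_screen.py`,
demo-sized: 200 simulated ODNs, 5 ensemble members):

```
per-member held-out balanced accuracy:
 member  mtry  balanced_accuracy   mcc
      0     2              0.636 0.273
      1     9              0.818 0.683
      2     2              0.727 0.455
      3     2              0.636 0.277
      4    10              0.773 0.567
mean: 0.718 (each member is scored on its own held-out test split)

top 5 screened candidates (of 1000 random 24-mers):
 rank       id  score  votes
    1 ODN00387  0.936      5
```

Each member is a random forest trained on its own down-sampled balanced
split; `score` is the mean probability, across members, that a candidate
is a high-activity (≥ 0.4) TLR9 agonist, and `votes` counts members
agreeing. The other scripts in `examples/` demonstrate featurization,
motif statistics and the learner benchmark; a thin CLI (`odnscreen
simulate|featurize|train|benchmark|predict|motifstats`) wraps the same
functions for shell use.

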
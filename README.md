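# branchtrain

Inference of leader–follower interaction strength and range in confined
single-cell migration trains, from branch-selection statistics at
symmetric T-junctions.

## The problem

Cells migrating in single file through a one-cell-wide microchannel reach
a symmetric T-junction one after another.  Each follower either takes the
same branch as the cell ahead of it or the opposite one, so continuous
intercellular coupling is converted into a binary sequence of branch
choices per train.  `branchtrain` turns those sequences into a
quantitative estimate of the effective cell–cell interaction — its sign
(attraction vs repulsion), its magnitude, and how far behind the leader
it persists — without force measurements or molecular labelling.  It is
aimed at groups running confined-migration branching assays (endothelial
or epithelial trains, for example) and at anyone studying correlated
binary choice sequences with run-length statistics.

## The model

Branch choices are modelled as a two-state first-order Markov chain.
With baseline same-branch probability *p* (0.5 at an ideal symmetric
junction) and effective interaction α,

```
P_jj = p + α,            -p ≤ α ≤ 1 - p
P(n) = P_jj^(n-1) (1 - P_jj),      ⟨n⟩ = 1 / (1 - P_jj)
```

so run lengths (cluster sizes: maximal stretches of consecutive
same-branch choices) are geometric, and the interaction is estimated from
the observed mean cluster size:

```
P̂_jj = 1 - 1/⟨n⟩_obs = Σ(n_i - 1) / Σ n_i      (mean-based ≡ MLE)
α̂   = P̂_jj - p       = 1/2 - 1/⟨n⟩_obs  at p = 0.5
```

Uncertainty comes from a nonparametric bootstrap over clusters
(percentile CIs); deviation from the independence null α = 0 is tested
with a parametric-bootstrap likelihood-ratio test.  Grouping clusters by
*cluster order* (1 = the front-cell cluster, 2 = the next, …) resolves
the interaction along the train and hence its spatial range.

## Worked example

Nineteen front clusters, seventeen of size 1 and two of size 2 — a
strongly alternating (repulsive) endothelial-like group:

```python
from branchtrain import GeometricRunModel

model = GeometricRunModel.from_lengths([1]*17 + [2, 2], group="front")
res = model.fit(bootstrap=10_000, seed=42)
print(res.summary())
lrt = res.lrt(B=99_999, seed=42)
print(f"LRT: Lambda={lrt.lambda_obs:.3f}  p={lrt.p_value:.2e}  (B={lrt.B})")
```

prints

```
Geometric run-length model
============================================
Group                 front
Clusters (M)          19
Mean cluster size     1.105
P_jj (baseline p)     0.095 (0.5)
alpha                 -0.405
SE (bootstrap)        0.056
95% CI               [-0.500, -0.292]
Bootstrap B / seed    10000 / 42
============================================
LRT: Lambda=15.904  p=2.00e-04  (B=99999)
```

The mean cluster size 1.105 maps to α̂ = 1/2 − 1/1.105 = −0.405: a strong
repulsive leader–follower coupling.  The percentile CI saturates at
−0.500 because α̂ cannot go below −p, and the LRT rejects independence
decisively.  Analysing real data is the same pipeline starting from a
delimited branch table (`train_id, cell_order, branch` with `L/R` or
`Up/Down` tokens):

```python
from branchtrain import read_branch_table
trains = read_branch_table("trains.csv")
res = GeometricRunModel.from_sequences(trains, "rear_pooled").fit(seed=0)
```

or from the shell:

```
branchtrain simulate --trials 20 --n-cells 20 --alpha -0.2 --seed 1 --out sim.csv
branchtrain analyze sim.csv --group all --bootstrap 10000 --lrt-reps 9999 --out report.tsv
branchtrain null-enum --n-cells 4 --p 0.5
branchtrain fixtures --scenario mdck_like --seed 1 --out mdck.csv
```

`analyze` writes a report table (Dataset, M, Mean Cluster Size, alpha,
SE, 95% CI, optionally Λ and p-value) plus a full-precision JSON
companion recording B, seeds and censoring policy.

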
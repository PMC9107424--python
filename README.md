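# reggnn

Predicting scalar cognitive scores (full-scale or verbal IQ) from functional
brain connectomes with a graph-convolutional regression network (**RegGNN**),
trained on a small set of maximally predictive subjects chosen by a
**learning-based sample-selection** procedure built on the Log-Euclidean
geometry of the symmetric-positive-definite (SPD) matrix cone.

The package is aimed at network-neuroscience practitioners who have, per
subject, a d × d Pearson-correlation connectome (e.g. d = 116 regions of an
anatomical parcellation) and a real-valued cognitive score, and who want

* a topology-aware regressor instead of vectorized connectomes, and
* a principled way to train it on only the k most representative subjects.

## The model

A correlation matrix **C** is positive semi-definite; **P** := **C** + μ**I**
(μ = 10⁻¹⁰) places it on the SPD cone. RegGNN applies two graph convolutions
with symmetric normalization and self-loops — with **Ã** = **A** + **I** and
**D̃** its degree matrix,

    H⁽¹⁾ = ReLU(D̃^{-1/2} Ã D̃^{-1/2} H⁽⁰⁾ W⁽¹⁾),   H⁽⁰⁾ = I,

followed by dropout, a second convolution down to one channel, and a fully
connected readout of the d-dimensional embedding to the predicted score.
Negative correlations are zeroed before training. The absolute readout
weights rank brain regions by their influence on the prediction.

Sample selection works in the tangent space at the identity: under the
Log-Euclidean metric the tangent matrix of the geodesic between **P** and
**Q**, parallel-translated to **I**, is log **Q** − log **P**, and the
geodesic distance is its Frobenius norm. In a nested N-fold loop over the
training set, each pair of train-in connectomes is compressed to a feature
vector (full tangent upper triangle, degree/eigenvector/closeness centrality
of the tangent matrix, their concatenations, or plain distances), a linear
map f from pair features to |ΔIQ| is fitted, and for every holdout subject
the k train-in subjects with smallest predicted |ΔIQ| are counted in a
frequency map; the k subjects with the highest cumulative frequency are
selected and RegGNN trains only on them.

## Worked example

```sh
reggnn simulate --out cohort --n-subjects 60 --d 30 --n-clusters 3 \
    --within-cluster-sd 0.1 --score-sd 1.0 --seed 7
reggnn pipeline --matrix-dir cohort --scores cohort/scores.csv \
    --outer-folds 3 --k-min 2 --k-max 15 --n-folds 5 \
    --epochs 500 --learning-rate 0.01 --seed 11 --out results
```

prints (numbers from an actual run; the synthetic cohort has three score
clusters about 40 IQ points apart):

```
RegGNN evaluation summary
=========================
k sweep: 2..15
MAE  mean +- sd (min, max) over k: 5.292 +- 4.585 (1.066, 13.143)
RMSE mean +- sd (min, max) over k: 6.511 +- 5.477 (1.266, 16.835)
baseline (all training samples): MAE 1.168, RMSE 1.434
best k by mean MAE: 8
Welch t-test p (best-k errors vs baseline errors): 0.4883
```

Reading: at the best k the network trained on just 8 selected subjects
predicts held-out scores with a mean absolute error of about 1 IQ point —
on par with training on all 40 training subjects, and far below the
~27-point error of predicting the training-set mean. `results/` contains
the per-(k, fold) table, the per-k means, the baseline row, the ROI weight
ranking and this summary.

The same steps are available as library calls
(`reggnn.generate_cohort`, `reggnn.select_samples`, `reggnn.train`,
`reggnn.run_pipeline`); see `docs/methods.md` for the underlying choices.

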
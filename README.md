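# gradiomics

Explainable CNN–radiomics fusion for binary lesion classification in 2D
grayscale radiographs.

Clinicians reading periapical radiographs look for root-end disease:
subtle dark, texture-heterogeneous regions near the root apex. End-to-end
CNNs can classify such images but are opaque and, on modest clinical
archives, often transfer poorly. `gradiomics` implements a multimodal
alternative: the network's own attention (Grad-CAM) selects the pixels
that handcrafted radiomic descriptors are computed from, so the learned
and handcrafted features describe the same anatomy, and every prediction
ships with a pixel-level heatmap and feature-level Shapley attributions.

## Method

For an image $x$ and a convolutional backbone with last-conv feature maps
$A^k$ and class score $y^c$:

1. **Saliency.** Grad-CAM weights
   $\alpha_k = \frac{1}{Z}\sum_{i,j} \partial y^c / \partial A^k_{ij}$
   give the heatmap $L = \mathrm{ReLU}(\sum_k \alpha_k A^k)$, min–max
   normalized and thresholded at 0.5 into a binary mask $M$. A mask is
   *unreliable* if it covers < 1% of the image or activates > 30% of the
   1-pixel outer border.
2. **Masked radiomics.** 87 features — 18 first-order, 24 GLCM, 16 GLRLM,
   14 GLDM, 5 NGTDM, 10 Shape2D (IBSI-style definitions, fixed bin width,
   distance 1, four 2D directions) — are computed only inside $M$;
   unreliable masks yield a zero-padded vector.
3. **Fusion.** The penultimate embedding (optionally averaged over five
   deterministic test-time views: identity, flips, ±10° rotations) is
   concatenated with the radiomic vector; two backbones' fused vectors
   can be concatenated into an ensemble.
4. **Reduction + classification.** SelectKBest (ANOVA F, k = 100) or PCA
   (95% variance), then a random forest or XGBoost tuned by grid search
   under stratified 5-fold cross-validation.
5. **Validation + explanation.** Accuracy/precision/recall/specificity/
   F1/AUC; paired *t* and exact Wilcoxon signed-rank tests on fold
   scores, within-fold label-permutation testing, McNemar on hold-out
   predictions, Holm–Bonferroni for families of comparisons; exact
   tree-Shapley attributions (local accuracy to 1e-6) in the reduced
   feature space.

Because clinical radiograph archives are typically private, the package
includes a first-class synthetic generator: root-like images over
correlated trabecular-bone clutter, with lesions of graded severity
planted at the root apex (a mean-intensity drop plus extra texture
noise). Every stage is tested against brute-force oracles on this
synthetic data.

## Worked example

`examples/04_fusion_classification.py` trains the test backbone on its
own synthetic archive, extracts fused features for an independent
evaluation set, and cross-validates the fused representation against
each modality alone:

```
evaluation set: n=200, reliable masks: 98%

fused           accuracy 0.775 ± 0.061   AUC 0.843
embedding only  accuracy 0.615 ± 0.060   AUC 0.690
radiomics only  accuracy 0.735 ± 0.080   AUC 0.825
```

The fused vector beats both ablations: embeddings carry global context
the radiomics lack, and Grad-CAM-masked radiomics resolve local texture
the small CNN summarizes away. `examples/05_statistical_protocol.py`
shows the metric identities on a 457-root confusion matrix
(TP=227, FN=11, TN=217, FP=2):

```
sensitivity 95.4%   specificity 99.1%   accuracy 97.16%
missed lesions 4.6%   mislabeled healthy 0.9%
```

The other examples cover the generator, saliency QC, the radiomic
census, and Shapley explanations; each prints what it computes and what
the numbers mean.

## Command line

A thin CLI mirrors the pipeline stages over an artifact directory:

```bash
gradiomics run config.yaml            # end to end
gradiomics simulate config.yaml       # or stage by stage:
gradiomics split config.yaml
gradiomics train-backbone config.yaml
gradiomics saliency config.yaml
gradiomics fuse config.yaml
gradiomics classify config.yaml
gradiomics explain config.yaml
gradiomics report config.yaml
```

Stages compose: running them separately equals the one-shot `run`.
Exit codes: 0 success, 2 configuration error, 3 data error, 4 numeric
failure.

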
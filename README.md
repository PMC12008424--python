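# anchorreg

Anchor-point based non-rigid image registration for microscopy.

Microscopy images of the same structure rarely agree: optical frames are
taken from different camera poses, and scanning-probe images pick up slow
non-linear distortions from thermal drift and piezo creep during the scan.
`anchorreg` registers each image against a *predefined structural model* —
a list of anchor points `P_m` (lattice sites, corner holes, device
corners) in unit-length normalised coordinates — instead of registering
images against each other. That turns alignment into an absolute-scale
problem: every rectified frame lives in the model's coordinate system, so
frames taken on different days, scales or instruments become directly,
pixel-for-pixel comparable, and the model's internal geometry localises
sub-features (e.g. adatoms) the detector never saw.

It is aimed at microscopists and image-analysis developers working with
periodic or geometrically constrained structures: SPM/STEM lattices,
patterned devices under optical microscopy, any "known shape, unknown
distortion" scenario.

## Method

Registration is a two-stage chain:

1. **Rough matching.** Points `P_e` extracted from the image (sub-pixel
   dark-blob centres, or fitted device corners) are cleaned by a *vote
   filter*: each point scores +1 per neighbour within the candidate radius
   whose distance lies in the accepted band `[0.9 L, 1.1 L]` of the
   inter-structure distance `L`, −1 otherwise; negative scores are
   excluded. The model is then placed by an affine map
   `A = S(s_x,s_y) R(θ) Sh(a_x,a_y) T(x_0,y_0)` whose scale/rotation/shear
   come from prior knowledge and whose translation is found by brute-force
   search; placed points are paired to `P_e` by gated nearest neighbours.
2. **Fine matching.** From the pairs, the homography `H` with
   `P_e = H ⊗ A ⊗ P_m` is estimated by least median of squares (LMedS):
   random 4-pair subsets solved by the normalised direct linear transform,
   scored by the median squared reprojection error, robust to up to ~50 %
   wrong pairs, followed by an inlier least-squares refinement.

The registered image is reconstructed at absolute scale through
`P_t = A⁻¹ ⊗ H⁻¹ ⊗ P_e` (and the same composite warps whole images).
Accuracy is reported as MAE (mean Euclidean error in model units) and
Recall@OKS — the fraction of runs whose Object Keypoint Similarity
`mean_i exp(−d_i² / (2 s² κ²))` exceeds a threshold (default 0.95).

## Worked example

`examples/01_register_lattice.py` renders a 5×5 lattice at 40 px/unit
under a known mild homography (SNR 20), then registers it:

```
status: ok, pairs: 25/25
MAE  = 0.0014 model units  (reconstruction error vs the model)
OKS  = 1.0000             (1.0 = every site on target)
estimated homography (image <- placed model):
[[ 0.9734 -0.016   4.3421]
 [ 0.0088  0.9831  0.9294]
 [-0.      0.      1.    ]]
```

MAE is measured in lattice spacings: 0.0014 means every reconstructed well
sits within ~0.14 % of the spacing of its ideal position. Rectifying the
same image (`examples/02_rectify_distortion.py`) puts the wells back on the
ideal 40 px grid:

```
rectified image: 201x201 px at 40 px/unit
wells vs ideal grid: max 0.100 px, mean 0.057 px
```

The remaining examples cover the optical-microscopy workflow (square
device fit, registered difference map, line profiles), unit-cell encoding
on a Si(111)-(7×7)-style lattice — each half cell becomes a 6-bit
adatom/defect vector that identifies cells across frames regardless of
contrast — and the desk-scale Monte-Carlo noise sweep:

```
cell (1, 1): vector (1, 1, 0, 1, 1, 1)     # planted defect recovered
cross-frame match: translation (2, 0), 9 cells agree
```

A thin CLI wraps the same library calls:

```sh
anchorreg fixture --out fx.tif --model-out model.json
anchorreg register --image fx.tif --model model.json --config cfg.yaml --out res.json
anchorreg rectify  --image fx.tif --model model.json --pixels-per-unit 40 --out rect.tif
anchorreg sweep    --config sweep.yaml --out sweepdir/
```

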
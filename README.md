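# ssa2d — circular and shaped 2D singular spectrum analysis for gene-expression images

Quantitative atlases of early *Drosophila* development record, per nucleus,
3D position and the expression level of co-stained genes on the embryo
cortex. Analysing these data raises three recurring problems:

1. the measurements live on an ellipsoidal surface, so images are built on
   an *unrolled cylindrical projection* whose top and bottom rows are
   contiguous (periodic boundary);
2. multichannel imaging leaks signal between acquisition channels
   ("crosstalk"), and the automated unmixing step can over- or
   under-correct, stamping the periodic 7-stripe pair-rule reference
   pattern (*eve*/*ftz*) onto the gap-gene channel under study;
3. the pair-rule stripes themselves have dorsoventral structure (straight,
   C-, or S-shaped stripes) worth quantifying.

`ssa2d` addresses all three with **2D singular spectrum analysis (2D-SSA)**
— a model-free decomposition of an image into trend, regular oscillations,
and noise — extended with **circular** embedding (windows wrap across the
periodic axis of the cylindrical projection) and **shaped** embedding
(image support and window may be arbitrary pixel sets, for non-rectangular
expression domains). It is aimed at researchers working with per-nucleus
expression point clouds (BDTNP-style PointCloud records) or regular-grid
expression images.

## The method

Given an image $\mathbb{X}$ and a moving window (the main parameter), SSA
proceeds in four steps:

1. **Embedding.** Slide the window over the image; each admissible
   placement, vectorized in a fixed (row-major) element order, becomes one
   column of the trajectory matrix $\mathbf{X} = \mathcal{T}(\mathbb{X})$.
   For a 1D series with window length $L$ this is the classical
   $L \times K$ Hankel matrix, $K = N - L + 1$; for a rectangular 2D window
   it is Hankel-block-Hankel. On a circular axis placements may wrap; with
   a mask, a placement is admissible iff every window pixel is supported.
2. **Decomposition.** SVD:
   $\mathbf{X} = \sum_i \sigma_i U_i V_i^{\top}$, at most
   $\min(L, K)$ nonzero terms. Each *eigentriple* $(\sigma_i, U_i, V_i)$
   has an *eigenimage* ($U_i$ reshaped to window form) whose frequency
   content identifies what the component carries.
3. **Grouping.** Partition the component indices
   $\{1,\dots,d\} = \sqcup_j I_j$ into interpretable groups (trend,
   stripes, noise).
4. **Reconstruction.** Project each grouped matrix back to image space by
   averaging all trajectory-matrix cells that cover the same pixel
   (diagonal averaging, generalized per pixel for shaped/circular
   embeddings), giving $\mathbb{X} = \mathbb{X}_1 + \dots + \mathbb{X}_s$
   exactly.

Crosstalk direction is diagnosed from the *phase relation* between the
stripe reconstructions of the two channels: antiphase stripes mean the
unmixing subtracted too much of the reference (overcorrection), in-phase
stripes mean it subtracted too little (undercorrection). Stripe boundaries
are read off the sign change of the zero-mean stripe reconstruction, and
the central stripe's centerline is classified straight / C / reverse-C / S
from an orthogonal-polynomial fit.

## Worked example

The embedding of the $3\times 3$ image with values $1,\dots,9$ under a
$2\times 2$ window has four columns (windows `1245`, `2356`, `4578`,
`5689`); making the row axis circular adds the wrapped windows `7812` and
`8923`:

```python
>>> import numpy as np, ssa2d as s
>>> img = s.GridImage(np.arange(1, 10).reshape(3, 3), circular=(True, False))
>>> s.embed(img, s.WindowShape.rectangular(2, 2)).matrix.astype(int)
[[1 2 4 5 7 8]
 [2 3 5 6 8 9]
 [4 5 7 8 1 2]
 [5 6 8 9 2 3]]
```

End-to-end on a synthetic embryo whose gap channel carries an
*overcorrection* (crosstalk coefficient $\alpha = -0.2$, i.e. part of the
stripe pattern was subtracted):

```sh
$ ssa2d simulate --n-nuclei 1500 --crosstalk -0.2 --noise-eta 0 \
      --noise-floor 0.02 --seed 7 --out sim
wrote 1500 nuclei to sim/pointcloud.txt
$ ssa2d unmix sim/pointcloud.txt --channels gap,pairrule \
      --step 1.0 --angular-step 6.0 --window 8x20 --components 12 --out out
verdict: overcorrection (phase correlation -0.965)
```

The report lists each component's energy share and dominant eigenimage
frequency (cycles per image extent) with its label:

```
comp     share   f_row   f_col label
   1   0.93144    0.00    0.00 trend
   2   0.05346    0.00    2.85 unassigned
   3   0.00787    0.00    4.75 stripe
   4   0.00498    0.00    5.70 stripe
   5   0.00050    0.00    7.60 noise
```

Component 1 is the smooth gap-gene trend; components 3–4 are the leaked
stripe pair sitting near the 7-stripe frequency; their reconstruction is
antiphase with the reference channel's stripes (correlation −0.965, below
the −0.3 threshold), hence the overcorrection verdict. `out/` contains the
corrected image, the extracted stripes, and the residual noise, which sum
to the original exactly.

Presets for the standard analyses (`--preset hb-ftz`, `sna-eve-central`,
`sna-eve-lateral`, `eve-stripe4`) bundle the documented window sizes, grid
step, and clipping fractions.

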
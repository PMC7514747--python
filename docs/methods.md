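# Methods

## Model and assumptions

`dictfuse` treats fusion as patch-wise sparse coding.  Every vectorized
8×8 patch y ∈ ℝ⁶⁴ of a source image is approximated as y ≈ Dα with an
overcomplete dictionary D ∈ ℝ⁶⁴ˣ²⁵⁶ and a sparse coefficient vector α
found by orthogonal matching pursuit under the error constraint
‖y − Dα‖₂ ≤ ε.  The assumptions this rests on:

* the inputs are **pixel-aligned** single-channel images on a common grid
  (no registration is attempted; multi-channel input is only accepted via
  explicit luminance conversion);
* intensities live on **[0, 1]** — 8/16-bit files are rescaled on load —
  so the coding tolerance ε has a fixed physical meaning (a patch-level
  RMS intensity error of ε/8 ≈ 1.6% of full scale at ε = 0.1);
* the modalities are **complementary**: one is informative where the other
  is flat, which is what makes a per-patch winner-take-all rule sensible.

The dictionary is learned online from the pair being fused, in two halves:
a brightness block trained on patches that won the per-slot energy
competition and a detail block trained on patches that won the detail
competition.  Patch means are deliberately not removed at any stage: the
brightness block is supposed to carry DC energy, which mean removal would
destroy.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `patch_size` | 8 | patch side ρ (atom dimension ρ² = 64) |
| `overlap` | 6 | overlapping pixels; sliding step δ = ρ − overlap = 2 |
| `enhance_levels` | 4 | neighbour-distance detail layers P added to training images |
| `nd_window` | 3 | ND / smoothing window (odd) |
| `downsample_rates` | (3,4,5,6) | decimation rates of multi-scale sampling |
| `sne_window` | 11 | side of the Σx² brightness window |
| `msf_scales` | (7,11,15) | spatial-frequency neighbourhood sides r₁<r₂<r₃ |
| `msf_weights` | (0.33,0.67) | weights of the two between-scale difference terms |
| `atoms_per_subdict` | 128 | atoms per block (256 total, 4× overcomplete) |
| `ksvd_iterations` | 50 | coding/update alternations |
| `omp_tolerance` | 0.1 | residual ℓ2 stop, [0,1] intensity scale |
| `max_atoms` | 16 | hard OMP support cap (ρ²/4) |

All neighbourhood operators (ND, SNE, SF) use reflective/symmetric border
padding; with it the ND residual has exactly zero frame mean and the
feature maps agree elementwise with brute-force loops.

Decimation keeps every d-th pixel starting at the first (length ⌈N/d⌉, no
anti-alias prefilter — the goal is patch diversity, not signal fidelity);
the sliding window stops at the last full patch, giving
⌊(N − ρ)/δ⌋ + 1 patches per axis.  On 256×256 input this yields 15625
full-scale patches and 3721/1600/841/529 at rates 2–5.

## Numerical and design choices

**Spatial frequency uses absolute central differences.**  A signed sum of
(neighbour − centre) terms telescopes toward zero and can go negative,
which contradicts the statistic's purpose of measuring detail richness;
the implementation therefore sums |neighbour − centre| (squared
differences are selectable via `sf_mode`).

**Winner-take-all with exclusivity.**  The E and C competitions run per
grid slot across sources, never across scales (grid indices are only
comparable within one scale).  Ties go to the lowest source index.  When
one patch wins both contests it joins the set where its population
z-scored feature is larger and the other set takes the runner-up for that
slot (or omits the slot in the degenerate single-source case), so the two
training sets never share a patch.

**OMP.**  Greedy selection by maximal |residual correlation| with a full
least-squares re-fit over the selected set at each step, implemented on
the precomputed Gram matrix so residual norms come from
‖y‖² − cᵀDᵀy without forming residuals.  Pursuit stops at ‖r‖ ≤ ε, at
`max_atoms`, or on numerical stall (no remaining correlation above 1e-14).

**K-SVD.**  Standard alternation of batch OMP with sequential rank-1 SVD
updates of each (atom, coefficient-row) pair over the atom's support,
plus two stabilizers:

* a *monotone coding guard* — each column keeps its previous code when
  that code (still consistent with the updated dictionary) beats the fresh
  pursuit, making the Frobenius objective provably non-increasing outside
  replacement steps;
* *atom cleanup* — atoms used by fewer than `min_usage = 4` columns or
  duplicating another atom (|coherence| > 0.99) restart on the currently
  worst-represented training column.

Initial atoms are training columns drawn without replacement under the
seed; SVD sign is fixed by making each atom's largest-magnitude entry
positive, so a given seed reproduces the dictionary bitwise.

**Fusion rule.**  "Max-absolute choosing" is interpreted at the vector
level: per patch the whole code with the largest ℓ1 norm is selected
(ties → lowest source index).  This keeps every fused patch a genuine
sparse code of one source.  An elementwise max-|coefficient| blend is
available behind `fusion_rule="elementwise"` for comparison.  Enhancement
and multi-scale sampling are *training-branch only*; fusion codes the raw
images.  Overlapping reconstructions are averaged per pixel; pixels missed
when δ does not divide (dim − ρ) are filled from the nearest covered pixel
with a warning.  Output is clipped to [0, 1] only at the end.

**Metrics.**  MI uses 256-bin joint histograms of 8-bit-quantized
intensities, log base 2, zero cells skipped.  Q^AB/F uses Sobel gradients,
orientation atan(g_y/g_x) (π/2 where g_x = 0), strength ratio
min/max, and the sigmoid constants Γ_g = 0.9994, κ_g = 15, σ_g = 0.5,
Γ_α = 0.9879, κ_α = 22, σ_α = 0.8; these constants cap the measure at
≈ 0.975 even for a perfect transfer.  Two flat sources score 0 by
convention.

## Synthetic phantoms

`synthetic.make_pair` emulates the modality contrast the method targets:
source A carries smooth Gaussian brightness blobs (energy-dominant, like
CT/MR-T2 contrast) on a soft ramp, source B carries sinusoidal gratings
and sharp bars (detail-dominant, like MRI edges) on a dark background, and
the returned composite reference is the pixelwise max of the two
noise-free content layers.  Blobs are placed on a jittered 3×3 grid so
their coverage — and with it the brightness/detail balance — is stable
across seeds.  Both observations carry additive Gaussian noise
(σ = 0.03): each source is an imperfect, partial view of the composite,
and because OMP coding at ε = 0.1 absorbs most of that noise, a correct
fusion lands measurably closer to the reference (in mutual information)
than either source alone.  What the phantoms do *not* model: anatomy,
modality physics, intensity non-uniformity fields, or registration error —
passing tests show the pipeline's mechanics are right, not that it is
clinically validated.

## Problem sizes used in tests and the acceptance script

The shipped experiments run at desk scale: the end-to-end pipeline checks
use 96×96 (tests) and 128×128 (acceptance script) phantoms with the full
default configuration, and the planted-dictionary experiment uses a 64×128
ground-truth dictionary, 6000 three-sparse signals with coefficients drawn
uniformly from ±[0.5, 1.5] (bounded away from zero, as is standard in
dictionary-identifiability experiments), noise σ = 0.01, and OMP capped at
the known sparsity.  Under these conditions 50 K-SVD iterations recover
92–100% of planted atoms within 10° across seeds.

## Known limitations

* The per-patch winner-take-all rule cannot mix two sources inside one
  patch; content finer than the 8×8 patch that appears in both sources at
  the same location is resolved in favour of the higher-activity source.
* Online learning ties the dictionary to the input pair; a dictionary
  trained on one pair transfers to others only as far as their patch
  statistics agree (the CLI supports saving/reloading for exactly that
  experiment).
* MI estimated from 256-bin joint histograms is biased upward on small
  images; comparisons should be made at a fixed image size.
* Grayscale only: pseudo-color functional modalities (SPECT/PET) are
  fused on their luminance.
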
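# Methods

`nanokymo` models the analysis chain of nanofluidic scattering microscopy
(NSM): single biomolecules diffusing inside a sub-wavelength nanochannel are
imaged in dark field, the interference between channel- and molecule-scattered
light produces a contrast dip that traces the molecule's trajectory in a
kymograph (time x channel position), and a learned estimator converts the
kymograph into molecular weight (MW), hydrodynamic radius (Rs) and the number
of usable trajectory points (N).

## Optical contrast model

The total scattered intensity from a channel segment containing a molecule is
approximately I_t = I_c + I_m − sqrt(2 I_c I_m), so the differential signal
after subtracting the empty channel is I_m − sqrt(2 I_c I_m). Because the
molecule's self-scattering I_m scales with volume squared, the cross term
dominates by orders of magnitude for sub-10-kDa analytes
(`simulate.differential_contrast` exposes this algebra and the tests verify
the dominance across I_m/I_c from 1e−8 to 1e−2).

The simulator renders a molecule as a point scatterer: per frame, a Gaussian
contrast dip of width `s` (nm) centred on the molecule position, scaled so the
dip integrates to the integrated optical contrast iOC (contrast x nm). The
relative response field is Ir = 1 − iOC·g(x − x_i; s) with g a unit-integral
Gaussian evaluated at pixel centres; multiple molecules multiply their
response fields, and the raw stack is the product I = I0 · Ir with the
empty-channel background I0. iOC is inversely proportional to the channel
cross-section area A, which is why small channels extend the detection limit.

## Trajectories

Positions follow x_i = x_{i−1} + v·dt + N(0,1)·sqrt(2 D dt), with D in um²/s
(converted internally to nm²/s), drift v in um/s, and dt defaulting to 5 ms
(200 fps recording). Positions are deliberately not reflected or clipped: the
physical channel (~80 um) is far longer than the imaged segment (~14 um at
512 x 27.4 nm pixels), so molecules simply wander out of view; only in-view
frames count toward N.

## Background noise model

Per frame t the empty-channel field is

    b0 = exp(−(x − (x0 + x_lam))²/lambda²) · (1 + dirt) · (1 + A·N(0,1))
    bf = b0 · (1 + N_theta·N(0,1)) + 0.4·N_theta·N(0,1)

with x_lam = (2·N(0,1) + sin((pi − 0.05)·t))·d_x the per-frame channel
vibration, `dirt` the convolution of a white-noise field with a unit-sum
Gaussian kernel of width C, and fresh per-pixel normal draws in the final two
terms. Two choices here are the package's own:

* **The dirt kernel rides the vibration.** The kernel is
  exp(−(x − x_lam)²/C²), normalized to unit sum. An additive scalar offset
  inside the kernel before normalization is degenerate (the normalizing sum
  can cross zero, exploding the field by orders of magnitude), whereas a
  vibration-shifted point-spread pattern is bounded and physically coherent —
  dirt stuck to the channel moves with it.
* **Dirt is static per kymograph.** The white-noise dirt field is drawn once
  per kymograph and only the kernel varies per frame; channel contamination
  does not redraw itself between frames.

Default sampling ranges (NoiseParams.sampling_ranges) are calibrated so that
in the default 63 x 30 nm² channel a 100-kDa-equivalent contrast has per-frame
SNR ≈ 2–5 while a 5-kDa-equivalent contrast is below the noise floor:
N_theta ~ U(5e−4, 2e−3), vibration amplitude d_x ~ U(0.5, 2) nm, per-frame
scalar shot scale A ~ U(0, 1e−3), dirt width C ~ U(100, 1000) nm, envelope
width lambda ~ U(6, 14) um. The vibration amplitude matters: because the
term enters through the envelope gradient, amplitudes of tens of nm would
swamp every sub-100-kDa signal with white-in-time fluctuations that no
temporal filter can remove.

## Preprocessing

Raw stacks are collapsed over the transverse axis (mean), normalized per
position against the full-stack time average, Ibar = (I − <I>_t)/<I>_t, and
high-passed by subtracting a separable moving average (200 frames along time,
then 200 pixels along position; edge windows are truncated and renormalized so
the filter keeps unit sum everywhere). Applying the time window first is a
documented convention; the operation order has only a second-order effect.

## The hierarchical vision transformer

The network ingests a standardized kymograph and the channel cross-section
area and produces, on a grid downsampled by 2^n_scales in both axes
(512-pixel-long kymographs at the full 7 scales give 512/2^7 = 4 columns):

* a **probability map** — per-bin sigmoid likelihood that a molecule crosses
  that space-time cell, trained with binary cross-entropy against a
  ground-truth occupancy raster;
* a **property map** — per-bin (MW, Rs, N) predictions through softplus heads
  scaled by configurable output ranges, trained with L1 loss on occupied bins;
* **per-scale scalar predictions** from globally pooled convolutional
  features at every scale, also L1-supervised.

Architecture: an initial kernel-7 convolution (leaky ReLU), then per scale a
kernel-3 convolution and 2x2 max pooling; the coarsest feature map is patch
encoded (linear projection + learned positional embedding), conditioned on
log10(area) through a learned embedding added to every token, and refined by
pre-norm transformer blocks (multi-head attention + MLP). Per-scale
probability logits are resized to the common coarsest grid by average pooling
and fused with the transformer head through a final convolution. (The
full-input-resolution fusion variant is expressible but carries the same
information at much higher desk-scale cost.)

The final scalar estimate of each property is the probability-weighted mean of
its property map, sum(P·theta)/sum(P); the total mass P_total = sum(P) is the
detection statistic used downstream. A map with zero mass yields an estimate
flagged undefined rather than NaN.

Input standardization subtracts the per-pixel temporal mean and divides by the
kymograph's mean temporal standard deviation. The L1 property heads emit
softplus outputs multiplied by per-property scales (`ArchConfig.prop_scales`,
default 30 kDa / 3 nm / 10^4 points) so every regression target is O(1) for
the optimizer.

Training uses ADAM (default learning rate 1e−4, the full-scale recipe) on
kymographs simulated fresh every step; a configurable fraction (default 25%)
contains no molecule, teaching the probability head to stay low on pure
noise. Curriculum stages widen the sampled (MW, Rs) ranges whenever the
training loss plateaus (< 1% relative improvement of the trailing window
mean over the preceding window, patience configurable); validation runs
against a held-out simulated set (default 150 kymographs) at a fixed cadence
and the best-validation parameters are checkpointed. A NaN loss aborts with a
diagnostic rather than silently continuing.

The network is built on a small reverse-mode automatic-differentiation engine
over numpy arrays (`nanokymo.nn`): broadcasting arithmetic, batched matrix
products, reductions, sliding-window patch extraction for convolutions, and
stable sigmoid/softplus primitives. Gradient correctness is pinned by central
finite-difference tests at the op, layer and whole-model level.

## Post-processing

Per-kymograph estimates are filtered in two steps. First, probability-sum
thresholding: P_thresh = ½·<P_control> from buffer-only control recordings;
kymographs with P_total < P_thresh are excluded. Second, Gaussian outlier
pruning: a single moment fit (sample mean, n−1 standard deviation) per
property, removing points with |v − mu| > 3 sigma. The fit is not repeated
after removal, points exactly on the boundary are kept, and MW and Rs are
pruned independently with a kymograph dropped from the joint population if
either dimension flags it.

## Physical conversions

* **Optical mass**: MW = kappa · iOC · A / a with a = 0.46 Å³/Da
  (0.46 nm³/kDa) converting mass to polarizability volume and kappa a
  dimensionless optical calibration (default 0.01, chosen so the default
  geometry meets the SNR design point above). A single constant serves all
  analytes; the <10% dn/dc difference of dsDNA against proteins is not
  corrected, matching the single-constant convention.
* **Size**: Stokes–Einstein D = H(Rs)·k_B·T/(6·pi·eta·Rs), default water at
  298.15 K (eta = 0.89 mPa·s). The hindrance factor H accounts for wall drag
  in narrow channels: identity by default, with a Renkin-style centerline
  model for a pore of effective radius sqrt(A/pi) and a monotone lookup-table
  mode for channel-specific calibrations. Inversion D → Rs uses bracketed
  root finding on [0.1, 100] nm (closed form when H = 1).
* **dsDNA ladder**: 0.34 nm and 660 g/mol per base pair, giving the nominal
  17/34/68 nm and 33/66/132 kDa reference values for 50/100/200 bp fragments.

## Cramer–Rao bounds

For n Gaussian increments the Fisher information in D is n/(2D²), so the
relative precision of any unbiased diffusivity estimator obeys
sigma_rel ≥ sqrt(2/n), independent of D; the increment maximum-likelihood
estimator D_hat = sum((dx − v·dt)²)/(2 n dt) attains it. For the contrast
amplitude of a known per-frame template in additive white Gaussian noise,
sigma_rel ≥ 1/(snr_eff·sqrt(n)) with snr_eff = a·||h||/sigma, attained by the
matched filter. `precision_vs_n` produces empirical sigma-rel curves
(standard deviation across replicate estimates about the mean) next to these
bounds; both fall as 1/sqrt(N), which is why trajectory length is the
currency of precision in this technique. The white-per-pixel noise model
behind the amplitude bound takes snr_eff as an explicit input rather than
deriving it from the full background model.

## Desk-scale benchmark sizes

The benchmark experiments (`nanokymo.benchmarks`, driven by
`scripts/acceptance.py` and the acceptance tests) use problem sizes chosen
for a single CPU: increment statistics at k = 1e5 frames; diffusivity-bound
attainment at N ∈ {100, 1000, 10000} with 500 replicates; matched-filter
attainment at N = 1e4 with 500 replicates; and a scaled-down learning run —
3 scales, 32-dim embedding, 2 transformer blocks, 64 x 128 kymographs in a
50 x 50 nm² channel, 200 ADAM steps of batch 8 at learning rate 2e−3 on a
discrete MW grid {5, 15, 30} kDa at high SNR (fixed N_theta = 1e−4, vibration
and frame-scalar noise off, diffusivity drawn from 2–10 um²/s so molecules
stay in view of a 64-frame window). The full-scale configuration (7 scales,
512 x 8192 inputs, ~640k training kymographs, MW 0–30 kDa and Rs 0.7–3 nm)
remains expressible through the same configs.

## What the synthetic data does and does not capture

The generator reproduces the signal structure that drives the method —
diffusive point-scatterer trails, multiplicative structured background, shot
noise, channel vibration and static dirt — and is faithful enough to study
estimator precision against information-theoretic bounds. It does not model
transverse optics (the channel is 1-D by construction), photophysics beyond
the Gaussian response, analyte flow or polydispersity, surface adsorption, or
instrument drifts outside the stated noise families. Tests passing on this
generator therefore demonstrate correctness of the pipeline and achievability
of the bounds under the stated noise model, not performance on any particular
instrument; real deployments would superimpose simulated trajectories on
measured empty-channel recordings (`embed_in_measured_background`) and
recalibrate kappa and the hindrance table per channel.

## Numerical choices and degenerate inputs

L1 terms use sqrt(err² + 1e−12) for differentiability at zero; BCE uses the
softplus(z) − z·y form for stability; sigmoid/softplus clip exponents at
±500. Max pooling splits gradients equally across ties. Normalization rejects
non-positive per-position time means; a zero-variance kymograph standardizes
to zeros; probability-weighted readouts with zero total mass return an
undefined-flagged estimate. Seeds thread through every stochastic stage
(trajectories, noise draws, crops, initialization, batch sampling), making
training runs and fixture files bit-reproducible.

## Known limitations

* Desk-scale training runs demonstrate rank-order recovery and
  detection, not the few-percent accuracy plateaus of the full-scale
  configuration; reaching those requires orders of magnitude more training
  than a test suite should spend.
* The estimator is biased toward small property values on noise-like input
  (a qualitative property shared with the full-scale model); precision
  curves of the learned estimator below the bound at small N reflect that
  bias, not super-efficiency.
* The iOC → MW mapping isolates all optical calibration in kappa; absolute
  MW accuracy on real data depends entirely on calibrating kappa (and the
  hindrance table) for the channel at hand.
* The CRLB amplitude bound assumes white per-pixel noise; structured
  background residuals make it optimistic for real recordings.
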
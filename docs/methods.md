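# Methods

This note records the statistical models behind `sedseq`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical choices that affect results.

## The pSup model

For transcript *i* in one fractionation experiment, let T, S, P be the
counts observed in the Total, Supernatant and Pellet libraries.
Conservation of mass holds in the lysate (`T_i = S_i + P_i` in molecule
units) but not in count space, because each fraction is processed and
sequenced separately. Per-experiment mixing ratios α_S, α_P restore it:

    E[T_i] = α_S·S*_i + α_P·P*_i,

where the asterisk denotes the noiseless fraction abundance. Counts are
modeled as negative binomial with a single shared dispersion φ
(`Var = m + m²/φ`), with priors α_S, α_P ~ Gamma(1,1) and a
half-Cauchy(0,3) prior on the scale σ = 1/√φ. Only transcripts with
more than `min_counts = 20` in **all three** fractions enter the fit (a
conservative reading of a count floor; configurable). Given fitted
ratios, `pSup_i = α_S·S_i / (α_S·S_i + α_P·P_i)`.

### Latent-abundance vs fixed-covariate likelihood

The simplest likelihood conditions on the observed S, P as fixed
covariates: `T_i ~ NB(α_S·S_i + α_P·P_i, φ)`. Because S and P are
themselves noisy, this is an errors-in-variables regression: on
synthetic data at reference conditions (5000 transcripts, depth 10⁷,
φ = 100) it biases the ratio α_S/α_P downward/upward by ~10–13%, and
even the identity case α_S = α_P = 1 recovers a ratio of ≈ 0.88.

The default (`covariate_model="latent"`) therefore treats every count —
T, S and P — as NB-distributed around latent per-transcript fraction
means, which matches the view that each count *measurement* is noisy
while the underlying abundances obey conservation. The two latent means
per transcript are profiled out (a damped 2-D Newton iteration,
vectorized over transcripts), leaving a three-parameter profile
posterior over (α_S, α_P, σ). This removes the ratio bias (median
error ~2% at reference conditions). Profiling two nuisance parameters
per three observations underestimates residual dispersion by a factor
of ≈ 3 (a Neyman–Scott effect: one residual degree of freedom per
transcript out of three observations), so the reported φ is corrected
by that factor; empirically the corrected φ lands within ~20% of the
generating value. The α estimates are unaffected by the correction.
The fixed-covariate likelihood remains available via
`covariate_model="fixed"`.

### Backends

MAP (default) maximizes the log posterior in log-parameters by
Nelder–Mead from two starts (a moment-matched ratio and the identity);
it is deterministic. MCMC samples the same posterior with the emcee
affine-invariant ensemble sampler (8 walkers × 500 draws by default,
first third discarded) and reports the posterior mean; acceptance
fraction and posterior SDs are returned as diagnostics. On
well-conditioned data the two agree to well under 2%.

## Condensation scores

All scores use the natural-log odds `lopSup = ln(pSup/(1−pSup))`,
clamping pSup to [ε, 1−ε] with ε = 10⁻⁴ first so boundary estimates
stay finite. Length control:

- **Windowed trend.** For each transcript, μ_L and σ_L are the mean and
  sample SD (ddof = 1) of lopSup over all transcripts whose log-length
  falls within a window of width 0.02 × (range of log lengths) centered
  on that transcript's log-length (the transcript itself included;
  windows are sliding, not tiled). Windows with fewer than 3 members are
  widened to the nearest 3 neighbors.
- **σ_control** is the SD over all transcripts of the control residual
  `lopSup − μ_L`.
- **ΔSed** = (lopSup_control − lopSup_treated)/σ_control; positive =
  condensation. Identically 0 for control vs itself.
- **eSed** = [(lopSup_T − μ_{L,T}) − (lopSup_c − μ_{L,c})]/σ_control;
  positive = escape relative to same-length transcripts. The denominator
  is the *global* σ_control, not the windowed σ_L (which is still
  reported).
- **rSed / sedScore** (one statistic, two names): per replicate,
  transcripts sorted by length (UTRs included), split into consecutive
  bins of 100 (a final partial bin is merged into its predecessor),
  z-scored within bins; replicate z-scores are averaged. With one
  replicate available, eSed is computed from the replicate-averaged
  pSup rather than averaging per-replicate eSed; both orders are
  algebraically close because the transform is affine per window.

Degenerate guards: a bin or random sample whose SD is zero (or is pure
floating-point residue of a constant vector, ~10⁻¹⁶) yields z = 0.

## The sedimentation model

Baseline: `pSup(L) = 1 − βL^χ` — an mRNP pellets in proportion to a
power of its mass, proxied by length. Stress: the pelleted fraction is
multiplied by `exp(μ + νL)` with a per-molecule term μ (e.g. per-end
interactions) and per-nucleotide term ν; μ = ν = 0 in the control. The
sign convention is that positive μ, ν increase pelleting; a flag
(`exponent_sign`) preserves the opposite reading. Fits minimize squared
residuals of predicted vs observed log-odds pSup (treating log-odds
sedimentation as approximately normal), using Levenberg–Marquardt from
a multi-start grid (β log-spaced over 10⁻⁶…10⁻², χ ∈ {0.5, 1}); β is
parameterized as log β. By default (β, χ, μ, ν) are fitted jointly on
control + treated data; `share_baseline=False` freezes (β, χ) at the
control-only fit. Reduced variants (μ-only, ν-only) support
extra-sum-of-squares F-tests:

    F = [(RSS_r − RSS_f)/(p_f − p_r)] / [RSS_f/(n − p_f)].

Numerical choices: predicted pelleted fractions are clipped to
< 1 − 10⁻⁹ (clipping is recorded in diagnostics); optimizer tolerances
are 10⁻¹² with ≤ 1500 function evaluations per start; μ and ν are
unconstrained in the fit so that null sampling distributions are not
boundary-distorted. A `warm_start` option lets a nested fit seed the
full fit, guaranteeing RSS_f ≤ RSS_r; a full fit that still ends with
RSS_f > RSS_r is reported as F = 0, p = 1 with a warning (an optimizer
failure, not evidence).

Calibration of the F-test was verified by simulation (1000 null
replicates at 100 length points, noise SD 0.2): rejection at nominal 5%
within binomial error and uniform p-values. The calibration study keeps
the generating parameters away from pellet saturation (βL^χ e^μ < 1 at
all simulated lengths): at the saturation boundary the clamped model is
non-smooth and the F approximation visibly degrades (~7% empirical
size in our checks). Effective-size ratios use
`k = [(1−pSup_t)/(1−pSup_c)]^{1/χ}`; mass arithmetic uses 3.3 MDa per
ribosome, 0.30 kDa per nucleotide (chosen to make 1.8 kb ≈ 0.54 MDa),
and 65 kDa per RNA-binding protein.

### Known bias when fitting count-estimated pSup

logit is concave below ½, so noisy pSup estimates of strongly pelleted
transcripts have log-odds biased downward; fitting the stress model to
count-estimated lopSup therefore overestimates μ somewhat (≈ 0.95 for a
generating μ = 0.8 in the README example), while fits to noiseless
log-odds recover μ exactly. Averaging (windowed means, replicates)
reduces but does not remove this; conclusions that depend on the exact
magnitude of μ should use deep libraries or model the sampling noise.

## Translation metrics

Spike-in normalization divides every TPM in a fraction by that
fraction's median spike-in TPM (spikes filtered to > 100 estimated
counts), mimicking the addition of a fixed amount of foreign-species
RNA to each pooled fraction; occupancy = bound/(bound+free) on the
normalized scale, association = bound/total. Association changes
between conditions are plain log2 ratios with a 0.5 pseudocount (a
documented choice; shrinkage-based differential pipelines are out of
scope). Sucrose-cushion occupancy corrects for EDTA-resistant pelleting
(condensate) conditionally: occ = (plus − edta)/(1 − edta), clamped to
[0, 1], mapping "all pelleting survives EDTA" to 0; a plain-subtraction
mode exists. The qPCR route computes fraction abundances relative to
spike Cq (`2^(Cq_spike − Cq_target)`), with the pellet rescaled by
spike_amount_ratio / pellet_concentration_factor — the assay's 10× spike
into a 10× concentrated pellet cancels to 1. The 5′ UTR structure score
is ΔG divided by UTR length, with a 50 nt default (median yeast 5′ UTR)
when no UTR is annotated.

## Colocalization

Per cell: marker intensity is averaged over 3×3 pixel boxes at each RNA
spot centroid and at 100 positions drawn uniformly (with replacement)
from the cell-mask pixels; the score is
`z = (mean_spots − mean_random)/SD_random`. Scoring per cell makes the
statistic exactly invariant to affine transforms of the marker channel
and robust to cell-to-cell background differences. Boxes may cross the
cell boundary (the full image neighborhood is used); boxes at the image
edge are clipped. Random sampling covers the whole mask, including any
nuclear region. The population score is the mean over cells with ≥ 1
spot; conditions are compared by pairwise Welch t-tests with Holm
adjustment. Images are treated as single 2-D planes; z-stacks are
max-projected on load.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the estimators
assume: log-normal transcript lengths clipped to 200–15000 nt (the span
from short transcripts to beyond the 12.4 kb dynein mRNA); log-normal
abundances on a TPM scale; true pSup from the physical model with
transcript-level scatter applied on the log-odds scale (default SD
0.35, chosen so the control residual spread is of order 1 in log-odds
units — the scale on which ΔSed/eSed are meaningful); NB counts with
one shared dispersion (default φ = 100); per-fraction lognormal scale
distortions (SD 0.3) with spike-ins at ~1% of the library; FISH fields
with disk-shaped cells on a grid, uniform per-cell background, Gaussian
granules and spots placed in granules with probability e/(1+e) at
enrichment e.

Not emulated: read- and UMI-level artifacts, alignment or
quantification error structure, per-fraction dispersion differences,
correlated noise across fractions, transcript-specific condensation
beyond the regulon effects, 3-D optics and spot-detection errors, or
irregular cell shapes. Passing recovery tests on this data therefore
shows the estimators are correct under their stated assumptions, not
that real libraries satisfy those assumptions.

## Reference study sizes

Self-validation (and the acceptance report) uses: 1000 null replicates
and 200 power replicates at 100 length points for F-test calibration;
20 seeds at 5000 transcripts / 10⁷ depth / φ = 100 / α_S:α_P = 4:1 for
pSup inference; a 3000-transcript two-condition run for score
directionality; 50-cell fields for colocalization; 2000 transcripts
with 20 spikes at 10⁶ depth for translation metrics. These sizes give
Monte-Carlo error comfortably below the decision thresholds while
keeping a full run to a few minutes on one CPU.

## Known limitations

- Mixing ratios are identifiable only up to the Total library's depth
  scale; only pSup and the ratio α_S/α_P are scientifically meaningful.
- The profile-likelihood dispersion correction is a first-order
  degrees-of-freedom argument, not exact; φ is a nuisance here.
- The stress-model μ is biased upward when fitted to boundary-noisy
  count-estimated pSup (see above).
- The F-test is the standard nonlinear-regression approximation; its
  calibration was verified away from pellet saturation only.
- qPCR pSup assumes perfect doubling efficiency by default.
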
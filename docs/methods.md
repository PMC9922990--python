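# Methods

This note records the models, defaults and numerical choices behind
`hydrospec`, and what the synthetic-data experiments do and do not show.

## Spectral channels and conversions

All spectra live on a shared uniform frequency grid, by default 0.5 to
1.5 THz at the instrument sampling interval of 0.0038 THz (264 points).
Transmittance is the sample/background power ratio; absorbance is its
decadic negative logarithm. Fresh leaves can return more power than the
empty-beam background at some frequencies (detector drift, standing
waves), which would produce T > 1 and negative absorbance; such values
are clipped to T = 1 with a logged warning rather than rejected, keeping
A ≥ 0 and the pipeline total on real instrument exports. Band lists are
matched to grids by nearest neighbour within half a grid step; sample
matrices are row-major (sample × frequency) everywhere.

The three channels are treated as independently supplied measurements:
no cross-channel consistency (e.g. power = reference × T) is enforced on
input data, because measured channels routinely violate it.

## Synthetic study generator

The generator emulates a four-level irrigation-stress experiment:
irrigation at 20/40/60/80 % of a standard dose, 20 leaves per level
(80 samples), each leaf scanned 10 times and the scans averaged.

* **Moisture.** Dry-basis moisture per leaf is Normal(level mean, 15 %)
  truncated at 0, with level means 120/180/240/300 %. No measured
  summary statistics exist for this design, so the means are chosen to
  give clearly separated but overlapping levels spanning the range
  typical of fresh dicot leaves (dry-basis moisture of well-watered
  leaves commonly sits around 300–400 %). Dry mass is Uniform(0.5, 2) g
  and fresh mass is back-computed so the gravimetric formula inverts
  exactly.
* **Absorbance.** Noiseless core `A*(f) = a0(f) + β(f)·w` with affine
  `a0(f) = 0.1 + 0.2 f` and `β(f) = 0.002 + 0.004 f` per moisture
  percent: absorbance increases with frequency and with moisture, and
  the per-frequency values fall in the 0.5–3 range seen in leaf
  transmission work. Each scan adds i.i.d. Gaussian noise
  (sd 0.02 absorbance units) before averaging.
* **Leaf-level nuisance.** Each leaf draws a random absorbance baseline
  offset and tilt (`u + v·f`, u, v ~ N(0, 0.12)) and the power channel a
  random gain error (sd 0.15). These terms emulate leaf thickness and
  scattering variability plus detector gain drift: they carry no
  moisture information, survive scan averaging, and — because they lie
  in the same affine-in-frequency space as the moisture term — cannot be
  regressed away within a single channel. They are what caps
  single-channel accuracy (prediction correlations around 0.85–0.95)
  and, because the absorbance and power nuisances are independent, what
  makes fusing channels genuinely better, reproducing the qualitative
  outcome such studies report. With the nuisance sds set to zero the
  generator is noiseless-core exact, which the monotonicity and
  variance tests exploit.
* **Transmittance** is `10^(−A)` of the averaged absorbance, so it
  inherits the absorbance channel's noise and nuisance.
* **Power** is an affine gain on a smooth positive background reference,
  `P(f) = ref(f)·(1 + 0.5·w/100 + nuisance + scan noise)`: power
  increases with moisture and sits above the background, matching the
  (physically surprising) behaviour measured transmission setups show on
  fresh leaves. A `physical_power` switch derives power as
  `reference × T` instead for users wanting self-consistent channels.
* **Planted-band mode** zeroes the smooth β(f) and the structured
  nuisance and plants the whole moisture signal at six fixed grid
  frequencies; every other column is exchangeable i.i.d. noise. This is
  the exact ground truth used to score band selection.

All randomness flows from one explicitly passed generator; a dataset is
bit-reproducible from its seed.

What the generator does **not** model: refractive-index dispersion,
etalon fringes, atmospheric water-vapour lines (the emulated protocol
dehumidifies the chamber), chemical absorbers other than water, or
spatial heterogeneity within a leaf. Passing tests therefore demonstrate
that the chain recovers the statistical structure it assumes — monotone
water dependence plus channel-specific nuisance — not that it handles
every artefact of real instruments.

## Smoothing

Savitzky–Golay with window widths 5/7/9/11 points (default 5) and
quadratic local fits; the polynomial order is a standard chemometrics
default, exposed in `SgConfig`. Edges are handled by evaluating the
boundary window's polynomial at the off-centre positions
(`mode="interp"`), so the output keeps full length and the 0.5/1.5 THz
band edges — which selection frequently picks — are not discarded.
Smoothing is applied across frequency within each spectrum, the standard
reading for spectra (as opposed to smoothing across replicate scans,
which the averaging step already addresses). The window-selection
harness refits a downstream calibration model per candidate width and
keeps the width with the highest Rc; candidates within 1e−9 of the best
Rc are treated as tied and the smallest tied window wins, so noiseless
data deterministically selects width 5. Because the downstream model is
fit on all 264 bands of 60 calibration samples, where ordinary least
squares is singular, the default downstream fit is partial least squares
with up to 10 latent variables (injectable via the `downstream`
callable).

## Sample partitioning

Kennard–Stone seeds with the sample pair at maximal Euclidean distance
and then repeatedly adds the sample whose minimum distance to the
selected set is maximal. SPXY runs the same recursion on
`d = d_x/max d_x + d_y/max d_y`; if exactly one of the maxima is zero
its term is dropped, and all-identical samples are rejected. All argmax
ties break toward the lowest sample index, so both algorithms are
deterministic without a seed and permutation-equivariant whenever
pairwise distances are distinct. The calibration fraction is 0.75
(round-half-up), giving the 60/20 partition at n = 80. Distances are
computed on the smoothed spectra of the channel being modelled; the
fusion stage computes its own SPXY split on the concatenated selected
features, since a single shared split is not identifiable from the
study designs this mirrors.

SPXY's response term makes wide response coverage very likely but does
not guarantee that the calibration set contains the exact extremes when
predictor distances dominate the joint metric; the suite asserts the
statistical form (SPXY's calibration response range dominates KS's in
≥ 90 % of random problems) and the exact guarantee only in the
degenerate-predictor case.

## SCARS band selection

Per sampling run `i` of N = 50:

1. **Stability.** Thirty Monte-Carlo subsamples of 80 % of the
   calibration rows; the inner regressor is PLS with
   `min(10, n−1, rank)` latent variables (at the early runs the retained
   variable count exceeds the sample count, so OLS is unusable; capping
   at the design rank is essential because NIPALS deflation degenerates
   on exactly collinear columns). Stability is
   `|mean(β_j)| / (sd(β_j) + 1e−12)`.
2. **Forced selection.** Keep the top `⌈r_i·p⌉` variables by stability,
   where `r_i = a·e^(−k·i)` is calibrated through `r_1 = 1` and
   `r_N = 2/p`.
3. **Adaptive re-weighted sampling.** Draw `⌈r_i·p⌉` variables with
   probability proportional to stability, with replacement; the distinct
   draws form the run's subset.
4. **Scoring.** 5-fold RMSECV of the inner PLS on the subset, with a
   fixed fold shuffle derived from the seed so runs are comparable.

The forced (EDF-sized) set — not the deduplicated draw — is carried into
the next run. Carrying the deduplicated subset forward would compound
its ~40 % shrinkage per draw and collapse 264 variables within about
nine runs, leaving most of the 50-run schedule empty; with forced-set
carry-over the candidate pool tracks the EDF exactly and subsets decline
smoothly to the floor of two variables, the trajectory this algorithm
family is known for. The run with minimal RMSECV wins, ties to the
earlier run. RMSECV uses the calibration set only; the prediction set is
never touched during selection. An optional repetition wrapper re-runs
the whole procedure and keeps the repetition with the smallest minimum
RMSECV (default: one repetition).

## Per-channel regression and metrics

The final per-channel model is ordinary least squares with intercept on
the selected bands. Rank-deficient designs are rejected with the
collinear column indices (pivoted QR). Rc/Rp are Pearson correlations
between predicted and measured moisture on the calibration/prediction
set; RMSEC/RMSEP the corresponding root-mean-square errors, in the units
of the modelled response. Moisture is carried in dry-basis percent
end-to-end; an optional min-max response scaling to [0, 1] is available
for users who prefer unit-interval errors. A constant prediction or
response makes the correlation undefined, which is reported as an
explicit flag, never silently zero.

In the orchestrated pipeline, the winning SCARS run is additionally
restricted to subsets of at most `n_cal/2` variables (argmin RMSECV over
feasible runs): on smooth synthetic spectra, where every band is
informative and heavily collinear, the RMSECV curve can bottom out at
large subsets for which OLS would be under-determined or unstable.

## Fusion model

The selected bands of the three channels are concatenated in fixed order
(power, absorbance, transmittance); the same frequency selected in two
channels remains two distinct columns. Because the channels live on
incommensurate scales, each fused feature is z-scored with calibration
mean/sd (a constant feature maps to zeros; min-max normalization is
available by flag) — equivalently, the PCA operates on the correlation
structure. PCA is computed by SVD of the centred calibration block;
contributions are squared singular values over their sum, and the
retained count k is the smallest index whose cumulative contribution
reaches the threshold (default 0.95, compared with a 1e−12 slack so a
printed cumulative of exactly 95.00 % counts as reached).

The regressor on the k scores is ε-SVR with RBF kernel. The response is
z-scored with calibration statistics before fitting — the ε grid
(0.001/0.01/0.1) is meaningful on a unit-variance response — and
predictions are mapped back. The grid spans g ∈ 2^−6…2^6, C ∈ 2^−4…2^6
and the three ε values, plus the triple (8.65, 2.41, 0.01) reported in
comparable work as an explicit parity point. The selection metric is the
correlation of pooled out-of-fold predictions under 5-fold CV on the
calibration set; ties break toward smaller C, then smaller g. Every
statistic in the chain — normalizer, loadings, SVR and its search — is
fit on calibration rows only.

## Determinism and problem sizes

One pipeline seed spawns independent sub-seeds for simulation, band
selection and the SVR fold shuffle; repeated runs of one configuration
produce byte-identical manifests, including content hashes of all
written CSVs. The test suite exercises the full study scale (80 samples
× 264 bands, 50 SCARS runs) — a complete pipeline run takes a few
seconds on one CPU — and repeats the fusion-versus-single-channel
comparison over ten seeds. SVR predictions are order-invariant only to
the dual solver's stopping tolerance (asserted at 1e−3 on standardized
responses), not bitwise.

## Known limitations

* The SCARS winner is a sampled subset, so two adjacent, equally
  informative bands may substitute for one another between seeds; the
  planted-band recovery criterion tolerates one missed band for this
  reason.
* The generator's affine nuisance model is a deliberate simplification;
  multiplicative scatter-style distortions and wavelength-dependent
  noise are not modelled.
* No vendor file formats are parsed and no time-domain processing (FFT,
  windowing, deconvolution) is performed; the package starts from
  frequency-domain tables.
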
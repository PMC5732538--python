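# Methods

This note documents the models, the tunable parameters, the synthetic-data
design, and the numerical choices behind `sipkit`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Image representation and preprocessing

Pixels are held as float64 in [0, 1]; integer inputs are divided by their
maximum code value (255 / 65535), so all downstream math sees a common
scale. Coordinates are 0-based `(row, column)`, row increasing downward.
Grayscale conversion uses the ITU-R 601-2 luma weights (0.299, 0.587,
0.114); Lab conversion assumes sRGB primaries and a D65 white point, with
grayscale inputs replicated to three channels first (they land on the
neutral axis). Resizing is bicubic everywhere and isotropic: the scale is
`sqrt(target / (w·h))`, each dimension rounded to the nearest integer ≥ 1,
which keeps the output area within 1 % of the target for all realistic
sizes; a second call on an already-conforming image is a no-op. Padding to
square centers the image and fills the border with the input's mean gray
(odd remainders go to the bottom/right).

## Edge-orientation entropies

**Filter bank.** 24 odd-symmetric (sine-phase) Gabor kernels at 15° steps,
wavelength 8 px at the 120,000-pixel analysis size (≈ 346 × 346), envelope
σ = 0.56 · λ (≈ one octave bandwidth), aspect ratio 1, truncated at 3σ and
re-centered to exactly zero mean. Sine phase makes the bank edge- rather
than line-sensitive, and the kernel at angle 180° is the negation of the
kernel at 0°, so the two half-banks encode edge polarity. Only the 12
distinct convolutions are evaluated; the other 12 responses follow by
negation.

**Response selection.** Each interior pixel (≥ 15 px from every border)
gets one winning orientation — the argmax of the 24 rectified responses —
and the 10,000 globally strongest winners are kept (fewer if fewer positive
responses exist; responses below 1e-9 are treated as zero to absorb FFT
round-off on flat regions). Ties at the cutoff break by (row, column,
orientation) order, so runs are exactly reproducible. One-winner-per-pixel
was chosen over keeping multiple orientations per pixel so that a single
high-contrast pixel cannot occupy several histogram bins.

**First-order entropy** is the Shannon entropy (bits) of the
strength-weighted 24-bin histogram after normalization; range [0, log₂ 24].

**Second-order entropy** accumulates every ordered pair (i, j): the frame
is rotated so edge i is horizontal, the displacement direction α is binned
into 48 × 7.5°, the distance d into 500 × 1 px (d = 0 skipped, d ≥ 500
discarded — the analysis-image diagonal is ≈ 490 px, so coverage is
complete), and the relative orientation θ = kⱼ − kᵢ into 24 bins, with
weight strengthᵢ · strengthⱼ (the natural symmetric reading of a
strength-weighted pair probability). Ordered pairs are used because the
reference rotation makes the two roles asymmetric. Per (d, α) cell the θ
histogram is normalized and its entropy computed; cells are averaged over α
per distance with empty cells excluded (zero-count cells carry no evidence,
and counting them as zero entropy would bias sparse images downward), then
over d = 20–80 px. Accumulation is chunked over reference edges (256 at a
time, ~10⁸ pairs for a full 10,000-edge set in well under a minute); the
result is independent of the chunking, which the tests verify.

## PHOG self-similarity

Images are converted to Lab and resized to 100,000 px. Gradients are
central differences per channel; each pixel contributes the orientation of
the channel with the largest gradient magnitude, binned into 16 bins over
the full 360° (polarity kept) and weighted by that magnitude. The pyramid
partitions the image 4-way per level (levels 0–3; odd dimensions give the
extra pixel to the bottom/right sections). Section histograms are
L1-normalized and compared with the ground histogram by the histogram
intersection kernel Σ min(h₁, h₂) — the comparator of the PHOG
self-similarity lineage. Aggregation is the mean over sections within a
level (all-zero sections excluded), then the mean over levels 1–3; the mean
was preferred to the median for smoothness, as the within-level aggregator
is otherwise unconstrained.

## Fractal dimension

The image is Canny-filtered (Gaussian σ = 1.0, hysteresis thresholds
0.1/0.2 on the [0, 1] scale — fixed in the run configuration for
reproducibility), cropped to the bounding box of its set pixels, and box
counted with dyadic box sizes from 2 px up to half the shorter cropped
side, mesh anchored at the top-left corner (no offset averaging). For
degenerate thin patterns (e.g. a 1-px line, whose shorter side would leave
fewer than three box sizes) the schedule falls back to half the longer
side. D is the OLS slope of log N(ε) versus log(1/ε) over all schedule
points; at least three points are required.

## Fourier slope and sigma

Luma grayscale → mean-gray square padding → bicubic resize to 1024 × 1024 →
power spectrum (squared DFT modulus, real-input FFT with conjugate-symmetry
weights in the annulus averages). Annuli are integer radial frequencies
1–512 cycles/image by rounding √(u² + v²). Log₁₀ power versus log₁₀
frequency is averaged inside 30 equal-width log-frequency bins spanning
5–256 cycles/image (a bin count that keeps ≥ 4 integer frequencies per bin
at the low end; empty bins are dropped), then fitted by OLS. Sigma is the
mean squared residual of the binned points about the line; it is reported
in squared log₁₀-power units (sigma is base-dependent, the base is fixed in
config). Power, not amplitude, is fitted. No window is applied before the
DFT — the mean-gray padding already suppresses wrap-around edges.

## Group statistics

All tests are rank-based. Kruskal–Wallis uses the tie-corrected H with the
χ² approximation (H guarded to 0 when all observations are identical).
Dunn's post-test computes z from pooled mean ranks with the tie correction
Σ(t³−t)/(12(N−1)) and adjusts two-sided p values by Bonferroni across all
pairs within a measure — Dunn's classical adjustment. The Wilcoxon rank-sum
z uses the tie-corrected normal approximation without continuity
correction; below a combined n of 4 the exact distribution supplies p and z
is recovered by the inverse normal. The effect size is Rosenthal's
r = |z|/√N. Undefined measure values (NaN from degenerate images) are
dropped listwise per measure, never imputed. The deviation rule flags
`high` (`low`) only when the artist median is beyond every one of exactly
four control medians *and* each of the four pairwise comparisons is
significant at α = 0.05 in that same direction — a deliberately
conservative conjunction. Five-category (pooled artists vs controls) and
per-artist analyses are the same operation on different groupings.

## Synthetic data: what it emulates, and what not

The generators plant exactly one controlled statistical property each and
are fully deterministic: a master seed derives per-image seeds through
`numpy.random.SeedSequence` spawn keys.

- `gen_powerlaw_noise`: inverse DFT of amplitude ∝ f^(−β/2) with uniform
  random phases, Hermitian-symmetrized (done directly on the real-FFT half
  plane, where symmetrization averages two independent phasors per
  coefficient — this amplitude randomness is what gives the spectrum its
  natural sampling scatter; a strictly deterministic amplitude would make
  the residual sigma an artifact of annulus discretization). Measured slope
  ≈ −β. β around 2 mimics monochrome graphic art, around 3 oil paintings.
- `gen_oriented_lines`: strokes sampled from a 24-bin orientation weight
  vector, rendered additively with equal unit heights and a sawtooth
  cross-profile (sharp 1.5-px flank, linear decay over 24 px). Two design
  points matter. First, the asymmetric profile gives each stroke one
  dominant edge polarity, so a point-mass weight vector concentrates the
  retained responses in a single orientation bin rather than a
  polarity-opposite pair. Second, flank positions are stratified along each
  orientation's normal: coincident parallel flanks would superpose into
  double-contrast edges whose secondary (opposite-polarity) response lobes
  — about 0.6 of the main lobe for a one-octave Gabor — would out-compete
  isolated main lobes; and flank spacings near the Gabor wavelength would
  turn the stroke field into a resonant sawtooth grating that the filter
  sees as a sinusoid, splitting responses 50/50 between polarities. Sparse
  stratified strokes (a few dozen per image for concentrated weight
  vectors) keep flank spacing at ~3 wavelengths and avoid both effects.
- `gen_box_fractal`: exact constructions (Sierpinski carpet of side 3^L
  with 8^L set cells, line, filled square) — closed-form dimension oracles.
- `gen_periodic_tiling`: one anisotropically smoothed noise patch tiled
  grid × grid (grid a power of two ≥ 8, aligning tiles with level-3 PHOG
  sections). The anisotropy gives the patch a dominant orientation so that
  optional per-tile 90° rotations visibly scramble section histograms.
- `gen_group_corpus` / `planted_shift_spec`: one artist group vs four
  control groups. The spectral-shift corpus places controls at β = 3.0,
  2.8, 2.6, 2.4 — spanning the oil-paintings-to-graphic-art range — and the
  artist 0.7 below the shallowest control, mirroring a "more fine detail
  than any control corpus" deviation; the orientation corpus gives controls
  uniform stroke orientations and the artist a point-mass distribution (low
  first-order entropy); the null corpus draws all five groups from
  identical parameters.

What the generators do *not* emulate: artistic content, color composition,
brush texture, or the correlated multi-property structure of real artworks
(a real corpus shift moves several SIPs at once; the planted corpora move
one by construction). Passing recovery tests therefore demonstrates that
the measurement and inference chain is correct and specific, not that any
particular empirical finding about real artwork corpora holds.

## Problem sizes and runtime choices

The test suite and the acceptance script run every stage at the sizes the
method prescribes (120,000 / 100,000-pixel analysis images, 1024² spectra,
full 10,000-edge pairwise accumulation where second-order entropy is
asserted). Corpus-level simulations use 15 images per group, 20 seeded
runs for the planted-shift and null recovery checks in the tests, and 10
runs in the acceptance script — sizes at which the planted effects are
overwhelming (complete or near-complete separation) so the recovery rates
are insensitive to the exact count. The deviation-recovery corpora compute
the two spectral measures rather than all six because those are the planted
and the adjacent nuisance measure; the entropy corpus exists as a second,
independent planting route.

## Known limitations

- Gabor parameters (wavelength, bandwidth) and Canny thresholds are fixed
  conventional choices; absolute entropy and dimension values shift with
  them, so only comparisons under a shared configuration are meaningful
  (outputs carry a config hash for that reason).
- Box counting uses a single top-left-anchored mesh; offset averaging would
  reduce small-sample bias in N(ε) at large ε.
- The box-count schedule bases itself on the cropped pattern's shorter side
  and falls back to the longer side for thin patterns; dimensions of
  near-1-D patterns embedded in large canvases are schedule-sensitive.
- Second-order entropy is O(n²) in retained edges (~10⁸ pairs per image);
  chunked NumPy evaluation takes tens of seconds per image on one CPU.
- EXIF rotation, ICC profiles and color management beyond assumed sRGB are
  out of scope, as is any automated curation of depicted content.
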
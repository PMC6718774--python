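# Methods

This note documents the models and procedures implemented in `caflux`,
the parameters that matter, the numerical conventions chosen where more
than one was defensible, and what the synthetic-data validation does and
does not demonstrate.

## Image model and segmentation

Input movies are ordered grayscale frames `(T, H, W)` with real
intensities, a frame rate `fps` and a pixel pitch `um_per_px`. Color
frames are reduced by Rec. 601 luminance (`0.299R + 0.587G + 0.114B`) —
monotone and exact for equal channels. Coordinates are 0-based
`(row, col)` with the origin top-left; all distances are computed in
pixels and scaled by `um_per_px` at the end.

Cell bodies appear as bright compact blobs. The detector runs on one
reference frame:

1. **Contrast stretch** `I = (O − min O)/(max O − min O)` maps the frame
   to `[0, 1]`; a constant frame maps to zeros with a warning. The
   stretch makes the downstream threshold scale-free: multiplying the
   input by any positive constant leaves the detection unchanged.
2. **Denoise** by Gaussian blur with `sigma_n` (default 1 px).
3. **Difference of Gaussians** `D = B∗G(σ_a) − B∗G(σ_b)` (defaults 2
   and 6 px) — a band-pass whose positive response peaks on blobs
   between the two scales when `σ_a < σ_b`. No ordering is enforced;
   the response is signed and the user chooses the convention.
4. **Threshold**: strictly `D > th` on the raw DOG response. `D` is
   *not* re-stretched before comparison, so `th` is calibrated against
   DOG amplitudes; for stretched input these lie well inside `[-1, 1]`
   and useful thresholds are typically 0.02–0.2.
5. **Connected components** at 4- or 8-connectivity (default 8, the
   usual blob-labeling convention), dropping clusters below
   `min_size_px` (default 4, suppressing single-pixel noise).

Gaussian kernels are truncated at radius `ceil(3σ)` and renormalized to
unit sum, so constant regions are preserved exactly; convolution is
separable (rows then columns) with reflect borders, which avoids the
dark rim zero-padding would create. Separability is exact: the test
suite checks agreement with a brute-force full-2-D-kernel convolution to
1e−9. Component labeling is iterative (scipy's C implementation), so
large blobs cannot overflow a recursion stack; a hand-written flood fill
serves as the independent oracle in the tests.

Manual editing is file-based: an added label mask contributes fresh
ROIs, removed ids are dropped, and disjointness is restored by
subtracting added pixels from overlapping automatic ROIs.

## Spike detection

Per ROI the brightness trace is the plain mean over the ROI's pixels per
frame. Detection runs on the first difference `r[n] = b[n] − b[n−1]`,
which cancels the (widely varying) per-cell baseline; adding a constant
to `b` provably leaves the spike train unchanged, and scaling `b` by
`c > 0` leaves it unchanged when `th_r` is scaled along.

The detector maintains a *filtered* rate series `r_f`. For each index
`n ≥ l` the window `r_f[n−l .. n−1]` supplies

- `μ_l` — window mean,
- `σ_l` — window **population** standard deviation (1/l normalization),

and the sample is scored `z[n] = (r[n] − μ_l)/σ_l`. A spike requires
both `z[n] > th_z` and `r[n] > th_r`; the absolute floor suppresses
detections on traces so quiet that tiny fluctuations have large
z-scores. After scoring, the filtered series updates:

```
r_f[n] = i·r[n] + (1−i)·r_f[n−1]   if s[n] = 1
                                    or (−r[n] − 2μ_l)/σ_l > th_z
         r[n]                        otherwise
```

The first branch limits the influence of the spike itself — and of the
equally extreme *negative* rate excursion on a transient's falling
edge — on the running statistics, so bursts cannot inflate `σ_l` and
mask subsequent spikes. The asymmetric `−2μ_l` term in the negative
gate is kept exactly as specified for the original algorithm; a
symmetric alternative (`|z| > th_z`) behaves almost identically on
realistic traces since `μ_l ≈ 0` for a rate signal.

Numerical conventions, chosen where the original description is silent
or ambiguous:

- **Window contents**: the `l` most recent filtered samples. (A literal
  reading of the published index bounds spans `l+1` samples against a
  `1/l` factor; `l` samples is the self-consistent reading and matches
  the stated "window of user-defined length `l`".)
- **Dispersion summand**: deviations of the window samples from the
  window mean (the alternative — deviating the *scored* sample — is not
  a dispersion at all).
- **Statistics over `r_f`, not raw `r`**: otherwise the influence
  mechanism would have no effect.
- **Zero-dispersion rule**: when `σ_l = 0` (noiseless window), `z` is
  `+∞` for any positive deviation and 0 otherwise, so detection still
  works on noise-free synthetic data instead of dividing 0/0. The
  negative gate degenerates analogously to a sign test
  (`−r[n] − 2μ_l > 0`).
- **Warm-up**: the first `l` samples initialize `r_f = r` and report no
  spikes; transients planted inside the warm-up are by construction
  undetectable.

Defaults `l=10, th_z=5, i=0.50, th_r=0.100` are the published operating
point for low-noise footage. ROIs with fewer than `min_spikes`
detections can be excluded to compensate for spontaneous activity.

## Cross-correlation and network reconstruction

For signals `f, g` of two ROIs (spike vectors by default; brightness or
rate configurable) the lagged Pearson cross-correlation is

```
x_τ = Σ_n (f[n−τ] − μ_f)(g[n] − μ_g) / (‖f − μ_f‖ · ‖g − μ_g‖)
```

with means and norms over each *full* series and the sum over the
overlapping index range only (the original formulation leaves edge
handling open; full-series normalization keeps `x_0(f, f) = 1` exact
and the estimator bounded). A constant series has zero norm and scores
0 with a warning. The identity `x_τ(f, g) = x_{−τ}(g, f)` holds to
machine precision; a positive `τ` means `f` leads `g`.

The network is reconstructed per unordered pair: `x_τ` is evaluated for
`|τ| ≤ ⌊max_delay_s · fps⌋` and its maximum located, with ties broken
toward the smallest `|τ|` and then the positive lag. An edge is created
iff the peak strictly exceeds `min_corr` and the centroid distance is at
most `max_dist_um`. The peak lag orients the edge leader → follower; a
zero-lag peak gives two reciprocal edges, rendering an undirected link.
Peak-over-lags (rather than `x_0`) is the aggregation consistent with a
"response within the delay bound" reading; both open choices are local
to `reconstruct_network` and easily changed. The constraints are
monotone by construction: raising `min_corr` or lowering the distance or
delay bound can only remove edges.

Default thresholds (`min_corr 0.25`, `max_dist_um 208`,
`max_delay_s 0.5`) are the published operating point for 1040-µm-wide
footage of neuron cultures, where typical neurite lengths of order
100 µm make longer connections anatomically implausible.

Map data (heat map totals normalized to the maximum; spatiotemporal
circles per active ROI with spike count and mean spike frame
`n_avg = Σ s[n]·n / Σ s[n]`) are exposed as plain tables; plotting is
left to the caller.

## Evaluation protocol

`match_rois` classifies by pixel overlap (≥ `min_overlap_px` shared
pixels, default 1 — the protocol never quantified "overlap", and one
shared pixel is the most permissive faithful reading):

- a detection overlapping ≥ 2 reference cells is a **merge** and is
  excluded from both TP and FP counting;
- a detection overlapping none is a **FP**;
- per reference cell, the largest-overlap single-cell detection (tie →
  lowest id) is the **TP**; redundant ones are FPs;
- an untouched reference cell is a **FN**; one covered only by merged
  detections is reported in a separate `merged_covered` bucket, not as a
  FN, because merge and miss are different error modes.

Every detection lands in exactly one of {TP, FP, merged} and every
reference cell in exactly one of {TP, FN, merged-covered}; this
conservation is property-tested on random configurations. Scores:
`TPR = TP/P`, `PPV = TP/(TP+FP)`, `recall = TP/(TP+FN)`, reported as
missing when a denominator is zero.

`match_spikes` matches detected to reference spike frames within
± `tolerance_frames` (default 1) by a sorted two-pointer sweep, which
attains the maximum-cardinality matching for this interval structure
(verified against a brute-force assignment oracle).

## Synthetic data

The generator emulates the features the analysis actually keys on:
compact bright cells (isotropic Gaussian blobs, σ default 3 px) on a
dark background, per-cell baselines (uniform in a configurable range),
instant-rise / single-exponential-decay transients (decay constant
default 3 frames), Bernoulli spiking, directed propagation along planted
edges (fixed lag, fixed transmission probability, applied transitively
so chains work), and additive Gaussian sensor noise. Default geometry
(128×128 px, 200 frames, 20 cells, 10 fps) keeps every validation run in
seconds on one core; the spec is a plain dataclass and scales up freely.

Randomness derives from one master seed through named per-cell
substreams, so output is a pure function of the spec and adding cells
does not reshuffle existing ones. Cells are placed by rejection sampling
with non-overlapping 3σ supports (bounded retries, then an error);
ground-truth masks cover 2σ disks.

What passing the synthetic validation does **not** show: robustness to
photobleaching or brightness drift, motion artifacts, non-isotropic or
touching cell shapes, neurites, Poisson-dominated noise, or dual-
exponential indicator kinetics — none of which the generator renders.
Results on real footage depend on parameter choices the same way the
original interactive workflow does.

## Validation conditions

The acceptance script and test suite use these fixed conditions:

- *Segmentation recovery*: 20 blobs, peak amplitude 10× the noise σ
  (peak SNR 10), detector at `σ_n=1, σ_a=2, σ_b=6, th=0.1`; required
  TPR ≥ 0.95 with zero false positives and centroids within 3 px.
- *Spike recovery*: 100 rate traces of 199 samples, pulses of 8× the
  noise σ planted with gaps larger than the detection window (isolated
  spikes; the detector's window statistics are only stationary between
  transients), detector at the published defaults; required sensitivity
  and precision ≥ 0.95. The SNR is defined on the rate signal the
  detector consumes.
- *Network recovery*: three collinear cells 150 µm apart, planted chain
  1→2→3 at 1-frame lag and transmission probability 1, movie at 10 fps
  and high SNR; the reconstruction must equal the planted edge set with
  correct directions, and the 300-µm 1–3 pair must be removed by the
  distance bound.
- *Determinism*: identical inputs and configuration must reproduce
  byte-identical CSV artifacts. The engine is single-threaded and uses
  no hidden global state, so this holds trivially by design; it is
  asserted end-to-end anyway.

## Known limitations

- The detector finds bright cores, not full cell outlines; area-based
  statistics underestimate true cell sizes (region growing is out of
  scope).
- The z-score detector degrades on near-constant high-rate activity:
  dense spiking contaminates the window statistics faster than the
  influence mechanism can compensate.
- Correlation-based direction inference cannot distinguish a true
  1→3 connection from transitivity through 2; only the anatomical
  constraints prune such shortcuts.
- TIFF stacks are not parsed (one file per frame); video support beyond
  multi-frame GIF requires the optional FFmpeg backend.
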
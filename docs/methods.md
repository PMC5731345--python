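# Methods

## Model

Transcription profiles are per-nucleotide counts of sequenced template
fragments covering each position of a reference, kept separately per
strand.  The profile height is a relative measure of steady-state
transcript abundance M(x) (arbitrary units, au).  The model assumes
first-order decay at a single bulk rate γ for every transcript, so at
steady state dM/dt = J(x) − γM(x) = 0 and the RNA-polymerase flux past
position x is J(x) = γM(x), in au/s.  All part metrics are functionals
of profile heights:

- Promoter activity: δJ = γ·(mean M over the n nt just downstream of the
  measurement boundary − mean M over the n nt just upstream).  The
  upstream window is the background (flux arriving from further
  upstream), so δJ isolates the flux the promoter itself launches.  When
  the promoter is insulated by a self-cleaving ribozyme the coverage
  step appears at the cleavage site, not at the promoter, because the
  cleaved 5′ leader is too short to survive library preparation; both
  windows then flank the annotated cut site.
- Terminator strength: T_s = (mean M over n nt before the part start) /
  (mean M over n nt after the part end), the fold decrease in transcript
  level across the terminator; the read-through fraction is 1/T_s.  The
  ratio as implemented is upstream/downstream — the orientation that
  makes a strong terminator a large number, consistent with the standard
  "fold decrease" characterization of terminator libraries.
- Ribozyme cleavage efficiency: with background flux B measured just
  upstream of the promoter TSS, p_c = 1 − (J_up − B)/(J_down − B), where
  J_up/J_down are window fluxes just up/downstream of the cut site,
  clamped to [0, 1].  Coverage upstream of the cut comes only from the
  uncleaved fraction.  That uncleaved leader is itself a transcript 5′
  end and carries the usual end-coverage bias, so the net upstream flux
  is divided by the correction factor C evaluated at the window's
  distance from the TSS (this assumes the background is locally flat —
  a good approximation whenever the background is small relative to the
  promoter's own flux).
- Devices: a sensor is summarized by the mean output-promoter activity
  over its on states and over its off states.  A NOT gate maps total
  input flux J_in (sum of input promoter activities plus upstream
  read-through; NOR gates are NOT gates on the summed inputs) to output
  activity through the repressing Hill form δJ_out = δJ_min +
  (δJ_max − δJ_min)·Kⁿ/(Kⁿ + J_inⁿ).

## End-coverage correction

Fragments counted toward a transcription unit must lie wholly inside
it, so a position x nucleotides from a transcript end can only be
covered by placements that fit between it and the boundary.  The
expected depletion depends only on the fragment-length distribution
(FLD).  It is reconstructed by Monte Carlo: lengths are drawn from the
empirical FLD and placed uniformly over the valid starts of a
hypothetical 2,000-nt unit; the pile-up T(x), max-normalized over its
first 500 nt, is the correction factor profile C(x).  Observed unit
profiles are divided by C at the 1-based distance to the nearest unit
end (≤ 500 nt); interior positions are untouched.  The closed form for
a single length L, min(x, L, N−x+1, N−L+1), serves as the test oracle.

Correction scope: only annotated transcripts internal to the circuit —
from the ribozyme cut site (or the promoter TSS when there is no
ribozyme) to the end of the next terminator.  Read-through regions
between units, antisense tracks and host transcription are left
uncorrected: the molecules covering them are long transcripts passing
through, whose local coverage carries no end bias.

Numerical choices: 10⁶ draws by default with a fixed recorded seed; the
Monte-Carlo pile-up is accumulated with difference arrays (exact integer
counts); C is reported unsmoothed.  A unit shorter than 1,000 nt makes
the two end windows overlap; the nearest-end distance is used so each
position is divided exactly once.

## Fitting

Gate responses are fitted by minimizing E1 = Σ_i [log(δJ_i) −
log(δJ_out(J_in,i))]² over (δJ_min, δJ_max−δJ_min, K) in log space and n
linearly, with SLSQP under bounds (magnitudes up to e²⁵, cooperativity
in (0.1, 8]).  Measured activities at or below a floor of 10⁻² au/s are
replaced by the floor before logging (off states can measure exactly
zero).  The optimizer starts from a small grid — K at the quartiles of
the positive input fluxes crossed with n ∈ {1, 2, 4} — and the lowest
error wins, ties going to the smaller n.  Flat observation sets are
returned flagged as degenerate (K is unidentifiable) rather than
raised.  Fewer than four observations is an error: the model has four
free parameters.

Tandem promoters cannot be separated within one profile (both cleaved
leaders are lost at the shared ribozyme), so they are measured as one
combined part and deconvolved across states by minimizing E2 = Σ_i
[log(δJ_{1+2,i}) − log(δJ_1,i + δJ_2,i)]², where each device contributes
its model value (on/off level for a sensor, Hill response of that
state's input flux for a gate).  E2 depends on the devices only through
per-state sums, which leaves one exact flat direction: a constant can be
moved between the two devices' output levels (both sensor levels, or a
gate's δJ_min and δJ_max together) without changing any prediction.
The fit pins this gauge by convention: the first device's minimal
output level is set to the log floor, i.e. the first device is taken to
be tight when off and residual leakiness is attributed to the second.
Identifiability is checked structurally first — two sensors with
identical on/off patterns across all states are rejected by name, as
are state sets smaller than the parameter count or missing inducer
combinations.  The fractional split of a combined measurement,
δJ_1,est = δJ_{1+2}·δJ_1/(δJ_1+δJ_2), conserves the measurement exactly.

## Normalization

Between-sample scaling uses trimmed-mean-of-M-values factors: per-gene
log2 ratios against a reference sample (the one whose upper-quartile
count fraction is closest to the mean), doubly trimmed (30% on M, 5% on
A), combined with inverse-variance weights from the delta-method
binomial variance, and centered to geometric mean 1.  The
implementation was validated against the reference implementation in
the edgeR package on a frozen fixture (agreement to ~10⁻¹¹).  FPKM uses
the effective library size (total mapped fragments × TMM factor);
profile normalization divides by the same effective library size over
10⁶, a convention chosen for internal consistency with FPKM.  Gene
expression in profile units is the mean height over the gene body.

## Synthetic data

The simulator emulates exactly the statistical structure the estimators
assume, so recovery tests are tests of the estimators, not of
additional biology:

- Expected profiles are traced 5′→3′ with the same rules the prediction
  module uses (promoters raise the height at the TSS by s·(1−p_c) of
  the assigned downstream ribozyme; ribozymes set it to the summed
  driving strengths plus terminator read-through; terminator ends
  divide by T_s), with M = J/γ.  Antisense promoters lay mirrored
  plateaus on the minus strand.
- Fragments are sampled per transcript species, not per plateau:
  uncleaved transcripts run from the TSS to the terminator end, cleaved
  3′ products from the cut site, and read-through continues past a
  terminator as the same long molecule (1/T_s of each stream).  For a
  drawn length L a species is selected with probability proportional to
  abundance × (length − L + 1) — the number of valid placements — and
  the start is uniform over them, which makes interior coverage exactly
  proportional to abundance and reproduces the end curvature the
  correction model expects.  Lengths that fit no species are redrawn.
- Noise enters in two places only: multiplicative lognormal jitter on
  per-state promoter activities, and the fragment sampling itself.

Defaults are chosen to emulate a bacterial RNAtag-seq-style experiment:
fragment lengths from a discretized truncated normal (mean 150 nt, sd
30, range 60–300), ribozyme cleavage efficiency 0.95 (typical of
RiboJ-class insulators), γ = 0.0067 s⁻¹, averaging window n = 10 nt,
low-flux filter 1 au/s, and circuit read-through entering the backbone
at 0.05 au/s.

What the simulator does not model — and what passing recovery tests
therefore do not demonstrate about real libraries: sequence-dependent
fragmentation and priming bias, fragments spanning cleavage sites of
the uncleaved fraction, polymerase traffic and premature termination
within genes, transcriptional bursting, rRNA depletion artifacts, or
host-genome background beyond an optional uniform floor.

Profiles recovered from simulated fragments are in raw count units;
recovery scoring rescales them by one global factor anchored to the
truth record's total expected profile mass (au is a relative scale; in
real data the anchor is the TMM-scaled library size, which has no
absolute meaning against simulator truth).

## Problem sizes and accuracy

The shipped validation runs use a 6 kb two-unit circuit at 10⁶
fragments per state, 10⁶ Monte-Carlo draws for the correction profile,
and 100 seeded repeats for noisy-fit statistics.  Under those
conditions promoter activities are recovered within a few percent,
terminator strengths within ~5%, cleavage efficiencies within ~0.02
absolute, noiseless Hill fits to ~10⁻⁷ relative, and K/n within 15% in
well over 90% of σ = 0.1 noisy repeats.  The Monte-Carlo pile-up is
compared to its closed form after scaling by the end-window mean rather
than the noisy maximum: the max over ~400 plateau counts is biased high
by about 1%, which would otherwise dominate the comparison.

## Known limitations

- The promoter measurement across a ribozyme cut site reads s·p_c plus
  a small leader correction; at the default p_c = 0.95 the residual
  bias is ≲2%.  A cleavage-corrected value (δJ divided by the estimated
  p_c) is reported in the measurement extras as a diagnostic.
- The p_c estimator needs the driving promoter's TSS annotated and at
  least n nucleotides between TSS and cut site.
- Series deconvolution reports gauge-fixed parameters; only sums of the
  two devices' outputs are determined by the data, and the convention
  (first device tight) should be kept in mind when comparing fitted
  off-levels across analyses.
- Host-genome fragments participate in gene counting and library sizes,
  but full per-nucleotide host profiles are not retained by default
  (memory).
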
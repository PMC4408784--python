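# Methods

## The measurement model

Stop-based chemical probing reads RNA secondary structure through reverse
transcription: an acylating reagent modifies the 2′-OH of conformationally
flexible riboses, and the adduct blocks the reverse transcriptase so that
the cDNA's 3′ end sits one nucleotide 3′ of the modified position.
A sequenced fragment is therefore summarized as a pair
(left = termination position, right = priming position) on the RNA, and a
fragment with left end *p* > 1 is counted as one stop at position *p* − 1.
Fragments with left = 1 reached the RNA 5′ end (run-off) and are kept in a
separate bucket: they carry no positional structure information and their
fraction of the library is the main diagnostic of background. This
termination convention — termination is a *failure to extend into the next
position*, for both adduct blocks and spontaneous drop-off — is used
consistently in the counter and the simulator, so the counting rule
recovers the adduct position exactly. The alternative reading (assign the
stop to *p* + 1) was rejected because it would place run-off counts inside
the molecule.

## Counting, coverage and TCR

Coverage at position *i* counts fragments that span *i* or terminate at it
(the covered set of a fragment (p, q) is the contiguous run [p−1, q]),
restricted to fragments whose priming site is at least
`min_priming_distance` (default 100 nt) away: libraries are size-selected,
so positions close to a fragment's priming site are depleted in a way that
would bias the ratio. The termination-coverage ratio is
TCR(i) = stops(i)/coverage(i), missing where coverage is zero ("no signal
observed" is not "zero reactivity").

One consequence of the distance rule: a stop whose fragment is shorter
than the threshold contributes to the raw termination profile but not to
coverage. The `tcr` function therefore treats counts(i) > coverage(i) as an
input-consistency error, and the pipeline computes the TCR numerator with
the *same* distance rule as the denominator
(`termination_counts(..., min_priming_distance=...)`), which guarantees
TCR ∈ [0, 1]. Raw, unfiltered termination counts remain the input to the
window normalization and to run-off fractions.

## Window Winsorized normalization

Random priming is strongly biased, so absolute counts are not comparable
along a long RNA. Every contiguous window of `window` nt (default 70) is
visited once; within a window, q = the 95th percentile of the counts,
counts above q are capped at q (upper-tail Winsorization) and all are
divided by q, giving in-window reactivities in [0, 1]. A position's final
reactivity is the mean of its values over all windows containing it.
Numerical choices that matter:

- **Quantile estimator**: linear interpolation between order statistics
  (numpy's default, matching R's default type 7). The 95th percentile of a
  70-point window differs across estimators, so this is fixed and the
  brute-force oracle in the tests uses the same estimator.
- **Winsorization is one-sided** (upper tail only): values above the
  percentile are capped; nothing is done to the lower tail.
- **Edges**: windows are all length-min(window, L) contiguous blocks;
  positions near the ends simply belong to fewer windows and are never
  dropped or given truncated windows.
- **Empty windows** (q = 0) contribute nothing; a position whose every
  window is empty is missing, not zero.
- The profile is invariant to rescaling all counts by a positive constant,
  and 30-nt to several-hundred-nt windows give closely similar AUCs on
  simulated data (the suite checks 30/70/300 pairwise within 0.05).

The default window of 70 trades locality (tracking priming bias) against a
stable percentile estimate from ~70 counts.

## ΔTCR background correction

With a no-reagent control, the background contribution is removed on the
TCR scale: ΔTCR = (TCR_S − α·TCR_C) / (1 − α·TCR_C), where α scales how
much of the control's termination propensity is present in the probed
sample. Positions where α·TCR_C ≥ 1 are set missing with a warning.
Rather than estimating α from a background model, a grid (default 0 to
0.99 in steps of 0.01; 1 is excluded to protect the denominator) is
searched for the α whose ΔTCR profile maximizes the AUC against a
reference structure; ties break toward the smallest α (least background
assumed). ΔTCR values are not clipped to [0, 1] by default — negative
values are informative about over-subtraction — and an optional clamp
exists for plotting parity.

## Structure-signal evaluation

The classifier is per-position pairing state with **unpaired as the
positive class**; higher reactivity must predict unpaired (this direction
follows from the chemistry and is fixed, not configurable). AUC is the
Mann–Whitney rank statistic, P(score_unpaired > score_paired) + ½·P(tie),
computed from midranks; ROC points are returned for plotting and their
trapezoid area equals the rank AUC. Filters before evaluation: the
configured region (1-based inclusive; default whole molecule), ribose
accessibility > 3 Å² when accessibility values are supplied (buried
riboses cannot react regardless of pairing), and non-missing scores
(missing coverage is excluded, never imputed). Dot-bracket (all bracket
families plus pseudoknot letters) and CT files are parsed; a plain
per-position paired/unpaired TSV is also accepted because neither format
can encode every noncanonical pair a crystal structure shows. Spearman
correlations use midranks with pairwise deletion of missing positions.

## Hydrolysis kinetics

Reagent hydrolysis produces a fluorescent product, fit as
f(x) = y₀ + a·(1 − e^(−bx)) by Levenberg–Marquardt least squares
(tolerances 1e−10; initialized from the data: y₀ ← first value,
a ← observed range, b ← 1/time span). Half-life is defined as ln 2 / b,
the only definition consistent with a reagent pool decaying as e^(−bt);
the raw decay constant b is always reported alongside so users can apply
any other convention. Degenerate inputs (constant signal, b ≤ 0, singular
covariance) yield a *flagged* fit rather than an exception.

## The synthetic-data generator

`simdata` generates experiments at the aligned-fragment abstraction with
these defaults, which define the conditions all simulation-based tests run
under:

| parameter | default | meaning |
|---|---|---|
| mod_rate_unpaired | 0.02 | adduct probability per unpaired position |
| mod_rate_paired | 0.002 | adduct probability per paired position |
| dropoff_rate | 0.002 /nt | spontaneous RT termination per extension |
| readthrough_prob | 0.0 | chance RT ignores an adduct |
| min_fragment_len | 20 nt | library size cutoff |
| selection_keep | 0.8 | adduct-terminated cDNA survives selection |
| selection_leak | 0.02 | background cDNA survives selection |
| priming | 3′-skewed ramp × lognormal(σ=0.5) | biased random priming |

Selection efficiency and leak rate are illustrative choices (no published
quantitative values exist); the 10× unpaired/paired rate contrast and the
small per-position rates reflect single-hit-style probing chemistry.
Synthetic structures are chains of hairpins (stems 3–8 bp, loops 3–8 nt,
adaptive linkers) hitting a target unpaired fraction, default 45%.
A closed-form *analytic twin* (`expected_stop_fraction`) gives the exact
marginal stop distribution of the generative model (per-step survival
s_i = (1 − m_i(1 − r))(1 − d), telescoped over priming positions), and the
simulator is tested against it position by position.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: sequence-dependent reagent or RT
preferences, RNA degradation and other non-drop-off background, mapping
and base-calling errors, PCR duplicates, inter-molecule structure
heterogeneity, and the correlated (helix-structured) placement of real
base pairs beyond the hairpin geometry. Under the default conditions the
simulated signal-to-background is stronger than typical real experiments —
probed-arm AUCs reach ~0.95+, where real probing data sit far lower — so
the pipeline's qualitative orderings (control ≈ 0.5 < probed < selected;
selection collapses run-off and depletes an unmodified spike-in) are the
meaningful checks, not the absolute AUC values.

## Problem sizes and runtime

The end-to-end simulation used by the tests and the acceptance script is
50,000 molecules on a 1,500-nt RNA plus two 300-nt spike-ins at 5,000
molecules each — large enough that Monte-Carlo error is negligible against
every asserted margin, and the whole suite still runs in seconds. The RT
walk is vectorized as a max over candidate stop positions (geometric
drop-off target vs highest blocking adduct below the priming site), which
is distributionally identical to the sequential walk; at a tie the adduct
wins, since it is encountered before the drop-off draw for the same step.
One seed drives each experiment; per-arm substreams are spawned
deterministically from it, so identical seeds give byte-identical outputs.
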
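# Methods

## Problem setting

Nanopore modification callers (e.g. tombo's alternative-model method)
emit, for every adenine of a reference, the estimated *fraction of
modified bases* — the proportion of reads in which that base appears
modified.  `modmotif` implements the downstream analysis that turns two
such tracks (a test sample and an unmodified negative control) into a
sequence motif for the modifying enzyme, plus the two orthogonal lines
of evidence used to corroborate such a motif: a methylation-aware
in-silico restriction digest and monoisotopic-mass annotation of
modified nucleosides from LC-MS peak lists.

## Pipeline model

1. **Control subtraction.** At every position/strand covered by the test
   track the differential signal is `max(0, f_test − f_control)`, with a
   missing control value treated as 0.  Positions missing in the test
   track stay missing: the pipeline never invents coverage.  This
   cancels systematic caller error, which affects both libraries alike.
2. **Window extraction.** Every fixed-width window (default 10 bp, the
   scale at which nanopore signal localises a modified base) is scored
   by the sum of differential fractions over both strands.  The top
   K = 100 windows are selected greedily in descending score with a
   disjointness constraint, ties broken toward the smaller start.
   Disjointness makes the 100 sequences independent pieces of motif
   evidence; summed (rather than averaged) scores are equivalent for
   ranking at fixed width but keep missing-value handling explicit.
3. **Two-strand ZOOPS EM.**  Each window sequence contains zero or one
   motif site (ZOOPS): with prior `lam` a site is present, uniform over
   start positions and, in reverse-complement mode, strands.  Site
   columns follow a PWM; everything else follows a 0-order background
   estimated once from the input and strand-symmetrised in
   reverse-complement mode (so the model treats both strands of the
   input identically).  The M-step uses a pseudocount of 0.25 per base,
   making the iteration MAP-EM with a Dirichlet(1.25) prior; the
   objective that is provably non-decreasing — and the one recorded in
   `MotifResult.trajectory` — is log-likelihood + log-prior.  Iteration
   stops when the objective gain falls below 1e-9 (500 iterations
   maximum); the tight threshold makes independently converged runs of
   the same optimum agree in likelihood to ~1e-6, which the
   strand-symmetry property relies on.  Ten seeded restarts are drawn
   from random input subsequences, and the winner is the model with the
   best *raw* data log-likelihood (the prior term would otherwise favour
   smoother, occasionally phase-shifted models).
4. **Orientation canonicalisation.**  Under a two-strand search a motif
   and its reverse complement are likelihood-equivalent, so "the"
   consensus is only defined up to orientation.  The returned model is
   the orientation whose consensus is lexicographically smaller (ties
   broken toward more plus-strand assignments); strand labels of the
   assignments are flipped accordingly.  With the planted ATC/GAT pair
   this reports ATC, matching the convention of reporting one strand of
   a two-strand motif.
5. **Width selection and core trimming.**  The pipeline scans widths
   3–8 and ranks the per-width models by BIC (3·width + 1 free
   parameters).  Because the top windows are co-selected around strong
   sites, flanking columns pick up real but weak enrichment (~0.1–0.2
   bits, e.g. a second site's bases); BIC therefore sometimes prefers a
   wider model whose extra columns carry almost no information.  The
   reported motif is the *information-trimmed core* of the best model:
   flanking columns below 0.25 bits (an eighth of the 2-bit maximum) are
   dropped and sites re-assigned.  The core columns of the planted motif
   carry 1.4–2.4 bits, so the decision is insensitive to the exact
   threshold over a wide range.
6. **Context profiling.**  For the discovered core the genome is
   scanned on both strands (IUPAC-aware, overlapping matches, circular
   wrap where applicable), the mean modified fraction at the target
   adenine is computed per motif (missing values count as 0, palindromic
   loci contribute one observation per strand), and the motif is
   extended one position at a time up- and downstream with each concrete
   base to probe flanking-base preferences.
7. **Restriction cross-check.**  `digest` cuts an `EnzymeProfile`'s
   primary palindromic sites only when *fully* methylated (both strands)
   and, optionally, its secondary sites on single-strand methylation.
   The shipped DpnI profile cuts GA^TC blunt (offset 2) with secondary
   CATC/GATG; the "to a certain extent" secondary activity is modelled
   as a boolean switch, not a probability, since no rate is available.
   Fragment lengths always sum to the genome length (c cuts → c+1
   fragments on a linear genome, c fragments on a circular one).

## Synthetic data generator

The generator emulates the study conditions the pipeline is meant for: a
genome in which every adenine of a fixed 3-mer context (default ATC, on
both strands) is strongly modified and everything else is background.

| parameter | default | meaning |
|---|---|---|
| `genome_length` | 200 000 bp | i.i.d. genome, `gc` = 0.5 |
| `motif`, `mod_offset` | ATC, 0 | planted context; the modified base must be an adenine |
| `p_hi_alpha/beta` | 8, 2 | planted fractions ~ Beta(8,2), mean 0.8 |
| `p_bg_alpha/beta` | 1, 19 | background and control ~ Beta(1,19), mean 0.05 |
| `blur_halfwidth`, `blur_decay` | 2, 0.5 | neighbour at distance d raised to max(current, f·0.5^d), same strand |
| `seed` | 1 | one global seed; per-stage sub-streams are spawned deterministically |

The Beta noise shapes are a modelling choice — modification callers do
not publish an error law for fraction estimates — and the geometric blur
encodes the ~5 bp localisation uncertainty of nanopore signal.  Only
adenine-bearing strand-resolved positions are covered, as a caller
restricted to 6mA would produce.  What the generator does **not**
emulate: read-depth variation (every position is "covered" equally),
non-specific off-target methylation, caller false positives correlated
between test and control beyond the shared background law, and real
genome composition (no repeats, no GC skew).  Passing tests therefore
demonstrate correctness of the *analysis*, not caller accuracy on real
signal.

Per-read quality scores are drawn from Normal(7.5, 1.5²) for native
libraries and Normal(11.5, 2.0²) for PCR libraries, truncated to
[1, 30] — hypermodified native DNA basecalls poorly (~Q7.5 ≈ 20%
error), PCR-amplified DNA does not (~Q11.5 ≈ 5–7% error).  The average
per-read quality is defined in error-probability space
(−10·log10 of the mean per-base error), the nanopore-tooling
convention; quartiles use linear interpolation (type 7).

## Mass annotation

Masses are monoisotopic over C/H/N/O/P (C 12 exactly, H 1.0078250319,
N 14.0030740052, O 15.9949146221, P 30.97376151); adducts are singly
charged, M ± 1.00728.  `explain_peak` enumerates (base species +
optional modification delta) candidates within an explicit tolerance —
0.03 Da for peaks printed to two decimals, 0.005 Da for four-decimal
peaks; tolerances are never hidden in rounding.  `explain_fragments`
assigns MS2 fragments to single or depth-2 chained neutral losses from
the parent composition.  The pentose decoration is shipped as the net
composition C5H8O4 ("pentose+O": a deoxypentose plus the O-glycosidic
oxygen retained by the base on fragmentation); no attachment structure
is implied.  One shipped peak, 360.10, is an MRM precursor-isolation
setpoint rather than a calibrated centroid — the pentosylated
deoxycytidine nucleoside it isolates has [M+H]+ = 360.1401 — so the
shipped peak list carries a wider (0.05 Da) tolerance for that row.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere; bedGraph I/O is
  shift-free and fractions are serialised with `repr` for bit-exact
  round-trips.
- Missing track values are NaN-backed and type-distinct from 0; each
  consumer states its imputation (differential: control-missing = 0;
  window scores and motif means: missing = 0).
- Consensus ties break A < C < G < T; assignment posterior ties break
  toward the lowest component index (no-site, then plus-strand sites
  left to right, then minus).  On exact-repeat inputs (e.g.
  `ATCATCATCA`) the motif phase is not identifiable and which cyclic
  phase is returned depends on initialisation.
- Windows with non-positive scores are never returned; if fewer than K
  qualify the shorter list is returned with a warning.
- Zero-length digest fragments (cuts at linear ends) are dropped;
  length conservation is asserted structurally.

## Known limitations

- The ZOOPS EM is a minimal motif finder: one motif per run, no OOPS/ANR
  models, no position priors, no E-value calibration against shuffled
  sequences.
- BIC width ranking plus information trimming is a pragmatic
  model-selection recipe, appropriate for short cores inside co-selected
  windows; it is not a substitute for a calibrated significance score.
- The digest models cut/no-cut only — no partial digestion kinetics or
  band intensities.
- Mass annotation is restricted to singly charged [M+H]+/[M−H]− species
  over C/H/N/O/P, matching the nucleoside chemistry it targets.
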
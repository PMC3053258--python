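# Methods

## Scoring model

A candidate precursor is scored by its natural-log posterior odds of
being a real miRNA precursor versus background, factorized over five
conditionally independent features (normalized MFE, shuffling
stability, read signature, nucleus conservation, star-read presence)
plus a prior term. All log-odds are natural logs; this convention is
forced by back-calculation of the published discrete constants from
their underlying frequencies (ln(0.98/0.25) = 1.37,
ln(0.02/0.75) = −3.624, ln(0.69·3000) = 7.64, ln(0.31/(1−1/3000)) =
−1.17; log2 reproduces none of them). The conserved-nucleus constant is
tabulated as 7.63; the exact recomputation from the rounded frequencies
0.69 and 1/3000 gives 7.635, i.e. the tabulated value appears to derive
from the unrounded cross-validated frequency. The package computes, and
reports, the exact value from its inputs.

Two tabulated constants carry sign ambiguity in their source
(unstable, non-conserved printed both positive and negative); the
negative signs are used, since the log-odds of a feature state
anti-correlated with real precursors must be negative.

### MFE term

The MFE is normalized by precursor length (kcal/mol/nt), which removes
the strong linear length dependence of hairpin MFE and collapses the
per-length distributions onto one curve. The log-odds of normalized MFE
x is modeled by a modified sigmoid f(x) = a/(b + e^{c·x}). Shipped
constants: monocot a = 1.339e-12, b = 2.778e-13, c = 45.843; dicot
a = 4.46e-4, b = 9.125e-5, c = 26.929. A comparison mode scores |MFE|
through the legacy animal minimum-Gumbel CDFs instead
(known: location 32, scale 5.5; background: 23, 4.8), as
ln F_known(|mfe|) − ln F_bgr(|mfe|) computed in log space
(ln F = −e^{(x−loc)/scale}) so deep tails stay finite. The CDF-ratio
convention is this package's choice; the probability discretization of
the original animal model is not published in comparable detail.

### Stability (rel)

randfold-style test: the sequence is shuffled N times (default 999,
mononucleotide; dinucleotide Euler-path shuffling available), each
shuffle refolded, and p = R/(N+1) where R counts shuffles folding at
least as stably as the native sequence. Ties count toward R
(conservative, larger p). p is floored at 1/(N+1): a finite ensemble
cannot attest a smaller value. Stable iff p ≤ 0.05.

### Nucleus conservation (nuc)

Exact match of mature positions 2–12 (1-based, the plant nucleus;
animals use 2–8) against the same window of any known mature. A
mismatch allowance exists (`nucleus_mismatches`) but defaults to 0: the
window was chosen to maximize within-family match specificity, and
loosening it reintroduces false homologs. Matures shorter than the
window score 0 with a logged notice.

### Signature (sig)

Each aligned read (weighted by collapsed count) is consistent if its 5'
end lies within ±2 nt of the mature or star 5' end, or the read is
contained in the loop. With n total and k consistent read counts, the
real-model log-likelihood is ln p + (n−k)·ln(1−p) (inconsistent count
geometric, default p = 0.7) and the background model is binomial with
uniform start positions, k·ln u + (n−k)·ln(1−u), where u is the
fraction of the precursor covered by consistent windows. The component
is their difference. These internals (tolerance, p, likelihood forms)
are inherited plumbing, deliberately not presented as plant-estimated
values, and all configurable.

### Star and prior

Star presence/absence log-odds are not part of the plant-estimated
constants; defaults ±ln 4 ≈ ±1.386 encode a nominal P(star=1|pre)=0.8
vs P(star=1|bgr)=0.2 and are configuration. The prior log-ratio
defaults to 0 (uninformative).

## Candidate generation

Reads are filtered to ≤1 mapping mismatch, ≤20 genomic hits, and zero
overlap with CDS/ncRNA exclusion intervals. Survivors are
single-linkage clustered per reference and strand (gap ≤30 nt, a
package default — the clustering gap is not a published value). For
each cluster two windows are excised around the highest-count (putative
mature) read — mature assumed on the 5' arm (20-nt proximal flank,
remainder of the 300-nt cap distal) or mirrored for the 3' arm — and
the better-scoring window is reported. Windows are clipped at
chromosome ends; minus-strand windows are reverse-complemented before
folding. The flank split (20 nt) is likewise a package default, exposed
as configuration.

The excision cap defaults to 300 nt, the tabulated plant value; the
coverage analysis that motivates it reports optimal lengths 277 (or
276) and 336 covering 96%/98% of known plant precursors — the
discrepancy between those printed numbers is documented, not resolved,
and `select_excision_length` lets users re-derive the choice from any
length sample (smallest length reaching the coverage target with ≥30
precursors within ±30 nt, the ±30 window being a package choice).

The mature:star duplex is read off the pair table: the star arm is the
partner span of the mature extended by the canonical 2-nt Dicer 3'
overhang (configurable). Unpaired counts are mature positions without
partner; a bulge is an unpaired run on exactly one arm (internal loops
— unpaired on both arms — count as unpaired, not bulge, matching the
tabulated separation of the two statistics). Defaults: ≥15 paired, ≤5
unpaired, ≤3 consecutive unpaired, bulge total ≤2. The parameter table
and the duplex table disagree on the bulge cap (2 vs 1); the declared
parameter-table value 2 is the default. The bifurcation filter
(rejecting multi-helix top-level structures) defaults to off, trading a
little specificity for sensitivity. Candidates whose mature spans the
terminal loop yield no duplex and are dropped.

## Folding backends

`ReferenceFolder` is a deterministic dependency-free folder minimizing
a nearest-neighbor-lite energy: fixed pair energies (G:C −2.0, A:U
−1.0, G:U −0.5 kcal/mol), a stacking bonus graded by the G:C content of
the two stacked pairs (−1.0/−0.5/−0.25), a hairpin-loop penalty
3.0 + 0.2·(L−3), minimum loop 3 nt, no dangles, no multiloop penalty.
It does not reproduce Turner-model energies and is not meant to; the
scoring model consumes |MFE| only through a fitted score function, so
any consistent energy scale serves, and the folder is exact (verified
against exhaustive enumeration on short sequences) and fully
deterministic — ties are broken by the lexicographically smallest
dot-bracket string. The dynamic program is numba-accelerated when numba
is importable, with a pure-Python fallback. `ViennaRNAFolder` shells
out to a Vienna-compatible `RNAfold` for production runs; a missing
executable raises immediately, never silently falling back.

## Estimation procedures

* **Gumbel fit**: scipy's maximum-likelihood fit of the minimum-Gumbel
  (Gumbel-left) family; the published one-parameter form is treated as
  the location-0 special case of this two-parameter family, which the
  parameter table makes explicit. Fit quality is the summed absolute
  deviation from the empirical CDF.
* **Binned log-odds**: shared histograms of normalized MFE at bin width
  0.01; per-bin ln frequency ratio, defined only where both classes
  populate the bin.
* **Sigmoid fit**: f is identifiable but ill-conditioned when
  b ≪ e^{c·x} over all bins, so the solver multi-starts over
  c ∈ {5, 15, 30, 45, 60}, initializes (a, b) by linearizing
  1/y = b/a + e^{c·x}/a on positive bins, refines all three in log
  space (keeping a, b > 0) by least squares, and keeps the best
  residual sum of squares. No fitting protocol is published; this one
  is the package's.
* **Discrete frequencies**: feature frequencies clipped to
  [pseudo, 1−pseudo] with pseudo-count 1/3000 substituting empty cells.
* **Conservation profile**: within a family (aligned, ≥2 members) a
  position is conserved iff the modal non-gap residue reaches 0.9 of
  members (gaps count as mismatches; the within-family metric is
  otherwise unspecified in the source). Profiles count conserving
  families per position; across-family blocks use threshold 0.75.
  A light center-star aligner (match/mismatch/gap = +1/−1/−2) is
  provided for unaligned input as a convenience; it is deliberately not
  a progressive multiple aligner.
* **Nucleus CV**: one shuffle, ten disjoint test folds (9:1), per-fold
  frequency of test matures whose 2–12 window occurs in training, fold
  mean returned.
* **KS test**: exact sup of the ECDF difference over pooled sample
  points with the asymptotic Kolmogorov p-value.

## Synthetic data

The generator emulates the training/validation conditions at desk
scale: perfect (or controlled-mismatch) stem-loops planted on both
strands of a toy genome whose background is codon-triplet-sampled
(coding-like composition, echoing the use of protein-coding sequence as
the negative class); Dicer-like read stacks (collapsed mature read,
default count 50, a 1-nt-jittered minority read, a low-count star read,
a rare loop read); optional uniform noise reads; a CDS annotation over
decoy loci; and a known-mature library of families sharing an identical
2–12 nucleus. Defaults: 5 hairpins + 1 decoy, 30-bp stems, 8-nt loops,
10 families × 10 members, 100 background sequences of 60–300 nt, genome
10 kb. Identical specs (including seed) produce byte-identical files.

Planted duplex mismatches are a contiguous block opposite the mature
with both strands set to the same self-incompatible base; scattered
single substitutions proved rescuable by register-shifted re-pairing
with compensatory bulges, which would make the generator's
"mismatches ⇒ failing duplex" contract probabilistic rather than
structural.

What passing on synthetic data does not show: real genomes have
repetitive loci, expression noise, RNA editing, overlapping
transcription and imperfect annotations; the generator models none of
these, so end-to-end recovery here validates the machinery, not
field performance.

## Numerical and design choices

* Coordinates are 0-based half-open internally; SAM/GFF3 converted at
  the boundary. Internal alphabet is DNA (U→T on input); the folding
  backend converts to RNA space on its own boundary.
* The parameter set carries both known and background Gumbel pairs plus
  an `mfe_mode` switch — one pair alone cannot express the legacy
  comparison mode's log-odds.
* Energy-tie tolerance in the folder's traceback is 1e-6; candidate
  ranking ties break lexicographically on precursor id.
* Degenerate inputs: empty alignment files yield empty results with
  exit 0; clusters longer than the excision cap are skipped with a
  logged notice; constant samples are rejected by the Gumbel fit.
* The CLI accepts `--threads` for interface compatibility; the
  implementation is single-threaded, so thread-count independence of
  results holds trivially.
* Test problem sizes (the package's own choices): folding oracle
  cross-checks on 200 random sequences of ≤16 nt; shuffle-conservation
  on 100 random sequences of 20–200 nt; stability recounts at N = 99 on
  ~60-nt hairpins; Gumbel recovery at n = 10,000; end-to-end runs on
  the 5-hairpin default dataset with full 999-shuffle stability.

## Known limitations

* The shipped sigmoid constants are the published plant fits;
  re-deriving them exactly would require the original miRBase
  release-14 precursor sets and five plant genomes, which are not
  bundled. `estimate` re-derives all constants from user data instead.
* Multi-functional stem-loops (several matures per hairpin) and
  riboendonuclease-specific product-size modeling are out of scope.
* The reference folder's energies are on an arbitrary consistent scale;
  score magnitudes from the two backends are not interchangeable —
  sigmoid constants fitted on RNAfold energies should be used with the
  external backend.
* mature reads overlapping a real precursor's loop boundary, or loci
  whose true precursor exceeds the excision cap, are not recoverable by
  construction.
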
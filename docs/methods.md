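# Methods

## Clonotypes and preprocessing

A clonotype is defined by the key (V segment, D segment, J segment, CDR3
nucleotide sequence). Segment names are normalised to gene level before
any comparison: surrounding whitespace and IMGT allele suffixes (`*01`)
are stripped, and missing-value tokens (`.`, empty, `NA`) map to a single
canonical token, so `TRBV20-1*01` and `TRBV20-1` collapse together. Rows
sharing a key are merged by summing counts; frequencies are recomputed as
count over total count. If two rows share a CDR3 nucleotide sequence but
disagree on its amino-acid translation, that is corrupt input and raises
a data-integrity error rather than being silently resolved.

Merged output is ordered by descending count with lexicographic
tie-breaks (CDR3nt, then V), making every downstream table
byte-reproducible. Non-functional clonotypes are those whose CDR3
amino-acid sequence contains a stop (`*`) or frameshift (`_`) marker —
the MIXCR-style convention; the marker set is configurable. Filtering
renormalises the surviving frequencies and logs the tally.

CDR3 translation is codon-wise under the standard genetic code (via
Biopython's codon table); stop codons render as `*` and a trailing
partial codon as `_`.

## Descriptors

All descriptors support two weightings: *diversity* (each unique
clonotype counts once — the default, appropriate when clonal expansion is
uninformative for the contrast of interest) and *counts* (clonotypes
weighted by molecule count).

**Residue occurrence** is a containment metric: the weight percentage of
clonotypes containing at least one copy of a residue anywhere in the
CDR3, anchors included. Values for different residues do not sum to 100;
C and F sit at 100 in anchor-conserved repertoires. A per-position
frequency metric would cap single-residue values near 100/length and
could not produce the high per-residue percentages this containment view
yields; containment is also the natural reading of "how often does a
repertoire's receptor carry this residue at all".

**Positional occurrence** reports the same quantity per 1-based position
from the N-terminal conserved C. The default denominator is the whole
repertoire, so clonotypes shorter than the queried position count as
non-occurrence; this keeps profiles comparable between repertoires with
different length distributions and gives the exact identity
Σ_X occ(p, X) = percentage of clonotypes of length ≥ p. A conditional
denominator (clonotypes of length ≥ p only) is available behind a flag.
Positions are always counted N→C; for α-chains with variable lengths a
C-terminal anchoring could be argued, and can be obtained by reversing
sequences before profiling, but is not the default.

**Segment usage** percentages are computed at gene level and sum to 100
per segment class. **CDR3 length distributions** likewise sum to 100.

Non-standard letters that survive filtering (which should not happen with
well-formed input) are tallied under a reserved `other` bin and logged,
never dropped.

**Percent change** of a case mean m₁ over a control mean m₀ is
100·(m₁−m₀)/m₀. With m₀ = 0 and m₁ > 0 the quantity is reported as an
explicit undefined flag (`None` in the API, empty field in reports)
rather than infinity; 0/0 is reported as 0.

## Group statistics

Per-feature comparisons use two-sample t-tests, pooled-variance by
default (the common default of spreadsheet-style "multiple t-test"
analyses); Welch is available behind a flag. The correction family is the
descriptor's full natural feature set — all 20 residues, all positions of
the queried residue, or all observed segments — and adjustment is
step-down Holm–Šídák: with sorted raw p-values p(1) ≤ … ≤ p(m),

    adj(i) = max_{j ≤ i} min(1, 1 − (1 − p(j))^(m − j + 1)),

returned in input order. This is never below the raw value and never
above Bonferroni. Features with zero variance in both arms and equal
means receive p = 1 (logged) so families keep their size; zero variance
with different means yields p = 0. Analyses require at least two donors
per arm; repertoires below a configurable minimum clonotype count
(default 50) are excluded and logged. The default significance threshold
is 0.05 with stars at 0.05/0.01 in reports.

The two-way ANOVA fits an ordinary least-squares model with interaction
(type-II sums of squares, identical to the classical decomposition on
balanced layouts) for per-donor single-feature values on two crossed
factors; the default pairing is condition × chain, which is an assumption
— condition × subset is equally valid and available by relabelling. With
one replicate per cell the interaction is dropped (additive model, with a
warning); an empty cell is a design error.

## Synthetic cohorts

The generator emulates the structure the analysis relies on, not human
germline biology. Each repertoire draws, per rearrangement:

- a V and a J segment from synthetic pools (15 V, 10 J; IMGT-style names;
  Zipf-like base weights w ∝ 1/rank). Each V contributes a fixed in-frame
  5′ flank translating to C⋯ and each J a 3′ flank translating to ⋯F, so
  every functional CDR3 is anchor-conserved by construction. Flank
  peptides deliberately contain no K or W, so lysine/tryptophan content
  is governed by the junction alone and injected K/W effects stay
  separable from segment usage;
- a junctional insertion of k sense codons, k geometric with mean 2
  (mean 6 nt — a typical junction scale); drawing whole sense codons
  keeps functional rearrangements in-frame and stop-free by construction;
- a clone size from a discrete power law with exponent 2.5 (capped at
  10⁴), independent of sequence content;
- for TRB, a D label (TRBD1/TRBD2, uniform); for TRA the missing token.

A configured fraction of rearrangements (default 8%, a plausible scale
for non-productive rearrangements in bulk RNA-based data) is disrupted
explicitly: half receive a random interior stop codon, half a
single-nucleotide deletion (frameshift), so the functional/non-functional
split is exact rather than emergent.

Donor individuality: per-donor segment weights are drawn from
Dirichlet(c·w) with concentration c = 50, giving a between-donor standard
deviation of roughly √(w(1−w)/51) — about 3–4 percentage points for a
segment used at 8% — which reproduces "considerable" inter-donor usage
variability while keeping arm means stable. Every (donor, condition)
repertoire derives its own random stream from the root seed by stable
hashing, so adding donors to a cohort never changes existing donors'
draws, and identical configuration + seed reproduces cohorts byte for
byte.

### Injected effects

Case-arm effects are specified in percentage points of diversity-weighted
occurrence: containment of a residue, a residue at one CDR3 position, or
usage of one segment. Effects are applied *after* collapsing, on the
unique-clonotype set the descriptors actually measure, by substituting
the target (a synonymous codon for the residue, or the target segment's
flank) into a Bernoulli-thinned subset of eligible functional clonotypes.
Substituted sequences can collide with clonotypes that already exist;
re-collapsing absorbs those, so calibration iterates (up to 8 rounds,
convergence tolerance 0.05 points) until the realized occurrence equals
the repertoire's own pre-enrichment baseline plus the requested effect.
Positional substitution is restricted to strictly interior positions
(2 … length−1), preserving both anchors; requesting an effect that would
push occurrence past 100%, or for which too few substitutable clonotypes
exist, is a configuration error.

### What the generator does not capture

- No real germline sequences, allelic variation, nibbling/trimming
  asymmetries, or thymic selection; CDR3 length and usage distributions
  are realistic in shape, not in detail. No α/β pairing.
- Collapsing identical rearrangements (the synthetic analogue of
  convergent recombination) concentrates counts on short-junction
  clonotypes, so collapsed counts are *not* independent of CDR3 content
  even though the clone-size draws are; count-weighted profiles therefore
  differ from diversity-weighted ones in a structural way, as they do in
  real repertoires with public clonotypes. The sharp independence
  property holds at the rearrangement level and is tested there (the
  generator exposes an uncollapsed diagnostic view).
- Passing tests on synthetic cohorts demonstrates correctness of the
  computations and calibration of the statistics under a known generative
  law — not that any particular biological effect exists; real-data
  conclusions still require the real tables.

## Validation scale

The standard validation cohort is 5 case + 5 control donors with 2,000
rearrangements per repertoire — the scale of a small sorted-cell
sequencing study. Power is assessed over 100 seeded cohorts per injected
effect (top-ranked family feature at adjusted p < 0.05), type-I error
over 200 no-effect cohorts per family, and realized effect sizes at
50,000 rearrangements where Monte-Carlo error is a fraction of a point.
Brute-force oracle comparisons run on 200 randomized repertoires of at
most 50 clonotypes, where literal loops are fast and unambiguous.

## Known limitations

- The t-test assumes approximate normality of per-donor percentages;
  with 3–5 donors per arm this is a pragmatic choice, not a guarantee,
  and rank-based alternatives are deliberately out of scope.
- Šidák-style correction is exact under independence and conservative
  under positive dependence; for strongly negatively dependent families
  (compositional segment usage) it can be marginally anticonservative.
  Measured family-wise error on null cohorts stays within the nominal
  band.
- Percent change is undefined for features absent from controls; reports
  flag rather than impute these.
- The pipeline compares one (subset, chain) stratum at a time and
  requires explicit sample metadata via the manifest; nothing is inferred
  from file names.
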
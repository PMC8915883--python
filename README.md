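# tcrprof

Case/control comparison of bulk T-cell receptor (TCR) repertoires at the
CDR3 level, plus a seedable synthetic V(D)J cohort generator so every
stage of the analysis can be validated without sequencing data.

## The problem

Antigen-specific T cells sorted from blood (e.g. by activation-induced
markers after stimulation with a chemical sensitizer) can be profiled by
bulk TCR sequencing and compared against randomly sorted cells from the
same donors. The scientific questions are compositional: does the
antigen-specific repertoire use particular V/J gene segments more often,
and are particular amino acids over-represented in the CDR3 — overall, or
at specific positions? `tcrprof` implements that comparison for clonotype
tables as produced by the standard MIGEC/MIXCR/VDJtools processing chain.

A *clonotype* is the unit of diversity: all molecules with identical V,
(D), J segments and CDR3 nucleotide sequence. After collapsing to
clonotypes and removing non-functional rearrangements (CDR3 with a stop
`*` or frameshift `_`), the package computes, per sample:

- **residue occurrence** — the percentage of clonotypes whose CDR3
  (conserved C and F anchors included) contains a residue at least once:
  occ(X) = 100 · Σᵢ wᵢ·1[X ∈ CDR3ᵢ] / Σᵢ wᵢ, with wᵢ = 1 per clonotype
  ("diversity" weighting, the default) or the clonotype's molecule count;
- **positional occurrence** — occ(p, X) for the residue at 1-based CDR3
  position p, counted from the conserved C;
- **V/J segment usage** and the **CDR3 length distribution**.

Case/control arms of a donor cohort are compared feature-by-feature with
two-sample t-tests (pooled variance by default) and step-down Holm–Šídák
correction over the family (20 residues; all positions of a queried
residue; all observed segments), reporting means, percentage-point
differences, percent change of the case mean over the control mean, and
raw/adjusted p-values. A classical two-way ANOVA is available for
per-donor single-feature values on crossed factors (e.g. condition ×
chain).

The synthetic generator builds CDR3s at the nucleotide level (germline V
flank + random junctional codons + germline J flank), injects a
configurable non-functional fraction, draws power-law clone sizes, jitters
per-donor segment usage, and can plant known case-arm effects
(containment, positional, or segment-usage shifts in percentage points) —
which makes power and type-I error of the whole pipeline measurable.

## Worked example

```sh
tcrprof simulate --outdir results/cohort --seed 1      # or analysis/01_simulate_cohort.py
python analysis/03_group_comparison.py
```

On the default cohort (5 case + 5 control donors, 2,000 rearrangements
each, with +15 points of tryptophan at CDR3 position 5, +15 points of
lysine containment and +5 points of TRBV4 usage injected into the case
arm) this prints:

```
comparison_CD4_TRB_aa_occurrence.tsv: 2 significant feature(s)
  K: case 22.55% vs control 8.05% (adj. p 1.3e-08) **
  W: case 18.89% vs control 4.65% (adj. p 1.3e-08) **

comparison_CD4_TRB_positional.tsv: 1 significant feature(s)
  (5, 'W'): case 16.53% vs control 1.51% (adj. p 1.7e-10) **

comparison_CD4_TRB_segment_usage.tsv: 0 significant feature(s)
```

Both planted residue effects are recovered as the only significant
features of their families, and the positional family localises the
tryptophan signal to position 5. The small V-segment shift is not
significant in this single cohort: a +5-point usage change competes with
donor-to-donor usage variability of similar size, which is exactly the
regime where such segment effects are hard to call — across 20 cohorts
the target segment averages 12.7% in the case arm vs 7.7% in controls
(+64% change) but crosses adjusted p < 0.05 in only ~10% of them.

Real data are consumed the same way: write a YAML manifest listing one
clonotype table per sample (`path`, `donor_id`, `subset` CD4/CD8, `chain`
TRA/TRB, `condition` case/control) and run
`tcrprof compare --manifest manifest.yaml --outdir results/`. Both the
VDJtools-style column set (`count freq cdr3nt cdr3aa v d j`) and raw
MIXCR export columns are understood.

## Layout

- `src/tcrprof/` — the library: `io` (tables, collapsing, filtering),
  `simulate` (cohort generator), `composition` (descriptors), `stats`
  (t-tests, Holm–Šídák, ANOVA), `pipeline` + `cli` (orchestration),
  `experiments` (cohort-level power/error studies).
- `analysis/` — numbered drivers reproducing the narrative:
  simulate → profiles → comparisons → calibration, writing `results/`.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
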
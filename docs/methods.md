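# Methods

This note records the models, numerical choices and limitations behind the
package, stage by stage.

## Identification

**Tiered validation.** Per engine, a protein is accepted when it has ≥ 2
*unique* peptides (peptides whose PSMs name exactly one protein) scoring above
`T1`, or any single peptide above `T2`; peptides above `T3` are then attached
to accepted proteins. The published tier values are Mascot `T1/T2/T3 =
16/40/10` and Phenyx `5.5/9.5/3.5`; engine scores are never compared across
engines (the scales differ roughly threefold). All three tiers are applied as
strict inequalities by default — the `T3` tier is explicitly strict in the
source procedure and we apply the same reading uniformly; `strict=False`
switches every tier to `≥` for sensitivity analyses.

**Conflicts, grouping, reporters.** A spectrum assigned different peptide
sequences by the two engines is evidence of at least one wrong match and is
removed from *both* engines. Accepted proteins are grouped into connected
components of the peptide-sharing graph (union-find; verified in tests against
a brute-force graph-components oracle). The group reporter is the
lexicographically smallest accession among members with the most
group-internal unique peptides, which makes output deterministic. After
grouping, a group's `unique_peptides` are the peptides appearing in no other
group — the quantitative basis for TMT ratios. Keratin groups are dropped only
when their description is a keratin *and* mentions "hair" or "cuticular"
(cytoskeletal keratins mark mesothelial cells and are retained); isoform
groups (`accession-N`) are merged and uniqueness recomputed.

**Mass recalibration.** A single-pass correction: the median ppm offset of
high-confidence PSMs (measured versus theoretical precursor m/z supplied in
the PSM table) is removed from every precursor. Theoretical masses are inputs,
keeping sequence chemistry out of scope. The original two-pass broad/narrow
search belongs to the acquisition side and is reduced to this one step.

**Decoy FDR.** The identical validation run on reversed-database PSMs yields
`peptide_fdr = n_decoy_peptides / n_target_peptides` and likewise for groups.
Two semantics deserve note. First, with the `T3` tier an incorrect peptide can
be "rescued" onto a correctly identified protein; no decoy protein is ever
validated, so reversed-database counting structurally cannot estimate such
peptides — they are accepted by design of the tier, not controlled by the FDR.
The ground-truth false proportion that the decoy estimate is compared against
in tests is therefore defined at the level the strategy actually estimates:
protein groups containing no truly present peptide, and the peptides of such
groups. Second, reversed-database counting is mildly conservative: a random
match onto a *present* protein is absorbed into a true group, while its
reversed counterpart still counts as a decoy. Tests characterise this
directly: at the default score separation the estimate agrees with truth
within 3 binomial standard errors (both are far below the 0.1 % / 1 %
headline levels), and under deliberately poor separation the estimate never
understates the realised error and agrees within 10 % relative.

## Modified Top3 abundance

`A_0f` is the trapezoidal area under the chromatogram between the earliest
(`T_0`) and latest (`T_f`) PSM retention times. `A_S` emulates local peak
integration: from the grid point nearest each PSM we hill-climb to the peak
apex, take the PSM whose apex is highest, and expand to the nearest local
minima below 5 % of that apex (configurable `frac_of_apex`); the area over
that region is `A_S`. A peptide with ≥ 2 PSMs takes `max(A_S, A_0f)`, a
single-PSM peptide keeps `A_S` (and `A_0f` is reported as NaN). The max rule
guarantees `area ≥ A_S`, and all areas are linear in trace intensity, so Top3
is scaling-equivariant. Top3 itself is the mean of the up-to-three largest
resolved areas; proteins with one or two peptides use the mean of what is
available. By default all validated peptides of a group are used
(`top3_unique_only` restricts to unique peptides); which variant the original
workflow used is not documented, so both are exposed.

## TMT quantitation and the paired test

Reporter ions are summed within ±0.005 m/z of the six 6-plex reporter masses
(windows may not overlap; a peak 0.006 away contributes nothing). Impurity
correction solves `M·x = v` for the label-sheet mixing matrix `M`
(column-stochastic, diagonally dominant); negative solutions are clipped to
zero and counted. Channel totals within a run are rescaled to their common
mean, which is idempotent and equalises totals to machine precision.

Per patient, a protein's log2 ratio is the ratio of summed unique-peptide
reporter intensities (treated over control channel, both in the patient's
run); the per-spectrum ionisation efficiency is common to both channels and
cancels. A `median` per-spectrum-ratio estimator is available. The original
workflow used a published heteroscedastic noise model for ratio estimation;
that model is outside this package's scope and is replaced by this documented
simpler estimator — the per-patient t-test downstream is implemented exactly.

**Differential test.** Per protein with ≥ 3 patient ratios (up to the 20
patients of the design), a one-sample t-statistic of the log2 ratios against
0; the reported p-value is one-sided in the direction of the sample mean
(half the two-sided p). Because that direction is chosen from the data,
flagging at the nominal α would realise a type-I rate of ~2α; the default
significance flag therefore requires the directional p < α/2 (equivalently
two-sided p < α), which calibrates the null significant fraction to α — the
test suite verifies 3–7 % at α = 0.05 on all-null data. `calibrated=False`
applies the literal one-sided threshold for comparison. The phrase "ratios
different from 1" is read as log ratios tested against 0; testing log ratios
against 1 would bias every protein. Candidate selection applies no
multiple-testing correction (deliberate extremes-of-phenotype choice of the
original design); a Bonferroni flag exists in the enrichment stage for the
secondary criterion. Degenerate inputs: zero-variance ratio sets give p = 0.5
when the mean is 0 and p = 0 otherwise; proteins below `min_ratios` are
reported untested with NaN p. The "stably abundant" subset keeps proteins
with ratios in ≥ 17 of 20 patients.

## Plasma comparison

Effluent proteins are mapped by accession onto a consensus plasma
concentration table; the correlation is Pearson's r on log10 values over the
shared set. Over/underrepresentation is measured on *relative* ranks
(average-tie rank divided by list length, each list ranked in full) because
the two lists have different lengths; the raw-rank mode is available. The
`n_each` most extreme proteins per direction are selected with lexicographic
tie-breaking, making the selection deterministic, antisymmetric under
swapping the two lists, and invariant to monotone transforms of either
abundance scale. Proteins absent from the reference have no plasma rank and
are reported separately rather than forced into the comparison.

## Enrichment

Annotations follow the true-path rule: memberships are propagated to all DAG
ancestors at load, so a parent's count is at least each child's. For a sample
of size `n` from a universe of size `N`, a term with `K` members has
`expected = K·n/N`, `fold = observed/expected`, and a one-tailed Fisher exact
p-value `P(X ≥ observed)` from the hypergeometric distribution (verified
against brute-force tail enumeration). The Bonferroni multiplier is the
number of terms actually tested (those with ≥ `min_observed` sample members,
default 1), not the whole ontology — this affects only corrected p-values,
never expected/fold. "Most specific" significant terms are those with no
significant descendant in the DAG. The reference size `N` may exceed the
number of annotated proteins (a genome-wide universe), which is why it is a
separate parameter.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical* structure the analysis assumes,
at desk scale (defaults: 600 proteins, 20 patients, 7 runs, 4000 spectra per
engine — chosen so the full test suite and acceptance script run in minutes):

* **Abundances** are log-normal (log10 sd 0.8 — a plasma-like spread already
  compressed by the bead equalisation step); the plasma subset sits one
  decade higher with overlap. Plasma concentrations correlate with log
  abundance at a configurable ρ (default 0.6), standardised within the plasma
  subset, where concentrations are defined. The observed correlation in the
  original study is an *output* of that analysis, not a generator input, so
  it is exposed as a knob rather than hard-coded.
* **PSMs**: correct matches draw peptides with abundance-weighted
  probability (so abundant peptides accumulate multiple PSMs, which the Top3
  `A_0f` rule needs); scores are engine-specific normals (target means well
  above `T1`, decoy means well below). Random matches are database lookups,
  blind to abundance: a protein slot is drawn uniformly from a database 15×
  larger than the present proteome (sequence collections dwarf any one
  sample's detectable proteins), identically for the target and reversed
  halves — this symmetry is what makes decoy counting track the true false
  proportion. Decoy peptides are reversed target sequences. Exactly the
  configured fraction of proteins receives a ±`effect_size` log2 treatment
  effect.
* **XICs** are sums of Gaussian peaks (σ = 0.08 min) at PSM retention times
  on a uniform 0.01-min grid, with areas proportional to true abundance.
* **Reporter tables** follow the cross-over design (three patients × two
  treatments per run; the final run carries two QC replicate channels
  re-measuring an earlier patient). Channel intensity is
  `abundance × 2^effect × lognormal(cv)` times a per-spectrum ionisation
  factor; an impurity matrix can be mixed in for round-trip testing.
* **Annotation DAGs** are three-level (root / mid / leaf) with random leaf
  memberships and an optional spiked term whose members can be oversampled
  into a candidate list.

Not emulated: fragment spectra and search-engine scoring themselves, digestion
chemistry, chromatographic drift and co-elution interference, missing-value
structure driven by precursor selection, between-patient (unpaired)
comparisons (these need internal standards and larger cohorts), and the
dataset-dependent counts of any real study. Passing tests therefore certify
the *procedures* — tier logic, grouping, estimator calibration, arithmetic —
under the stated noise model, not performance on real effluent data.

## Pipeline

Stages exchange flat TSV/JSON so each is runnable in isolation; a run
directory contains every stage output, the echoed configuration, realised
stage seeds, per-gate counts and SHA-256 checksums. Reruns with the same
configuration and seed are byte-identical. Stage seeds are derived from the
master seed via a seed sequence (kept below 2^31).
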
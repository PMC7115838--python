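# Methods

## Scope and model

`sompkit` curates a biomineral proteome from four kinds of post-search
evidence: a long-format peptide-evidence table (one row per identified
peptide per purification-method × solubility fraction), target-vs-contaminant
alignment statistics in BLAST tabular form, per-protein annotation flags
from external predictors (SignalP-style signal peptides, TMHMM-style
transmembrane spans, PredGPI-style GPI anchors, gene-model N-terminus
completeness, GO terms), and ortholog-pair tables against previously
published skeletal proteomes. It computes none of these upstream quantities:
FDR control belongs to the search engine, alignment statistics to BLAST,
secretion features to their predictors. What it owns is the curation logic —
acceptance, screening, set algebra, classification, overlap and enrichment —
and the bookkeeping that makes a curation auditable and repeatable.

## Stage order and determinism

`run_curation` applies the contaminant screen before the evidence filter.
Both are per-protein predicates on disjoint inputs, so the two filters
commute (a test asserts this on a full bundle); the chosen order simply
mirrors the curation narrative: discard what is not coral, then ask what is
well supported. All outputs are written in a single phase after every stage
has succeeded, so a failing stage never leaves partial outputs. The pipeline
proper contains no randomness; every output row order is a pure function of
content (ascending accession), making re-runs byte-identical.

## Evidence filter

Acceptance is evaluated within one (method, solubility) cell: ≥ 2 *distinct
significant peptide sequences*, or ≥ 1 significant peptide with ≥ 10 spectra
and score ≥ 250. Two readings were genuinely open:

* "two peptides" counts distinct peptide sequences, not spectra — the
  standard proteomics distinction, and the rule's second branch explicitly
  switches to spectra when support is meant;
* the 10-spectra criterion is kept within-fraction rather than summed across
  fractions, because presence itself is reported per fraction; the run
  report records the thresholds in force.

The score threshold applies to the score column of the evidence table; users
with protein-level scores replicate the value across that protein's rows.
`best_score` is the maximum score over a protein's *accepted* cells only, so
a rejected cell can never contribute the headline score. Monotonicity
(raising spectra or score, or making a peptide significant, can never revoke
acceptance) is enforced by property tests against a brute-force restatement
of the rule.

## Contaminant screen

Candidate flagging uses three strict-inequality branches over per-hit
statistics: (e < 1e−50 ∧ similarity > 50), e < 1e−100, similarity > 80. The
"percent similarity" is taken from the BLAST positives column (`ppos`,
13-column dialect) when present, else percent identity as a conservative
proxy; the run report names the source. Each branch is per-hit: a
"mean similarity" averaged over HSPs would require the underlying
alignments, which the tabular contract does not carry.

Removal additionally requires ≥ 3 distinct shared peptides of ≥ 7 residues,
identical between the target and **one single** contaminant entry (no
pooling across subjects — the decision models a pairwise alignment
inspection). Matching is exact substring matching on uppercase sequence with
I and L distinct, because the criterion is *identity*, not isobaric
indistinguishability. Shared peptides default to the MS-observed identified
peptides — the entities the pipeline actually has; a fallback derives
fully-tryptic in-silico peptides (cleave after K/R except before P, zero
missed cleavages, via pyteomics) when observed peptides are unavailable.
Both modes are exposed and logged. The triggering hit is the satisfying hit
with the smallest e-value, ties broken by higher similarity then
lexicographic subject accession, so verdicts are order-independent.

## Fraction set analysis

The detection matrix (proteins × 8 cells) feeds all set summaries. "Detected
by a method" pools both solubility fractions of that method; the two
protocol families are pooled as CF = {CF2, CF4} and ACT = {ACT1, ACT3}.
Venn-region counts for up to four named sets are computed by explicit
membership-pattern partitioning and verified against brute-force enumeration.
Percentages are reported to one decimal place with half-up rounding
(`Decimal`), matching how such proportions are conventionally printed;
inclusion–exclusion holds on every report by construction and by test.

## Export and functional classification

A signal peptide counts (`has_sp`) only on proteins whose gene model has a
complete N-terminus — an SP call on a truncated model is an artifact of the
prediction, so the raw SP flag is reported separately but does not count as
export evidence. `ecm_evidence = has_sp ∨ has_tm ∨ has_gpi`; its complement
marks non-classical-secretion candidates, giving a strict partition of the
proteome.

No published rule list maps GO terms to the five functional groups
(membrane processing; ECM/transmembrane; metal binding; vesicular/secretion;
protein modification), so the package ships an explicit, editable default
map (`data/default_category_map.yaml`): exact GO-identifier rules plus a few
case-insensitive keyword patterns over the protein description. Every report
stamps the SHA-256 of the map in force, so any two runs are comparable only
when their hashes agree. Multi-assignment is deliberate — a calcium-binding
vesicle protein belongs in two groups — but a protein increments each
category at most once.

## Orthology overlap and enrichment

Set membership pools every ortholog-relation multiplicity (1:1, 1:many,
many:many, best BLASTP hit); multiplicity is preserved in the output for
audit but never weights the sets. The enrichment question — is k of n
curated proteins with known skeletal orthologs more than chance? — is
answered with the exact binomial upper tail when the background is a
proportion (default p = 0.002, i.e. skeletal matrix proteins are ~0.2% of a
reference proteome) and the exact hypergeometric tail when it is counts
(K, N). Both tails are evaluated through scipy's exact distribution
functions and validated against an arbitrary-precision `fractions.Fraction`
summation oracle for all n ≤ 100; the two forms agree to < 1e−6 once
N ≥ 10⁴·n.

## Synthetic data

The generator emulates the statistical structure of the inputs, not the
physics of mass spectrometry (no spectra, masses or retention times).
Sequences are i.i.d. over the 20 standard residues with lysine and arginine
at double weight, so tryptic peptides of plantable length (≥ 7–9 residues)
are abundant. Contaminant entries are built by embedding the planned number
of tryptic peptides copied from their paired target inside random
background, which makes the shared-peptide count true by construction.
Planted populations sit strictly inside or outside every threshold:
accepted proteins carry two distinct significant peptides per planted cell
(one with ≥ 10 spectra and score in [260, 750]); sub-threshold plants rotate
through three strictly-failing patterns (9 spectra / high score; ≥ 10 spectra
/ score 249; non-significant only); contaminant alignments are planted at
e = 1e−110, similarity 85%, and clean-protein decoy hits at e ∈ [1e−35, 1e−3],
similarity ≤ 45%. Default sizes (12 skeletal, 3 contaminant-like, 5
sub-threshold, mean length 300) keep unit fixtures fast; default per-cell
detection probabilities are insoluble-heavy and CF-heavy, mirroring the
study system's outcome.

`headline_bundle` plants the published headline structure exactly —
60 curated; CF 52 / ACT 13 with 5 shared (down to the per-protocol
exclusives); ISOM 57 / SSOM 8 with 5 in both; 17 SP-on-complete-N-terminus /
8 TM / 10 GPI / 25 with ECM evidence; the five GO groups at 10/19/25/21/12
over 39 annotated; 16 proteins with orthologs, 7 in all three reference
proteomes — so the full pipeline recomputes every printed summary from raw
synthetic inputs. A protein's planted cells are the product of its method
set and solubility set, the simplest joint layout consistent with all
marginal counts. Because the plants are margin-strict, passing tests show
the *rules* are implemented exactly; they do not show robustness to
borderline real data (score ties at 250.0, e-value ties at 1e−50), which the
strict/non-strict conventions above define deterministically.

Identical config and seed give byte-identical bundles (integer-seeded numpy
generator, content-sorted writers); the ground-truth manifest is emitted
next to the data.

## Published reference tables

`sompkit.datasets` packages the published curated-proteome table (60
proteins with annotation, best score and per-solubility detection marks as
printed) and the ortholog-pair table (16 mapped proteins, 7 shared with all
three reference proteomes). The printed per-solubility marks tally to
SSOM 7 / ISOM 59 / both 6, which differs from the prose totals 8 / 57 / 5
derived from the study's supplementary per-fraction table; the package
reports whichever input it is given and never reconciles the two silently —
the prose totals are exercised on the headline-structure synthetic bundle
instead.

## Degenerate inputs and numerical conventions

Empty FASTA or evidence tables curate to an empty proteome with zero totals
and a warning, not an error. An e-value of 0.0 is the strongest possible hit
and satisfies every `<` threshold. Percentages over an empty denominator are
0.0. Venn summaries accept 1–4 sets (region enumeration is exponential in
the set count; published comparisons use at most 4). All JSON output is
sorted-key, newline-terminated, for stable diffs.

## Limitations

The pipeline trusts the search engine's protein assignments (no grouping or
parsimony inference), consumes but never recomputes FDR, alignments or
secretion predictions, and ships a GO-category map that is a documented
default, not a community standard — results grouped by category are only
comparable across runs with the same map hash. The synthetic generator makes
no attempt at realistic spectral counts, peptide detectability or homology
structure beyond the planted overlaps.
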
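# Methods

## Model and assumptions

The pipeline treats a milk proteomics dataset as a *set* of detected
proteins, keyed by gene symbol. This all-or-nothing abstraction discards
abundance deliberately: published identification lists come from
heterogeneous instruments, labelling schemes and search pipelines, and
presence/absence is the only layer at which they can be pooled without
statistical modelling of between-study effects. The price is a strong
detection assumption — absence of a protein from a dataset may mean
absence from the sample, concentration below the detection limit, or an
identification failure. Exclusivity findings are therefore screening
hypotheses, not quantitative results.

Three structural rules define the analysis:

1. **Within-dataset deduplication.** A gene symbol reported several
   times in one dataset (isoforms, fragment entries, redundant
   accessions) contributes one presence pair. The atlas invariant is
   `n_presence_pairs = Σ_datasets |gene_names|`.
2. **Category union.** A category's protein set is the union over its
   datasets; a protein seen once in any dataset of the category counts.
3. **Exclusivity by exact membership signature.** The union sets over a
   dimension (milk fraction or lactation stage) are decomposed into all
   2^k − 1 Venn regions; a protein is *exclusive* to a category when its
   signature is that singleton. Regions are pairwise disjoint and
   rebuild every category set — this disjoint-cover invariant is
   revalidated on every decomposition.

## Identifier harmonization

Raw identifiers are normalized (trim, collapse internal whitespace,
uppercase) and isoform suffixes on accession-shaped tokens ("P62803-2")
are stripped before lookup, collapsing isoforms onto their parent entry.
Multi-mapped identifiers are resolved by a configurable policy —
`first` (default; one symbol per protein entry, mirroring how ID-mapping
services report a primary gene name), `all`, or `drop_ambiguous`.
Unmapped identifiers are excluded from the atlas but counted in
per-dataset provenance; an audit flag retains them under a reserved
`UNMAPPED:` prefix instead.

## Classification rules

Lactation stage is a function of days in milk (DIM), with inclusive
integer intervals that tile the axis: colostrum 0–5, early 6–21, peak
22–80, mid ≥ 81; any post-cessation sampling day maps to drying-off.
Two boundary choices were genuinely open and are fixed as: DIM 81 →
mid (so early/peak/mid tile the integers without a gap at 81), and
exactly 100 000 × g → whey (reading "over" as ≥ keeps the g-force rule
total). The `StageRuleSet` constructor rejects any override that breaks
the tiling, so classification is total and single-valued by
construction. Fraction precedence is sucrose gradient → cream
separation → g-force test, because exosome protocols also centrifuge
skimmed milk; acidification and major-protein depletion flags never
change the class.

The bundled 35-dataset manifest encodes each dataset's printed
descriptors in machine-readable form. Where a source row gives no
numeric DIM (e.g. a breed-comparison dataset described only as early
lactation), a representative DIM inside the printed stage interval was
curated (14 for early, 60 for peak, 120 for mid); skimmed-milk rows
carry max_g = 3000 and whey rows 100 000 (150 000 for
ultracentrifugation). The curated class columns stay in the fixture and
the classifier must reproduce them for all 35 rows.

## Over-representation testing

The hypergeometric upper tail is summed exactly in log space
(log-gamma binomial coefficients, log-sum-exp), with the summation
clipped to the support `[max(x, n−(N−K)), min(n, K)]`. Benjamini–
Hochberg adjustment is the standard step-up: sort, multiply by m/rank,
take the running minimum from the largest rank, cap at 1, restore input
order. Note that BH is not idempotent — re-adjusting an adjusted vector
multiplies by m/rank again; only fully-collapsed (tied) outputs are
fixed points — so the tests assert the procedure's actual properties
(adjusted ≥ raw, permutation equivariance, monotonicity in the sorted
order) and cross-check against independent implementations.

Configuration the upstream literature leaves unstated is explicit here:
the background universe is the atlas genes carrying at least one
annotation in the tested namespace (logged per run); BH families are
per-namespace by default with a flag for a single global family; the
evidence-code whitelist defaults to all codes; annotations are used as
given, with no GO-DAG ancestor propagation. Reported terms are those
with p_adj < α (default 0.05), truncated to the top k (default 50)
with the deterministic tie-break (p_adj, p_raw, term_id).

Exact enriched-term counts from any particular GO release are not a
target: they depend on the annotation snapshot, which is an input.

## Candidate evidence and shortlisting

The last two screening steps — comparison against tissue proteomes and
manual literature/pathway mining — are represented as declarative
inputs, because the web sessions behind them are not reproducible while
their per-protein outcome is. The bundled evidence table records, for
each of the 59 early-lactation candidates, curated pathway flags,
tissue hits and a literature-support boolean; the default criteria
shortlist a candidate carrying (an energy-metabolism flag OR the
proliferation flag) AND literature support. Respiratory-chain and
ribosomal subunits whose signal is redundant with a sibling complex
member carry their pathway flag but no literature-support mark, which
is what keeps the shortlist at six. The criteria are configurable and
monotone: adding a flag never removes a gene. The shipped tissue lists
are an explicitly synthetic stand-in (only the six shortlisted
proteins' memberships are curated); real liver/adipose/mammary lists
must be transcribed from their sources by the user.

## Synthetic compendia

The generator emulates the structure the analysis assumes, with
defaults sized like a modest meta-analysis: a universe of 300 proteins;
five stage categories × 3 datasets; a 20-protein ubiquitous core
(the analogue of the major caseins and whey proteins every study
reports); 40 planted exclusives per category (the same order as real
exclusive-set findings); per-dataset detection probability 0.9;
synonym-accession probability 0.1 and unmappable-identifier probability
0.02 (mild identifier noise of the kind ID conversion actually loses).
Background proteins draw Bernoulli(0.5) category memberships, topped up
to at least two categories — this populates the intermediate Venn
regions while guaranteeing that the planted sets are the *only* truly
exclusive proteins, so perfect detection must recover them with
precision = recall = 1. A protein present in D home datasets is
recovered as exclusive iff detected at least once, giving the
closed-form per-protein recall 1 − (1 − p_detect)^D used as the
simulation oracle (0.999 at p_detect = 0.9, D = 3). All randomness
flows from one integer seed through `numpy.random.default_rng`; equal
seeds give identical compendia.

What the simulator does not model: protein abundance, correlated
detection across proteins (shared peptides, co-isolation), study-size
heterogeneity, or biased missingness. Passing recovery tests therefore
demonstrates the correctness of the set algebra and bookkeeping under
the stated dropout model, not robustness to real mass-spectrometry
missingness.

## Numerical and output conventions

Venn signatures are canonicalized to lexicographic category order;
region enumeration is capped at six categories (tabular UpSet-style
output beyond that). Reports are byte-stable for fixed inputs: rows
sorted, floats written with 6 significant digits, JSON keys sorted.
Every CLI run logs tool version, config hash and seed. Empty inputs are
defined outcomes, not errors: an empty identifier list ingests as an
empty set (warned), an empty manifest yields a valid empty atlas and an
all-zero summary.

## Test problem sizes

The test-suite and acceptance-script workloads are desk-scale by
design: the bundled 59-protein/35-dataset tables, exhaustive
hypergeometric enumeration up to N = 12 (N = 10 in the acceptance
script), 20 noise-free recovery runs, and 200 dropout replicates of the
default 300-protein compendium — together a few seconds of compute.

## Known limitations

- Gene-symbol keying inherits every ambiguity of symbol nomenclature;
  distinct proteins sharing a symbol merge, and unmappable local IDs
  drop out (counted, not recovered).
- The exclusivity screen is sensitive to single spurious
  identifications: one false positive in another category removes a
  candidate. No error model is applied, faithfully to the binary
  design.
- The compendium-scale headline figures (thousands of unique proteins,
  per-dimension totals, all-category cores) can only be verified
  against the source studies' supplementary files via
  `milkatlas.integration.check_full_atlas`; the package ships the
  expectations, not the data.
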
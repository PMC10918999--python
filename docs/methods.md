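# Methods

## Proteotyping model

The unit of taxonomic evidence is the Taxon-to-Spectrum Match. A
peptide identified from an MS/MS spectrum is looked up in an index of
in-silico digested reference proteomes; if every protein containing
the peptide belongs to the same taxon at rank *r*, the spectrum
counts as one TSM for that taxon at *r* and for its ancestors at
every higher rank. Two statistics accumulate per (rank, taxon): TSM
count (spectra) and spePEP count (distinct taxon-specific peptide
sequences). The underlying assumptions are the usual ones of
peptide-centric proteotyping: identifications are correct (FDR is
controlled upstream by the search engine), one peptide per spectrum
(chimeric deconvolution is the engine's job), and the reference
database contains the organisms actually present — an organism absent
from the index can only suppress, never create, signal.

### Digestion and peptide normalization

Trypsin cleaves C-terminal of K/R; a following proline blocks the cut
by default (`proline_block=False` gives the unconditional rule for
comparison). Defaults: 2 missed cleavages, peptide length 7–30
residues — one shared default for both search stages. Leucine and
isoleucine are isobaric and indistinguishable by the tandem-MS data
this package consumes, so I→L collapsing is applied identically at
index build and query time (`il_equivalent=False` disables it).
Peptides containing X are indexed but never counted as taxon-specific.
Sequences with characters outside the 20-residue + X alphabet are
rejected with the offending character and position named.

### Specificity with incomplete lineages

A peptide is specific at rank *r* only when all source organisms
carry the same, present, taxon at *r*. Lineages may be truncated
(a rank present implies all higher ranks present — the table format
enforces this); when a source lacks rank *r* the peptide cannot be
*r*-specific and its attribution lands at the nearest rank where all
sources agree. This matches how incomplete reference lineages are
handled in practice and preserves the monotonicity invariant:
specificity at *r* implies specificity (to the ancestor) at every
rank above *r*.

### Cascade search

Round 1 assigns TSMs against the full generic index and accepts
genera with spePEP ≥ 3 and TSM ≥ 5 (both configurable). Round 2
restricts the index to the accepted genera's descendant species —
implemented as an exact sub-index filter, provably equal to
rebuilding from the restricted proteome set — reassigns, and accepts
species by the same thresholds. Count thresholds were chosen because
the evidence requirement is stated in the source material only as a
significance level without a defined test; an optional binomial
screen (`binomial_alpha`) computes P(X ≥ k) for X ~ Binom(N, 1/m)
under a uniform-assignment null over the m candidate taxa at the
rank, and additionally requires p ≤ α.

Merging runs takes the union of accepted taxa, sums TSM counts, and
keeps the best single-run spePEP count — summing spePEP across runs
would double-count sequences observed in several runs, since
cross-run peptide identity is not tracked.

### Biomass estimation

`fraction(T) = 100 · signal(T) / Σ signal` over attributed taxa at
the requested rank (species by default). Signal is either the TSM
count or, in intensity mode, the summed intensity of protein groups
whose member accessions all resolve to one taxon at the grouping rank
(species by default, genus optionally); mixed or unmappable groups
are excluded and their intensity reported as unattributed alongside
the group ids. Unattributed signal is excluded from the denominator —
fractions are shares of *attributed* biomass — because the correct
treatment of unassigned spectra is genuinely ambiguous;
`include_unattributed=True` switches the denominator to all spectra.
Note the estimator is unbiased only insofar as spectra are sampled
proportionally to biomass and peptides are taxon-unique; shared
peptides move signal up-rank (lowering species-level retention) and
database redundancy can inflate spectral-count estimates for taxa
with many near-identical reference sequences.

### Database construction

Organisms are retained when biomass ≥ 0.1% **or** spePEP ≥ 10
(disjunctive by default, `combine="and"` available): the disjunction
is deliberate, so a rare organism backed by strong specific-peptide
evidence survives the biomass floor. An optional coverage target
switches to greedy selection in descending biomass order until the
cumulative fraction meets the target. The emitted FASTA carries
`organism=<species_id>` header tokens so intensity-mode
quantification can resolve protein groups back to taxa; duplicate
accessions across organisms are kept once and logged.

### Functional profiling

Pathway coverage = 100 · |observed KOs ∩ pathway KOs| / |pathway
KOs|. Abundance weighting uses the mean protein abundance across
replicates, summed within pathway (mean-then-sum, fixed and
documented because the aggregation order is otherwise ambiguous). A
KO belonging to k pathways contributes its protein's full abundance
to each — standard KEGG practice — with a uniqueness-weighted option
(abundance / k) when conservation of total abundance matters. The
genus × category matrix is the pivot of per-taxon pathway weights
resolved to genus, with unresolvable taxa in an `unclassified` row.
Two-taxon comparison partitions observed KOs into shared / A-only /
B-only (disjoint, exhaustive) and labels each pathway by the
partitions it draws on (`mixed` when several).

## Synthetic data: what it emulates, and what it does not

The generator emulates a spike-in reference standard: species with
fixed biomass fractions, spectra sampled proportionally to biomass,
log-normal precursor intensities, uniform quality scores, and a
controlled rate of cross-taxon peptide sharing. Proteins are built
from generated peptide "units" (no internal K/R, no leading P,
terminal K/R) so the fully cleaved digest recovers exactly the units
and ground truth is known by construction; sharing is implemented by
literally copying a fraction f of units into every species of the
sharing scope, so the index discovers it naturally. Missed-cleavage
products are emitted by concatenating adjacent units (defaults
90.2% / 9.5% / 0.3% for 0/1/2, typical of a high-quality tryptic
digest); concatenations exceeding the 30-residue window fall outside
the index and count as unattributed, a benign thinning that does not
bias fractions.

Defaults: the three-member 2:1:97 community; 40 proteins of ~300
residues per species (a desk-scale stand-in for real proteomes —
large enough for thousands of distinct peptides, small enough to
index in milliseconds); K/R-terminated units of 7–20 residues, giving
tryptic-length peptides without real sequences; intensity
ln-location 13.8 (≈1e6 median, a typical precursor intensity scale)
and ln-scale 1.0. All randomness derives from the single spec seed
via a `numpy` SeedSequence spawn: child 0 community, child 1 spectra,
child 2 KO fixtures.

What the simulator does **not** model — and hence what passing tests
do not establish about real data: sequence homology (sharing is
all-or-none copying, not gradients of similarity), identification
errors and FDR, chimeric spectra, peptide detectability and
ionization biases, protein-abundance distributions within a proteome
(units are sampled uniformly), or database incompleteness beyond
outright absence. Estimator accuracy on synthetic communities is
therefore a correctness statement about the computation, not a
performance claim about real microbiomes, where shared-peptide
attribution is known to overestimate taxa with many close relatives
in the reference database.

## Numerical choices

- Top-N spectrum selection breaks score ties by (run, spectrum id)
  for determinism; a missing quality score is an error naming the
  record.
- Biomass fractions sum to 100 within 1e-9 over attributed taxa;
  zero attributable signal is an error, not a NaN.
- All output tables are written in sorted taxon order; set-valued
  internals are sorted before serialization, so identical inputs and
  seed give byte-identical outputs.
- Empty inputs: an empty PSM list is a valid empty cascade result; an
  empty biomass profile yields an empty selection with a warning; an
  empty annotation group reports zero counts, not a division error.
- The peptide index serializes to a line-oriented text format with a
  versioned header carrying the digestion parameters, so an index
  cannot silently be queried under different normalization than it
  was built with.

## Problem sizes

The validation suite simulates 100,000 spectra for the spike-in
recovery (binomial sampling error ≈ 0.03–0.05 percentage points for
the 1–2% components), 1,000 → 100,000 spectra × 10 seeds for the
estimator-consistency trend, and ≥ 100 randomized micro-fixtures per
operation for oracle-equivalence checks; the whole suite runs in
well under a minute on one CPU.

## Known limitations

- The TSM parsimony is the documented baseline: each spectrum counts
  once per rank at its peptide's specificity level; no
  spectrum-level reallocation between competing taxa is attempted.
- Intensity-mode taxon resolution requires provenance-tagged
  accessions (the custom-database dialect); arbitrary external
  FASTAs need an accession→organism mapping supplied by the caller.
- spePEP counts are per run; the merge keeps the best run rather
  than a true cross-run union of sequences.
- The CLI pipeline's `quantify` stage excludes quant rows whose
  accessions fall outside the custom database rather than failing.
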
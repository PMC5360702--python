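# Methods

This note documents the models, parameter choices and numerical conventions
behind `sstdbkit`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Search-space construction

Transcripts are translated in all six reading frames with the standard
genetic code. ORFs are **stop-to-stop fragments** — no start-codon
requirement — matching the behaviour of sixpack-style translators; a
start-codon mode is deliberately not the default because transcriptome
assemblies routinely truncate 5' ends. Codons containing `N` translate to
`X`, and `X` does not split a fragment: divergent or low-quality regions
stay searchable. Trailing partial codons are ignored.

The minimum ORF length (`min_orf`, default 60 residues) is applied
**strictly**: a 60-residue fragment is discarded, a 61-residue fragment
kept. ORF coordinates are 0-based half-open on the forward strand
regardless of the encoding strand, so `end − start = 3 × n_residues`
always holds; negative frames −1/−2/−3 are counted from the first base of
the reverse complement. Deduplication of identical ORFs is off by default
(configurable) since duplicated entries are harmless to attribution and
dedup would hide genuine transcript multiplicity.

Decoys are full sequence reversals, one per target, accession-prefixed
`REV_`; contaminants are prefixed `CON_`. Reversal preserves amino-acid
composition and length distributions, the property decoy-based FDR
estimation relies on.

## Digestion and masses

Trypsin cleaves after K or R except before P (the plain rule, without the
ExPASy WKP/MRP counter-exceptions — the search settings modelled here use
the plain rule). Up to 2 missed cleavages are enumerated by default.
Peptide masses are monoisotopic: water 18.010565 Da plus standard residue
masses (pyteomics tables), with carbamidomethylation of cysteine
(+57.02146 Da) applied as a fixed modification to every C.

Variable modifications — deamidation (N, Q), oxidation (M) and
Gln→pyro-Glu at an N-terminal Q — are enumerated combinatorially with a cap
of 3 variable modifications per peptide (search engines cap this
internally; 3 is a common default). At an N-terminal Q, deamidation and
pyro-Glu are **alternatives**, never co-applied at the same position.
Precursor matching uses a ±10 ppm relative tolerance. The fragment-ion
tolerance (0.6 Da) is carried in the pipeline configuration for
completeness but is inert: no fragment spectra are simulated, and
pretending otherwise would be fake physics.

Two identity keys drive matching and conflict logic: `il_key` (I→L
substitution; leucine/isoleucine are isobaric and indistinguishable by MS)
and `composition_key` (sorted residue multiset, permutation-invariant).

## PSM validation

The posterior probability model is a **two-component Gaussian mixture on
the raw search score**, fitted by EM — a deliberate simplification of
PeptideProphet's discriminant-plus-delta-mass model, which is not
reproduced here. Initialization is deterministic: component means at the
25th/75th score percentiles, both variances at the overall variance, mixing
0.5. EM stops when the relative log-likelihood change drops below 1e-8 or
after 1,000 iterations; the E-step is computed in log space. A degenerate
score set (zero spread) skips the fit with a warning and filtering falls
back to decoy counting alone.

Acceptance is `posterior > 0.95` (strict). FDR is estimated as
`100 × n_decoy / n_target` among accepted identifications — the **target
count** in the denominator, so 13 accepted decoy clusters against 1,397
target clusters give 0.93%. Peptide-level uniqueness collapses I/L and
keeps modification strings distinct.

## Conflicts

Within one spectrum, hits whose scores agree within a relative tolerance of
1e-6 (floating-point exports make exact equality meaningless) are
top-score ties. If the tied hits name more than one distinct I/L-collapsed
sequence — typically composition permutations of the first residues — the
spectrum is unresolvable and all its rows are excluded from origin counts
(tallied separately). Tied hits with the same I/L-collapsed sequence are
one identification; the lexicographically first row is kept.

## Parsimony inference

Three rules, applied in order: (1) entries with identical peptide sets
merge; (2) a group whose peptide set is a proper subset of another's is
absorbed into the smallest strict superset group; (3) remaining groups are
selected greedily by decreasing uncovered-peptide count (ties broken by the
representative accession) until all peptides are covered. Greedy set cover
is a heuristic: on random small instances it occasionally reports one
cluster more than the exhaustive optimum (the test suite enumerates the
exact optimum on instances of ≤10 entries / ≤15 peptides and documents the
known gaps). A cluster is a decoy cluster only if **every** member is a
decoy — conservative, since a mixed cluster still carries target evidence.
Shared peptides remain attached to every covering cluster; no razor-peptide
assignment is performed at cluster level.

## Attribution

Contaminant matches are ignored when classifying; contaminant-only
identifications are tallied separately so the three origin categories sum
with conflicts to the total. The enrichment ratio is
`(sstdb_only + both) / (vpdb_only + both)` at peptide level — the count
identifiable with the transcriptome database present over the count
identifiable with the orthologue database alone — reported to one decimal,
undefined (never infinite) when no peptide has orthologue-database
evidence. Peptide-level conflict percentages are reported against the PSM
total, since conflicts are per-spectrum events.

## Annotation transfer

Best hit per query: lowest e-value, ties by higher bit score, then subject
accession. Transfer requires best-hit e-value ≤ 1e-4. E-value bins use
strict upper bounds, so a boundary value falls in the bin it opens
(e = 1e-20 → `1E-20..1E-10`). Annotation is monotone in the threshold.
BLAST itself is not run; the module consumes 12-column tabular output, with
species parsed from Swissprot-style subject ids or supplied via a metadata
map.

## Synthetic data: what it emulates and what it does not

Defaults: 200 proteins (length ~ N(350, 100²), floor 80 residues so every
planted protein clears the 60-residue ORF filter), 200 non-coding
transcripts (uniform 200–1500 nt), UTRs of 20–150 nt, orthologue coverage
0.7 at per-residue divergence 0.1 with 20% unrelated entries, 260
contaminants, 10,000 spectra at p_correct = 0.7 with scores N(4,1) correct
vs N(0,1) incorrect. Reverse translation uses uniform random synonymous
codons (codon bias is irrelevant to this pipeline); stop codons are placed
in frame at both CDS boundaries so ORF recovery is exact, making the
round-trip invariant strict. Orthologue substitution redraws a residue
uniformly **from the whole alphabet**, giving the closed form
E[identity] = 1/|alphabet| at divergence 1 used by the tests. Incorrect
PSMs hit a random target or decoy peptide with equal probability — the
assumption under which the decoy count estimates the incorrect-target
count, so decoy FDR is calibrated against labels.

Not emulated: fragment spectra (m/z peak lists), intensities, retention
time, charge states, sequencing reads, assembly errors, chimeric
transcripts, or realistic search-engine score shapes. Consequently the
tests demonstrate the **logic** of the pipeline — exact ORF recovery,
calibrated decoy FDR under the mixture's assumptions, parsimony and
attribution arithmetic — not robustness to assembly artifacts or to
score distributions a real engine produces. Because the simulated
transcriptome covers the whole proteome, vpdb_only counts are structurally
near zero in synthetic runs; the vpdb_only path is exercised by unit tests
with hand-built inputs.

## Problem sizes and determinism

The shipped test and acceptance runs use 30–200 proteins and 2,000–10,000
spectra — sizes at which exhaustive oracles (six-frame enumeration,
brute-force digestion, exact set cover) remain feasible while the
statistical checks (±2 FDR points, ±0.03 mixing proportion) have adequate
power. All randomness flows through `numpy.random.default_rng` seeded from
the configuration; every generator and stage is a pure function of
(inputs, seed), and an end-to-end rerun reproduces output files byte for
byte.
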
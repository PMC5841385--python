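# Methods

## Scope and data model

The pipeline analyzes glutamine homorepeats (polyQ) in sets of orthologous
proteins. Its inputs are per-species pairs of protein and CDS FASTA files,
a tab-separated ortholog table (`group_id`, `species`, `protein_id`), a
species table (`species_code`, divergence time in Myr to the reference
species, which sits at 0), and optionally a disease-panel table naming a
reference protein and the 1-based coordinates of its disease-associated Q
stretch. Every record is validated on load: after stripping at most one
terminal stop codon the CDS must be exactly three nucleotides per residue
and must re-translate to the peptide under the standard genetic code.
Records failing either check are excluded (reason codes `LENGTH_MISMATCH`,
`TRANSLATION_MISMATCH`); records with ambiguous nucleotides inside a codon
are kept for length-based statistics but never contribute to CAA/CAG
tallies, because codon counts are literal triplet counts. Coordinates are
0-based half-open internally and 1-based inclusive in every emitted table.

When a species contributes several candidate proteins to one ortholog
group, the longest protein is chosen, ties broken by smallest protein id.
This is a package decision — deterministic, and biased toward complete
isoforms — not a property of the underlying biology; groups missing any
configured species are dropped and counted.

## Stretch detection and codon usage

A Q stretch is a maximal run of consecutive glutamines, counted
non-nested: "QQQQ" is one stretch of length four. Stretches of length 1
and up are all reported. For unambiguous records each stretch satisfies
n(CAA) + n(CAG) = length, since CAA and CAG are the only glutamine codons
in the standard code.

Per-proteome CAG percentages are ratios of pooled codon counts within a
length bin — ratio of sums, not the mean of per-stretch ratios — because
the quantity of interest is the proteome-level codon usage at a given
stretch length, and stretch-level ratios would weight short stretches
disproportionately. Percentages are reported to two decimals with
round-half-even. Three binning schemes are used: exact lengths 1..8 plus
">8"; the coarse "1–3" / "4–8" / ">8" split (short stretch, short polyQ,
long polyQ, with "short polyQ" defined as 4 ≤ Q ≤ 8); and "0–3" / "4–8" /
">8" for reference-length binning, where 0 encodes an ortholog whose
region is absent.

## Alignment and region delineation

Ortholog groups are aligned at the protein level and the alignment is
back-translated so that every non-gap cell carries its residue's codon
(ungapping a codon row reproduces the CDS exactly). The built-in engine
is a center-star construction: each non-reference member is aligned to the
reference by global affine-gap Needleman–Wunsch (BLOSUM62, gap open 10,
extend 0.5, via Biopython's pairwise aligner, whose scores the test suite
checks against an independent dynamic-programming oracle), and the
pairwise alignments are merged on reference coordinates with insertions
left-aligned. This is weaker than a full progressive aligner between
non-reference members, but the downstream statistics only require
column-consistent correspondence of Q blocks to the reference, which the
merge guarantees; the construction is also deterministic and
member-order-invariant. An `external` hook accepts any engine honouring
the same contract for users who want a heavier aligner.

An orthologous polyQ region is seeded by any member's *pure* glutamine run
of length ≥ 4 mapped to its alignment columns. Overlapping seed intervals
merge; each interval then extends across any adjacent column in which some
member carries a glutamine, iterating to a fixpoint, and intervals that
meet after extension merge into one region. Regions of a group are
analyzed independently. Within a region, a member's **merged length**
counts all its Q residues in the column interval — interrupting residues
do not terminate the count, and their identity is ignored: QQQQPQQQQ has
merged length 8, QQQQQQQQQ merged length 9. A member entirely gapped over
the region has merged length 0 and still participates in stability
statistics, which is what populates the 0–3 reference bin (such regions
exist only because some other ortholog carries a polyQ there). A member's
region codon run is trimmed to its first..last glutamine codon, so the
interrupted-purity class (`MIX_WITH_OTHER`) is reachable exactly when a
non-Q residue sits strictly inside the glutamine span.

Two boundary rules are package decisions where reasonable alternatives
exist: region extension is inclusive (ties resolved by extending), and
partially overlapping seed runs from different members are merged by
union. Both favour counting every glutamine plausibly associated with the
region.

## Stability classification

A region is **stable-in-length** when the modal merged length is shared by
at least half of the members — read literally as multiplicity ≥ n/2, so 6
of 12 suffices, and a 2-member group is always stable (each length has
multiplicity 1 ≥ 1). The assigned length is the modal length; among tied
modal lengths the one carried by the species with the smallest divergence
to the reference wins (the reference itself dominates any tie it is part
of), and a residual tie at identical divergence goes to the smaller
length, for determinism. Length-difference profiles emit signed
differences (other − reference) for every record and every choice of
reference species, grouped by the reference length's bin; the sign
convention is the package's.

The stability × length codon-usage table pools CAA/CAG counts per species
over the classes 4–8S, 4–8U, >8S, >8U, where the class comes from the
region's assigned length and stability flag. The rank-sum contrast
(two-sided Mann–Whitney U, exact null when n1·n2 ≤ 400 with no ties,
normal approximation with tie and continuity corrections otherwise, via
scipy behind the package surface) defaults to per-region pooled CAG
fractions as the sampling unit; per-species percentages can be passed to
the same test instead. No multiple-testing correction is applied — single
raw P values are reported.

## Disease panel

Panel entries anchor one disease-associated stretch by reference
coordinates; the reference protein must be glutamine across the anchored
span (proteins with several stretches contribute only the anchored,
pathogenic one). Ortholog sets here may be incomplete. An available member
is accepted when its aligned first..last-residue span overlaps at least
50% of the anchor columns (configurable). The rule quantifies "the
alignment covers the stretch coordinates": literal full coverage would
reject a near-complete ortholog over a single terminal gap, while the 50%
floor still rejects fragments ending before the stretch. Known
normal/pathological length ranges are annotations only and never enter
computation.

## Synthetic data generator

The simulator produces complete inputs (FASTA pairs, ortholog, species,
panel and truth tables) with the statistical structure the analysis
assumes, so the whole pipeline is testable offline. Its defaults are the
study conditions used throughout the tests:

- **Species**: 12 primate-like taxa at divergences 0–74 Myr.
- **Background stretches**: per protein, Poisson counts with means 10, 1
  and 0.1 for lengths 1, 2, 3 — the observed spectrum of short glutamine
  stretches per protein. Background (non-Q) residues are drawn from fixed
  amino-acid frequencies excluding glutamine, so every Q is planted and
  truth is exact; spacers of 5–40 residues separate stretches.
- **Codon usage**: each glutamine codon is CAG with probability θ(bin of
  the ancestral stretch length): 0.70 for 1–3, 0.80 for 4–8, 0.77 for >8.
  For planted polyQ seeds (one per group, ancestral length uniform on
  4–13) the CAG count is stratified — length·θ stochastically rounded,
  then shuffled — so per-region CAG content scatters tightly around θ
  while run structure still varies. A side effect mirrors real primate
  data: all-CAA polyQ regions essentially never occur. Planted stretches
  longer than 8 carry one proline interruption with probability 0.05.
- **Evolution**: a star tree scaled by divergence time (a nested topology
  adds little for the statistics tested here and the star keeps branches
  independent). Per branch, each stretch undergoes Poisson(0.18 · t)
  slippage rounds. Per round it expands with probability
  p = min(0.8, 2.4e-5 · r^5.5), where r is its longest consecutive CAG
  run, and contracts with probability 0.95·p. Expansion duplicates a codon
  inside the longest CAG run (slippage acts in the tract that drives it),
  contraction deletes one there; both therefore preserve and propagate
  CAG-richness, which is the proposed mechanism made generative: CAG-rich
  stretches destabilize, grow, and stay CAG-rich. The steep run exponent
  concentrates instability in long runs; the constants were fixed once so
  that the generator alone reproduces the qualitative stability gradient
  seen in real primates (near-complete stability at length 4, falling
  steeply beyond 8) while leaving bin-level codon usage recoverable.
- **Panel groups**: 9 separate groups with θ = 0.92, ancestral lengths
  9–23, contraction-biased branch evolution scaling with divergence (so
  distant species carry shorter versions and the unevolved reference is
  longest), and 10% per-species dropout. Panel proteins live in separate
  FASTA/table files so the proteome-wide profiles are not contaminated by
  the deliberately extreme panel composition.

One seeded generator drives all sampling; the same seed yields
byte-identical files. What the generator does **not** emulate: substitution
of background residues (orthology is by construction, so the aligner is
never stressed by divergent flanks), isoform structure, GC/codon-bias
gradients along genes, selection, and any coupling between groups. Tests
passing on this data therefore validate the pipeline's bookkeeping and the
recoverability of planted signal — not the biological claims themselves,
which require real proteomes.

## Numerical and reporting choices

Problem sizes in the shipped tests and acceptance checks: 300 groups × 12
species for recovery runs (a few seconds end-to-end), 15–40 groups for
unit-level fixtures. Stability-gradient checks band assigned lengths into
4–5, 6–7, 8–10 and ≥ 11, giving 55–90 regions per band at the default
size. Exact Mann–Whitney mode is validated against full permutation
enumeration, and its type-I error bounded by simulation at α = 0.05.
Percentages everywhere are two-decimal round-half-even. Pipeline outputs
go into fresh `run_NNN` directories and contain no timestamps, so reruns
on identical inputs are byte-identical.

## Known limitations

- The center-star alignment does not optimize non-reference pairs; with
  highly divergent real sequences a progressive or consistency-based
  aligner (via the external hook) is preferable.
- The "at least half" rule makes every 2-member region stable; with the
  intended 12-species sets this case does not arise, but small real data
  sets should use ≥ 3 members.
- The literal multiplicity ≥ n/2 reading (not strict majority) is
  followed; with even member counts a 50% share counts as stable.
- Proteome-scale claims (real stretch frequencies, real stability rates,
  disease-protein lengths) depend on full database proteomes and are out
  of the package's validated scope.
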
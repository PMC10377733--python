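# Methods

## Repeat model

A protein short tandem repeat (pSTR) is a maximal run of `n ≥ 2`
identical, directly adjacent copies of a unit of length `k ≥ 2`.
Unit length 1 (homorepeats) is excluded: adjacent identical residues
arise too easily by chance to be informative at this granularity.
Unit lengths range up to ⌊L/2⌋, the largest length that still allows
two units.

Detection slides, for every `k`, a window along the sequence and
records runs of consecutive equal `k`-mers. The implementation reduces
this to a self-match profile per `k` (`seq[i] == seq[i+k]`): every
maximal true stretch marks a region periodic with period `k`, from
which one maximal run per phase is emitted in O(L) per `k`. All
patterns are kept, even when they overlap:

* cyclic rotations (`ACD`, `CDA`, `DAC` in `ACDACDACD`) are distinct
  repeats with their own maximal runs;
* non-primitive units (`PQPQ` inside a `PQ`×4 tract) are reported as
  independent repeats;
* a run is suppressed only when its interval lies strictly inside a
  longer run of the *identical* unit string (sub-run suppression keeps
  the output finite and canonical).

Two optional filters (`primitive_only`, `exclude_homopolymer_units`)
suppress periodic units and single-letter-composition units; both are
off by default since the base procedure reports everything. Residue
coverage is the size of the union of all run intervals divided by the
sequence length — each residue counts once no matter how many runs
cover it.

## Alignment

Unit variation is evidenced in global pairwise alignments. The
built-in aligner is a Gotoh dynamic program: BLOSUM62 substitution
scores, affine gap penalty of 10 to open and 0.5 per additional gapped
residue, terminal gaps penalized like internal ones (the intended
inputs are full-length homologs, so semi-global scoring would hide
terminal repeat variation). Scores are held as doubled integers, so
co-optimality comparisons are exact. Among co-optimal tracebacks, gap
states are preferred over the diagonal while walking back from the
C-terminus; the practical consequence is that a gap that could sit at
any phase of a periodic tract is always placed at the tract's
C-terminal end. Residues without a BLOSUM62 row (U, O, J) score as X.
Symmetry is enforced by aligning each pair in a canonical internal
order, so `align_pair(a, b)` and `align_pair(b, a)` are
column-identical after a row swap.

The inner matrix fill is JIT-compiled with numba; a pure-Python path
is kept as fallback. An adapter can replace the built-in aligner with
any external executable that takes a 2-sequence FASTA and emits
aligned FASTA (MUSCLE-style `-in`/`-out` template or MAFFT-style
stdout). Published event counts depend on the aligner's gap placement,
so parity with a specific pipeline requires its pinned aligner binary;
results across aligners agree up to gap-phase choices, which the event
canonicalization below absorbs.

## Event calling

For each pSTR of each sequence of a pair, every unit is classified by
its alignment columns: *gap-opposed* (all columns opposite gaps in the
partner) or *conserved* (all columns opposite identical residues).
One event is emitted per maximal contiguous block of gap-opposed units
that is immediately adjacent, within the pSTR, to at least one
conserved unit; the block size is `n_extra_units` and the sequence
holding the block is the carrier. Units only partially opposed to
gaps do not count, and degenerate (non-identical) conservation is not
accepted. Each emitted event is re-validated against the raw carrier
sequence (the block plus its conserved neighbour must spell
`unit × (n_extra_units + 1)`).

Because the gap could sit at any phase of the periodic tract with
equal score, the reported block is canonicalized to the C-terminal
phase: it is slid towards the C-terminus while the unit beyond it is
conserved. The built-in aligner already places gaps there, so
canonicalization is a no-op for it; for external aligners it makes
event keys independent of an arbitrary phase choice.

Family-level calling runs all n(n−1)/2 pairs, deduplicates events on
(carrier, unit, canonical start, block size) while collecting the
supporting partners, and fills a symmetric pair-support count matrix
(the heatmap). Carriers are never merged across sequences: two family
members each gaining a unit are two events. Event counts can be read
either as deduplicated events or per supporting pair (the matrix);
both are reported because either convention is defensible.

## Query mapping

Events are projected onto one query sequence from the input (default:
the first; any id can be chosen). The carrier is aligned with the
query and the mapped position is the query residue in the column of
the central carrier position `carrier_start + (k·n_extra − 1)/2`
(integer division). When that column is a gap in the query — common,
since the query may lack the extra units entirely — the nearest
preceding non-gap query position is used, 0 if none exists. This
choice keeps hotspot tracks dense near the tract instead of dropping
such events.

## Composition statistics

Per proteome (not per protein): coverage is total covered residues
over total residues of the X-free sequences; amino-acid frequencies
are computed over the 20 standard amino acids, once over all residues
(background) and once over residues inside ≥ 1 pSTR. Rare letters
(B, Z, U, O, J) stay in the coverage denominator but are excluded from
the 20-vectors. A proteome without any repeat residue yields a zero
in-pSTR vector with an explicit flag rather than NaNs.

## Enrichment test

The overlap between proteins in variable families and a thresholded
score set is tested with the one-sided hypergeometric upper tail,
P(X ≥ k) for X ~ Hypergeom(N, K, n) — the enrichment direction.
Thresholding is inclusive (score ≥ cutoff). A two-sided Fisher exact
variant is available behind a flag. For the published
phase-separation propensity tables (20,366 human proteins; 6,239 above
0.75 and 40 of 99; 4,707 above 0.90 and 35 of 99) this yields
p = 0.0244 and p = 0.0038, rounding to the reported 0.024 and 0.004.

## Synthetic families

The generator emulates a small ortholog family whose members differ
only in repeat-unit counts: one random background sequence (uniform
over the 20 amino acids by default, configurable), shared by all
members, with a tract `unit × countsᵢ` inserted at each locus, and
optional point substitutions outside the loci. Defaults for the
random spec: 2–6 members, background length 240 (total length roughly
the 200–300 residue scale of curated ortholog sets), 1–3 loci,
primitive units of 2–7 residues, 1–5 units per member — i.e. the
one-to-five-unit regime in which repeat-number variation is typically
observed.

The planted truth is computed in closed form, not by running the
pipeline: for a carrier with `m` units against a partner with `p < m`
at a locus with primitive unit `u` (length `k`), there is one event
for every super-unit multiplicity `t = 1 … min(p, m−p)`, with unit
`uᵗ`, canonical start `locus + p·k` and `⌊(m−p)/t⌋` extra units; query
positions follow from the same arithmetic. Three guard rules keep
this truth well defined:

* substitutions never touch a locus or its unit-width flanking
  windows;
* tract phases are pinned: the residue before a tract never equals
  the unit's last residue and the residue after it never equals the
  first (otherwise maximal runs and optimal gap placements could
  slide past the locus by a rotation), and any chance repeat run
  straddling a tract boundary is removed by deterministically
  rewriting the single flank residue at that boundary;
* units whose doubled form contains a shorter repeat crossing the
  copy junction (e.g. `HVTTFHV`, whose tract spells `…FHVHVT…`) are
  rejected, because such junction sub-repeats generate additional
  events no locus-level formula can enumerate.

With zero substitution noise, the full pipeline reproduces the truth
table exactly — this is the package's main end-to-end guarantee, and
`scripts/acceptance.py` measures it as precision and recall over 100
seeded families. What passing does **not** show: robustness to
substitution noise inside repeats, to indels outside loci, to
degenerate (imperfect) units, or to misalignment in low-similarity
families — real homolog sets have all of these, and the method by
construction only reports perfect-unit events.

## Homolog selection

Single-protein mode delegates the similarity search itself to BLASTP
(or any tool emitting `-outfmt 6` tabular hits) and implements the
selection: at most one subject per proteome, by highest bitscore, ties
broken by lowest e-value, then lexicographic subject id — a
deterministic rule invariant under input permutation. Proteome tags
default to the token after the last `_` of the subject id
(UniProt-style `GENE_SPECIES`), overridable with a regular expression
or an explicit mapping file. Fragment hits are kept: they can only
lose events, not fabricate them.

## Numerical and degenerate-input choices

* Coordinates are 1-based and inclusive everywhere.
* Detector output is sorted by (start, unit length, unit); ties in
  the aligner are broken by the fixed state preference above — runs
  are fully deterministic, identical input gives byte-identical
  output.
* Sequences shorter than 4 residues cannot contain a pSTR and return
  an empty list; empty sequences, `*`/`-` characters, duplicate ids
  and malformed FASTA are hard errors.
* `X`-containing sequences are excluded everywhere and the exclusion
  is logged with the ids (silently changing denominators would be
  worse).
* Acceptance-scale parameters: 1,000 random sequences of length ≤ 60
  for the detector oracle, all pairs of 50 random length-≤20 sequences
  for the aligner check, 100 families for planted recovery — sizes at
  which the brute-force oracles are exact and fast.

## Known limitations

* Only perfect repeats are modelled; degenerated units (the common
  fate of old repeats) are invisible to both detection and calling.
* Events are not polarized into gains versus losses — that requires a
  phylogeny, which is out of scope.
* Event counts depend on the aligner's gap placement in ways
  canonicalization can only partly absorb; cross-study comparisons
  should pin the aligner.
* The proteome statistics are descriptive; no test is attached to
  compositional differences between species.
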
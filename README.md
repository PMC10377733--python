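# pstrtool

Detection of **protein short tandem repeats (pSTRs)** and of the
gain/loss of their units within protein families.

A pSTR is a stretch of two or more *identical* residue units, with unit
length ≥ 2, lying directly adjacent in a protein sequence (`ACDACDACD`
is an `ACD` repeat with three units; homorepeats such as poly-Q are unit
length 1 and are excluded). Repeat tracts expand and contract, e.g.
through replication slippage, so homologous proteins often differ only
in the number of units at a tract. `pstrtool` finds those differences:

1. **Detection** — for every unit length *k* from 2 to ⌊L/2⌋, a window
   of length *k* is slid along the sequence and every maximal run of ≥ 2
   consecutive identical *k*-mers is reported, including overlapping
   runs, cyclic rotations and non-primitive units.
2. **Unit-variation calling** — every pair of input sequences is
   globally aligned (built-in Needleman–Wunsch/Gotoh with BLOSUM62,
   affine gaps 10/0.5; or an external aligner of your choice). When one
   or more whole units of a repeat align entirely to gaps in the partner
   while an adjacent unit of the same repeat is perfectly conserved, a
   unit gain/loss event is called for the carrier of the extra block.
3. **Query mapping** — each event is projected onto one chosen query
   sequence through the alignment column of the central residue of the
   extra block, annotated as `[UNIT(position)]`, so hotspots of repeat
   evolution can be read off a single reference coordinate system.
4. **Proteome statistics** — fraction of residues inside ≥ 1 pSTR and
   amino-acid usage inside repeats versus the proteome background.
5. **Enrichment** — one-sided hypergeometric test of the overlap
   between proteins in variable families and any thresholded
   per-protein score set (e.g. phase-separation propensities):
   *p* = P(X ≥ k), X ~ Hypergeom(N, K, n).

It also ships a synthetic-family generator that plants repeat
expansions with a machine-readable truth table, and a best-hit-per-
proteome selector for BLAST tabular output (single-protein mode).

## Worked example

`family.fasta` holds three homologs: `at1` with a `GP`×4 tract, `sp1`
with `GP`×3, and `sp2` with `GP`×2 plus an expanded poly-N region
(`NNNNNN` for the others' `NNN`):

```bash
pstr variation family.fasta -o out
# INFO pstrtool: evaluated 3 pairs; 6 deduplicated event(s); 3 pair(s) with support
cat out/events.tsv
```

```text
carrier_id  partner_ids  unit  carrier_start  n_extra_units  query_pos
at1         sp2          GP    13             2              14
at1         sp2          GPGP  13             1              14
at1         sp1          GP    15             1              15
sp1         sp2          GP    13             1              13
sp2         at1,sp1      NN    23             1              26
sp2         at1,sp1      NNN   23             1              26
```

Reading the table: relative to `sp2`, `at1` carries two extra `GP`
units starting at its position 13 (equivalently one extra `GPGP` block
— overlapping descriptions are reported, never merged); relative to
`sp1` it carries one. `sp2` itself is the carrier of an extra `NN`/
`NNN` block in the poly-N tract, supported by both partners. The
`query_pos` column places every event on the first input sequence
(`at1`, selectable with `--query`), revealing two hotspots around
positions 13–15 and 26. `out/pair_matrix.tsv` is the symmetric
pair-support matrix behind the heatmap (rows/columns in input order)
and `out/position_track.tsv` the per-query-position event counts.

The other subcommands: `pstr detect` (one TSV row per pSTR),
`pstr stats` (per-proteome coverage and 20-dim usage vectors),
`pstr synth` (synthetic family + truth table), and

```bash
pstr enrich --universe 20366 --selected 6239 --family 99 --overlap 40
# ...
# p_value 0.0244229
```

All of this is available as a library too, e.g.:

```python
from pstrtool import read_fasta, filter_x_sequences, call_family_events

records, dropped = filter_x_sequences(read_fasta("family.fasta"))
result = call_family_events(records, query=records[0].id)
for event in result.events:
    print(event.carrier_id, event.annotation())
```

Sequences containing `X` are always excluded before analysis (and
reported), coordinates are 1-based and inclusive everywhere, and runs
are deterministic: identical input gives byte-identical output.

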
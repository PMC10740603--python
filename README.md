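# hostblock

Design and in-silico evaluation of **blocking primers** for suppressing host
rRNA amplification in eukaryotic (18S) metabarcoding.

When universal eukaryotic primers (e.g. the 18S V4 set) are applied to animal
tissue, the host's own rRNA dominates the library and drowns out the
microeukaryote community of interest — for freshwater snails, host amplicons
can exceed 80% of reads. A blocking primer is an oligo carrying a 3' C3
spacer (non-extendable by polymerase) that anneals to the host template
overlapping a universal primer's binding site, out-competing it on host
molecules while leaving other templates amplifiable. `hostblock` implements
the computational side of that design:

1. **refdb** — read a taxonomically annotated reference database
   (Silva-style FASTA, `>accession Domain;...;Genus`) and partition it into a
   host clade (e.g. Heterobranchia), excluded clades (e.g. all other
   Metazoa), and the non-target community.
2. **insilico_pcr** — IUPAC-aware, mismatch-tolerant primer-site search and
   amplicon extraction. One mismatch per primer is tolerated by default,
   because known snail sequences differ from the universal reverse primer at
   a single position — the very position a snail-specific blocker exploits.
3. **entropy_profile** — per-column Shannon entropy (bits) over the last
   *W* = 40 nt of host and non-target amplicons, right-anchored at the
   3' terminus (which contains the reverse-primer site). Columns with low
   host entropy and high non-target entropy delimit the design window.
4. **blocker_design** — enumerate host-consensus candidate oligos over a
   length range (24–32 nt, targeting ~28) and an overlap range with the
   reverse primer's 3' suffix (8–12 bp, targeting ~10), filter on host
   conservation and melting temperature (SantaLucia nearest-neighbor by
   default), and rank by `host_blocked − λ·off_target_blocked`.
5. **specificity** — binary in-silico block calls (full-length blocker match
   with ≤ *k* mismatches on the strand the reverse primer anneals to),
   host/non-target blocked fractions and a per-clade breakdown of off-targets.
6. **synthetic_data** — a seeded generator of Silva-like databases with known
   truth (conserved host clade with the snail-specific primer mismatch,
   divergent non-targets, primer-free decoys), so the whole pipeline is
   testable without downloading any reference release.

The bundled assay constants are the published 18S V4 pair
`CCAGCASCYGCGGTAATTCC` / `ACTTTCGTTCTTGATYRA` and the 28-nt
*Biomphalaria* blocking primer `TCTTGACTAATGAAAACATTCTTGACAA`, whose 5'
prefix overlaps the reverse primer's 3' suffix by 10 bp with exactly one
(snail-specific) mismatch.

## Worked example

```sh
hostblock simulate --seed 1 -o db.fasta          # 100 hosts, 100 non-targets, 10 decoys
hostblock design db.fasta -o design_out
```

prints

```
INFO hostblock.pipeline: partition: 100 host / 110 non-target / 0 excluded records
INFO hostblock.insilico_pcr: extract_amplicons: 100/100 references yielded an amplicon ...
INFO hostblock.insilico_pcr: extract_amplicons: 100/110 references yielded an amplicon ...
top candidate: GTTCTTGAACAACCACCTTGCATC (host blocked 100.00%, off-target 0.00%)
```

The 10 skipped non-target records are the decoys, which carry no primer
sites. `design_out/candidates.tsv` ranks every candidate that passed the
constraints:

```
rank  sequence                  length  overlap  tm     host_blocked  off_target_blocked  mean_conservation  score
1     GTTCTTGAACAACCACCTTGCATC  24      12       58.62  1.0           0.0                 1.0                1.0
2     TTCTTGAACAACCACCTTGCATCA  24      11       58.94  1.0           0.0                 1.0                1.0
...
```

and `design_out/specificity.txt` holds the in-silico audit of the winner:

```
blocking primer: GTTCTTGAACAACCACCTTGCATC
mismatch allowance (k_block): 0
host amplicons predicted blocked: 100/100 (100.0%)
non-target amplicons predicted blocked: 0/100 (0.00%)
no non-target amplicon is predicted to be blocked
```

Every host amplicon carries the blocker's full footprint — including the
host-specific mismatch inside the primer overlap — so all 100 are predicted
removed, while no divergent non-target matches the 24-mer exactly. The top
candidate is written to `design_out/blocking_primer.fasta` with a `/3SpC3/`
ordering suffix, and `synthesis_note.yaml` records the standard blocking
protocol defaults (3' C3 spacer; 1.5:1 blocking:target ratio; 1.2 µM).

To audit any oligo — for instance the published snail blocker against your
own Silva snapshot:

```sh
hostblock evaluate TCTTGACTAATGAAAACATTCTTGACAA silva_ssu.fasta -o audit_out
```

The same stages are available as a library: see
`hostblock.design_blocker(...)` for the one-call pipeline.

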
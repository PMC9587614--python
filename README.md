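# ltdrscan

Structural annotation of **LTDR-bounded composite DNA transposons** —
elements of the KolobokP lineage whose internal region (INT) is flanked
by two long terminal *direct* repeats (LTDRs), each carrying its own
short terminal inverted repeat (TIR) and the Kolobok 5'-RR..YY-3'
terminal signature.

It is written for curators and comparative genomicists who need to take
a genome plus a small part library (LTDR and INT consensi) and produce:

* every copy of each part, on both strands (`scan`);
* each insertion locus parsed into the structural vocabulary
  **solo LTDR** (`L`), **monomer** (`L-I-L`), **shared-LTDR multimer**
  (`(L-I)ⁿ-L`, n ≥ 2), **tandem-INT array** (`L-Iᵐ-L`, m ≥ 2, with
  3–4-bp micro-deletions at the INT–INT junctions), the partial forms
  **LTDR-INT**, **INT-LTDR**, **solo INT**, or **COMPLEX** — gated on a
  recognizable target site duplication (TSD) (`annotate`);
* per-family census tables with the dimer fraction
  `round(100·dimers/multimers)` and mean copy-to-consensus diversity;
* a rebuilt family consensus: greedy 75 %/75 % clustering, star
  alignment, 50 %-majority consensus, iterative 5-kb flank extension,
  and terminus calling from signature + TIR + TSD evidence
  (`consensus`);
* excision footprints for partial insertions sitting inside another
  repeat family: the reconstructed pre-insertion ("empty") site and the
  inferred one-sided deletion of 0–5 flanking bases, with all ambiguous
  readings ranked (`footprint`).

A bundled synthetic-genome simulator (`simulate`) plants every one of
these structures with exact ground truth, so the entire pipeline is
testable without downloading a genome.

## Worked example

Write a small study configuration (150-kb genome, 13 insertions
spanning all seven architectures, divergence 0) to `small.yaml`:

```yaml
seed: 5
genome_length: 150000
divergence: 0.0
min_spacing: 1500
count_monomer: 3
count_solo_ltdr: 3
count_multimer: 2
count_tandem_int: 2
count_ltdr_int: 1
count_int_ltdr: 1
count_solo_int: 1
```

then run the three stages:

```sh
ltdrscan simulate --config small.yaml --out demo
  # writes demo/genome.fasta, demo/truth.tsv, demo/parts.fasta
ltdrscan annotate demo/genome.fasta demo/parts.fasta --config small.yaml --out demo/ann
ltdrscan consensus demo/genome.fasta demo/parts.fasta --config small.yaml --out demo/cons
```

`annotate` prints:

```
[ltdrscan 0.1.0] annotate seed=5
41 hits, 13 loci (13 with recognizable TSDs), 2 families
```

and `demo/ann/census.tsv` holds one row per family in the familiar
census column order:

```
family_id  diversity_pct  monomer  solo_ltdr  multimer  dimer  ltdr_int  int_ltdr  solo_int  tandem_int  complex  dimer_fraction_pct
FAM450     0.0            2        2          1         1      0         1         0         2           0        100
FAM660     0.0            1        1          1         0      1         0         1         0           0        0
```

Reading the first row: family FAM450 (473-bp LTDR class) has 2 intact
monomers, 2 solo LTDRs, 1 multimer which is a dimer (hence a dimer
fraction of 100 %), 1 INT-LTDR partial and 2 tandem-INT arrays, all
flanked by exact TSDs; copies are identical to the consensus
(diversity 0.0 %).  `consensus` then reports

```
FAM450: 2637 bp, evidence=signature,tir,tsd, confidence=ok
FAM660: 2453 bp, evidence=signature,tir,tsd, confidence=ok
```

— both rebuilt consensi match the planted elements exactly, with all
three terminus-evidence tests (RR..YY signature, TIR, member TSDs)
passing, and `demo/cons/consensus.fasta` contains each element plus its
`:LTDR` / `:INT` split.

The same stages are available as a library:

```python
from ltdrscan.config import RunConfig
from ltdrscan.pipeline import annotate
from ltdrscan.io import read_fasta

result = annotate(read_fasta("demo/genome.fasta"),
                  read_fasta("demo/parts.fasta"), RunConfig())
for cluster, call in zip(result.clusters, result.calls):
    print(cluster.outer, call.label, call.tsd and call.tsd.tsd)
```

## Layout

| module | role |
| --- | --- |
| `ltdrscan.core` | alphabet, intervals, affine-gap alignment, TIR / signature / TSD detectors |
| `ltdrscan.simulate` | synthetic genomes with planted insertions and truth records |
| `ltdrscan.scanner` | seed-and-extend part-copy detection (both strands) |
| `ltdrscan.classify` | locus grouping, architecture grammar, TSD gating, censuses |
| `ltdrscan.consensus` | clustering, star MSA, majority consensus, flank extension, termini |
| `ltdrscan.footprint` | empty-site reconstruction and excision-footprint inference |
| `ltdrscan.oracles` | brute-force reference implementations used in validation |
| `ltdrscan.pipeline` / `ltdrscan.cli` | stage drivers and the `ltdrscan` command |
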
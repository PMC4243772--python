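# alncat

Multiple-sequence-alignment processing and supermatrix concatenation for
phylogenetics, as a Python library and a pipeline-friendly command-line
tool.

Phylogenomic studies routinely juggle hundreds of per-gene alignments
that need renaming, translating, recoding, filtering, and finally
concatenating into one supermatrix with partition coordinates for
RAxML/MrBayes. `alncat` chains these steps in a single run, in one fixed
hierarchical order:

1. sequence renaming (tab-delimited old→new map)
2. sequence translation — nucleotide → amino acid with IUPAC-ambiguity
   resolution, or amino acid → compressed IUPAC codons
3. consensus generation for predefined sequence blocks
   (most-frequent / majority-rule / strict)
4. RY coding (whole sequences or third codon positions)
5. exclusion of every third codon position
6. concatenation into a supermatrix, padding missing taxa
   (`N` / `X` / `.` by data type) and tracking per-gene partitions
7. extraction of parsimony-informative sites
8. output: FASTA / PHYLIP / NEXUS (optionally with a MrBayes charset
   block), RAxML and MrBayes partition files, and plain-text reports

Chains that contradict this flow (e.g. RY coding *before* translation)
are rejected up front — run the tool twice for those.

## The rules at the core

* **Ambiguity-aware translation.** A triplet containing IUPAC codes is
  expanded into every concrete codon it covers; the amino acid is
  emitted only if all of them agree, otherwise `?`. So `YTR` → `L`
  (TTA/TTG/CTA/CTG are all leucine) but `RCT` → `?` (ACT is Thr, GCT is
  Ala). Incomplete triplets give `?`, all-gap triplets give `-`.
  Reverse translation compresses an amino acid's codon set position-wise
  into IUPAC codes (`L` → `YTN`, lossy by construction).
* **Consensus.** Majority rule requires a state in strictly more than
  50 % of the block's sequences (gap-bearing rows stay in the
  denominator). Strict consensus returns the IUPAC code covering every
  base observed, ignoring `-`/`?` while any base exists; an all-gap
  column is `?`.
* **RY coding.** A/G/R → `R`, C/T/U/Y → `Y`; gaps and `?` are kept;
  ambiguity codes spanning both classes become `?`.
* **Parsimony-informative site.** A column with at least two concrete
  states (gaps and ambiguity codes don't count) each occurring at least
  twice.
* **Dot-bracket structure strings** are stack-parsed into stem pairs and
  loop positions, reported in both infile and supermatrix coordinates.

## Worked example

Two genes, one mitochondrial nucleotide fragment and one nuclear
protein fragment, with chimp missing from the protein gene:

```sh
alncat -i cox1.fas -i rag1.phy --concat --partitions \
       --out-format fasta --out-format nexus --mrbayes-block \
       --out-dir out
```

stderr log:

```
INFO read 2 input file(s)
INFO supermatrix: 3 taxa x 23 columns, 2 partition(s), 1 padded cell(s)
INFO wrote 5 output file(s) to out
```

`out/supermatrix.fas` — chimp's missing protein fragment is padded with
`X`:

```
>Homo_sapiens
ATGGCACTGTGGATGMKLFWEQD
>Pan_troglodytes
ATGGCYCTGTGGATGXXXXXXXX
>Mus_musculus
ATGGCTTTATGGATGMKIFWEQD
```

`out/partitions_raxml.txt` — the nucleotide gene is labelled `DNA`; the
protein gene carries a placeholder model label (`WAG`) since best-fit
model selection is delegated to external tools:

```
DNA, cox1 = 1-15
WAG, rag1 = 16-23
```

`out/info_report.txt` lists, per input and for the supermatrix, taxon
counts, lengths, sequence types, character compositions, GC content
(0.5000 for cox1 here), each fragment's coordinate range, and every
inserted replacement string (`Pan_troglodytes in rag1`).

The same run is available programmatically:

```python
from alncat import RunConfig, run_pipeline
summary = run_pipeline(RunConfig(inputs=["cox1.fas", "rag1.phy"],
                                 concatenate=True, out_dir="out"))
summary.supermatrix.partitions   # [Partition('cox1', 1, 15, ...), ...]
```

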
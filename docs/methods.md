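# Methods

## Scope and model

`alncat` treats a phylogenomic data set as an ordered list of per-gene
alignments, each an equal-length set of uniquely named sequences of one
data type — nucleotide, amino acid, or dot-bracket secondary structure.
Processing is a fixed eight-stage pipeline (rename → translate →
consensus → RY → third-position exclusion → concatenate → informative
extraction → output); every stage is the identity when disabled, and a
configuration that would need a stage to run *before* an earlier one is
rejected at validation, before any file is read. This keeps a single
run deterministic and makes two-pass workflows (e.g. RY-code first,
translate in a second invocation) explicit rather than silently
reordered.

## Sequence-type detection

No published heuristic exists for calling a file nucleotide vs protein,
so the detector is a documented stand-in: a string whose informative
characters are all `(`/`)`/`.` is structure; otherwise it is nucleotide
when at least 95 % of its non-gap, non-`?` characters are A/C/G/T/U/N,
else amino acid. The 95 % margin tolerates occasional ambiguity codes
(R, Y, W, …) without misclassifying proteins, and the
structure → nucleotide → amino-acid priority order is essential because
any DNA string is also a character-wise legal protein string.

At file-read time the non-structure records of a file are typed from
their *pooled* residues rather than individually. A 10-residue peptide
that happens to spell only alanine/cysteine/glycine/threonine letters
would otherwise be called DNA and the file spuriously rejected as
mixed-type; pooling makes the per-file homogeneity assumption (one
file, one data type) robust for short sequences. `detect_seqtype`
itself remains a pure per-string function.

## Translation

The standard genetic code (Biopython's table 1) is used; frame is fixed
at +1 and never inferred — reading frames are the user's
responsibility, and the only guard is a warning when an alignment
length is not a multiple of three (the trailing incomplete triplet
becomes one `?` column). A triplet is resolved by expanding each
position through the IUPAC ambiguity sets, translating every concrete
codon, and emitting the amino acid only on unanimity. `?` inside a
triplet expands like N; a gap mixed with bases is unresolvable (`?`);
a pure-gap triplet stays an indel (`-`), preserving codon-aligned gap
columns. Stops translate to `*`; an expansion mixing stop and sense
codons is `?` by the same unanimity rule. Expansions that agree on a
*stop* (e.g. TRA = TAA/TGA) therefore yield `*`, not `?`.

Reverse translation uses position-wise IUPAC compression of the amino
acid's codon set. This convention is lossy upward: the compressed
triplet always expands to a superset of the true codon set (property-
tested), never a subset — e.g. `L` → `YTN`, which also covers the
phenylalanine codons TTT/TTC. B, Z, and J compress the unions of the
D/N, E/Q, and I/L codon sets respectively; `X` and `?` give `NNN`, `-`
gives `---`.

## Consensus

Frequency-based rules (most-frequent, majority) count input ambiguity
codes as their own states, which keeps frequencies well defined; the
strict rule expands them into the base union. The majority denominator
is the full block size including gap-bearing rows, and the threshold is
strict — exactly 50 % yields `?`. Most-frequent ties among plain bases
collapse to the covering IUPAC code; ties involving ambiguity codes,
and all amino-acid ties, yield `?` (the source behaviour for the
nucleotide tie case is ambiguous between IUPAC and `?`; this dialect is
ours and is asserted only as such). A consensus state is never a gap:
a column of only `-`/`?` is `?` under every rule. Consequently, the
"single-sequence block is an identity" property holds exactly at
gap-free columns; a lone gap column intentionally becomes `?`.

Blocks are defined in a small text dialect (`name : member1,member2`),
one block per line, unique names, disjoint membership, applied per
input file; a block member absent from a file is an error rather than
silently skipped.

## RY coding and third positions

Purines (A, G, R) map to R and pyrimidines (C, T, U, Y) to Y; `-` and
`?` pass through. Ambiguity codes spanning both classes (W, S, K, M, B,
D, H, V, N) are converted to `?` rather than left verbatim, because a
two-state RY matrix downstream cannot interpret them. The encoding is
idempotent. "Third positions" means columns ≡ 0 (mod 3), 1-based, of
each input alignment — i.e. frame-1 codon third positions; exclusion
removes those columns (output length `L − ⌊L/3⌋`). Third-position RY
coding and third-position exclusion are mutually exclusive in one run.

## Concatenation

Taxa are matched by exact name; the supermatrix row order is first
appearance across inputs in input order (a deterministic choice — the
alternative, alphabetical order, is equally defensible but less stable
under renaming). Gene names are input-file stems, with numeric suffixes
for duplicate stems. Missing (taxon, gene) cells receive pad strings —
`N` (nucleotide), `X` (amino acid), `.` (structure) — and each padded
cell is recorded. The partition map is contiguous, 1-based, inclusive,
and sums to the supermatrix length by construction. The inverse
operation, `slice_partition`, drops exactly the recorded padded rows
rather than rows that *look* padded, since a genuine all-dot structure
row is indistinguishable from a `.` pad by content alone.

## Parsimony-informative sites

A column is informative iff at least two concrete states each occur at
least twice. Gaps, `?`, ambiguity codes, and `*` are not states (the
usual convention in tree software; whether the original counts gaps as
a fifth state is unrecorded, so the exclusion is documented here). U
and T are identified as one state so RNA and DNA inputs behave
identically. The classifier is column-local and row-permutation
invariant, and is checked against a brute-force counting oracle on
random columns.

## File formats

FASTA, CLUSTAL, and PHYLIP are read with automatic detection from the
first line; FASTA, relaxed-sequential PHYLIP, and NEXUS are written.
The PHYLIP dialect is relaxed (full names, whitespace-delimited) since
strict 10-character names truncate modern taxon identifiers; strict
files are still accepted on read. CLUSTAL/PHYLIP parsing is delegated
to Biopython; the FASTA reader is local to support blank-line body
concatenation and line-numbered errors; the NEXUS writer is local so a
minimal MrBayes block (charsets + `partition combined` + `set
partition`, no model commands) can be appended. Mixed-type
supermatrices are written with a `DATATYPE=MIXED(...)` span list. GC
content is (G+C)/(A+C+G+T+U), ignoring ambiguity codes, gaps and `?` —
an unambiguous, reproducible denominator.

## Synthetic data

The fixture generator emulates a small multi-gene data set: 8 taxa and
4 genes by default, per-gene lengths 30, 45, 60, … (multiples of three,
so the nucleotide genes read as in-frame coding sequence), alternating
nucleotide/amino-acid genes, 5 % gap rate, and 20 % missing-taxon
probability per (taxon, gene) with one anchor taxon always present —
roughly the incompleteness regime of real supermatrix studies. A few
columns per gene are overwritten to be parsimony-informative by
construction and recorded as ground truth. Files rotate through FASTA,
PHYLIP, and CLUSTAL so multi-format input is exercised by default
(structure genes are always FASTA; brackets collide with the other
formats' syntax). All randomness flows from one `random.Random(seed)`;
equal seeds give byte-identical files.

What the generator does **not** emulate: phylogenetic correlation
between sites or taxa (residues are i.i.d.), realistic base
composition or codon usage, indel placement along a guide tree, or
alignment error. Passing tests therefore demonstrate the correctness
of the *bookkeeping and per-column rules* on arbitrary content, not
biological plausibility of inferences drawn downstream.

## Verification sizes and numerical choices

The acceptance script checks the translation resolver against
brute-force expansion over all 16³ = 4,096 ambiguity triplets, locates
the informative-frequency boundary, the majority threshold, and the
length-warning divisor by scanning (never by reading constants), and
runs 100 concatenation fixtures, 100 × 3 format round-trips, 3 × 1,000
consensus-property columns, and 1,100 dot-bracket strings — a few
seconds in total on one core. There is no floating-point machinery
anywhere except the GC ratio; all comparisons are exact string/count
equality, so no tolerances are needed.

## Known limitations

Only the standard genetic code; no frame inference or ORF handling; no
NEXUS input; no pseudoknot bracket alphabets; no ortholog selection or
missing-data-based gene filtering; best-fit protein model selection is
delegated to external tools (the RAxML partition file carries a
configurable placeholder label, default WAG). Renaming is exact-match
only; there is no pattern-based renaming or name sanitisation.
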
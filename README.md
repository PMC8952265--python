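# gutreads

Prey identification from shotgun sequencing of predator gut contents — and
the laboratory verification and statistics that go with it.

## The problem

Diet analysis of arthropod generalist predators works from gut-content DNA
that is heavily degraded by digestion and overwhelmingly dominated by the
predator's own DNA. Two detection strategies are in use: **metabarcoding**
(PCR enrichment of a barcode such as 16S, then sequencing and reference
assignment) and **assembly-free read mapping** — shotgun-sequence the whole
DNA community and map unassembled reads against a database of annotated
reference mitogenomes. Metabarcoding is cheap per sample but hostage to
primer–template complementarity; read mapping needs no primers and its read
counts can carry quantitative signal, but rare prey fragments are sampled
without amplification. `gutreads` implements the read-mapping detection
pipeline together with the melt-curve verification caller, qPCR
quantification, and the confusion-matrix framework used to compare methods.

## What is in the package

**Detection pipeline** (`gutreads.lazaro`). Starting from BLASTn tabular hits
(extended `outfmt 6` with aligned `qseq`/`sseq` columns) of reads against
annotated mitogenomes:

1. *Mismatch reanalysis* — per-column comparison of the aligned strings;
   a reported mismatch against a degenerate IUPAC reference code (R = A/G,
   Y = C/T, ...) whose expansion contains the query base is a *false
   mismatch* and is credited back, giving a corrected percent identity
   `100·(L − gaps − true_mismatches)/L`.
2. *Overlap–identity threshold* — keep hits with corrected identity ≥ 100%
   over ≥ 130 aligned bases (both configurable).
3. *Best-hit assignment* — per read, rank passing hits by corrected
   identity, overlap, bitscore; ties across species discard the read as
   ambiguous.
4. *Coding-region filter* — ≥ 50% of the alignment must fall inside
   annotated CDS/rRNA/tRNA features of the reference.
5. *Singleton elimination* — a species needs ≥ 2 supporting reads per
   sample; the predator's own species is reported on a separate channel
   (indistinguishable from a cannibalized conspecific).

**Melt-curve verification** (`gutreads.mca`). −dF/dT from raw fluorescence by
local quadratic fits; median baseline; peak extraction; the replicate-
consensus call: positive iff ≥ 2 technical replicates show a peak more than
0.1 above background (or one replicate more than 0.2) at the expected Tm
± 0.5 °C, with a no-positive-control variant requiring a shared single sharp
Tm across ≥ 3 replicates.

**qPCR quantification** (`gutreads.qpcr`). Window-of-linearity efficiency
estimation (E = 10^slope of log₁₀ signal vs cycle over the most informative
4–6 cycle window), Cq by interpolating the threshold crossing, relative
starting template N0 = Fq/E^Cq, and the theoretical limit of detection at
Cq = 40 (upper 95% CI of the geometric mean of replicate extrapolations).

**In-silico PCR** (`gutreads.insilico_pcr`). IUPAC-aware ungapped primer
scanning (≤ 2 mismatches, exact 3′-terminal anchor) and amplicon extraction,
to predict which templates a barcode primer pair can and cannot amplify.

**Evaluation** (`gutreads.evaluation`). TP/FP/TN/FN classification of
detections against melt-curve verification (a verified species absent from a
method's reference database is excluded, not a false negative); sensitivity,
specificity, FDR, FOR, accuracy; Welch and paired t-tests, logistic
regression of verification on ln reads (Wald χ²), Pearson correlation with
Fisher-transform p-values.

**Synthetic data** (`gutreads.synthetic`). Generators with known ground
truth for every input: annotated reference databases, digested gut read
mixtures (dominant predator + trace prey, truncated-lognormal fragment
lengths), sigmoid melt curves, saturating amplification curves — plus a
Smith–Waterman oracle aligner standing in for BLASTn at desk scale.

**Bundled benchmark** (`gutreads.datasets`). Published observations from a
field study of five epigeal predators (27 libraries) and a known-diet
ladybird feeding trial, used by the evaluation examples and acceptance
checks.

## Worked example

```python
from gutreads.lazaro import LazaroConfig, run_lazaro
from gutreads.synthetic import (GutCommunitySpec, make_reference_db,
                                oracle_align, simulate_gut_reads)

db = make_reference_db(seed=8, n_species=4, genome_len=4000)
spec = GutCommunitySpec(seed=9, n_reads=500,
                        proportions={"Species_00": 0.92, "Species_01": 0.03,
                                     "Species_02": 0.03, "Species_03": 0.02})
reads, truth = simulate_gut_reads(spec, db)
result = run_lazaro(oracle_align(reads, db), db,
                    LazaroConfig(predator_species="Species_00"))
print(result.prey[["species", "read_count"]])
print(result.audit["status"].value_counts())
```

prints

```
   species  read_count
Species_03           3

unassigned    460
counted        39
singleton       1
```

Species_03 is detected with 3 coding-region reads ≥ 130 bp at exact
identity. Species_02 contributed exactly one qualifying read and is removed
as a singleton; most reads are unassigned because digestion leaves fragments
below the 130-bp overlap requirement — exactly the behaviour the strict
threshold is designed to produce (specific detections at the cost of
sensitivity for rare, highly fragmented prey). The same run from a shell:

```bash
gutreads simulate refdb --seed 8 --n-species 4 --outdir refdb/
gutreads lazaro --hits hits.tsv --ref refdb/references.fasta \
    --annot refdb/references.gff3 --taxonomy refdb/taxonomy.csv \
    --predator Species_00 --outdir out/
```

More narrative examples are in `examples/` (melt-curve calls, qPCR
quantification and LOD, primer mismatch checking, the field-survey
comparison).

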
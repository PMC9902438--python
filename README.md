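# cubkit — codon usage bias toolkit

Every organism uses the 64 codons of the genetic code with its own
characteristic bias, and that bias carries signal: the 64 codon usage
frequencies of a genome's coding DNA are enough to predict which kingdom
an organism belongs to (archaea / bacteria / eukaryote / bacteriophage /
virus) and which cellular compartment its coding DNA comes from
(nuclear / mitochondrial / chloroplast).  `cubkit` packages that
observation into three tools for sequence analysts and comparative
genomicists:

1. **Statistical ORF screening.**  Any (start codon, in-frame stop
   codon) pair is a *potential* open reading frame, and potential ORFs
   vastly outnumber real genes.  `cubkit` enumerates all of them and
   rejects the implausible ones with a goodness-of-fit test of their
   codon usage against a reference organism's distribution.  With
   observed in-frame counts `O_i` and expected counts
   `E_i = n * p_i` scaled from the reference frequencies `p_i`,

       chi2 = sum_i (O_i − E_i)^2 / E_i ,

   with `k − 1` degrees of freedom over `k` retained codons; the
   candidate is rejected when `chi2 > chi2_{1−alpha, k−1}` (codons with
   zero reference frequency are removed from both sides; a Cressie–Read
   power-divergence variant, lambda = 2/3, keeps all 64 bins instead).
2. **Codon influence ranking.**  Which codons carry the taxonomic
   signal?  Two independent rankers: the lasso regularization path
   (`min ||Y − Xb||² + alpha ||b||₁`, swept over a dense alpha grid,
   scoring each codon by how many fits its coefficient survives) and
   random-forest impurity importance.  Their top-20 intersection is the
   consensus codon set, which also makes ORF screening markedly less
   trigger-happy when the test is restricted to it.
3. **A classification harness** — stratified splitting, k-fold CV,
   from-scratch Euclidean k-NN and Gaussian naive Bayes, a hard-voting
   {k-NN, SVM, RF} ensemble with tuned presets, the full confusion-matrix
   metric suite (accuracy, per-class/micro/macro precision, recall, F1,
   one-vs-rest trapezoid AUC), PCA-reduced classification, and a K-Means
   cluster survey.

A Dirichlet-multinomial synthetic-data module generates labeled usage
tables and plasmid-like sequences with known ground truth, so the whole
pipeline is testable without downloading anything.  Real inputs are
supported through FASTA (sequences) and the CUTG-derived labeled
usage-table CSV dialect (columns `Kingdom, DNAtype, SpeciesID, Ncodons,
SpeciesName` plus the 64 codon columns).

## Worked example

Simulate a 1.9 kb plasmid-like sequence with one embedded 120-codon
gene, then screen every potential ORF against the generating reference:

```bash
cubkit simulate plasmid --orfs orfs.json --background 1500 --seed 7 \
    --out plasmid.fa --truth truth.json
# wrote 1860 nt with 1 embedded ORFs -> plasmid.fa

cubkit screen-orfs --fasta plasmid.fa --reference ref.json --out report.tsv
# screened 293 potential ORFs (293 tested, 270 rejected, 0 untestable) -> report.tsv
```

(`orfs.json` is `[{"reference": "ref.json", "n_codons": 120}]`;
`ref.json` maps each codon to its reference frequency.)

The 1860 nt sequence contains 293 potential ORFs — start/stop pairs in
frame — of which only one is a real gene.  The test rejects 270 of the
spurious candidates at alpha = 0.05.  The embedded gene (coordinates
938–1295 in `truth.json`) survives:

```
start  stop  n_codons  statistic   p_value  rejected
  938  1295       120    80.5864  0.066932  False
```

Restricting the test to the shipped consensus codon subset
(`--subset consensus`, the 11 codons in the top 20 of both published
rankings) makes screening more conservative — 155 rejections instead of
270, embedded gene retained at p = 0.14 — the mode intended for use
alongside a real annotation pipeline.

From Python, the same machinery is a library:

```python
from cubkit import chi_square_gof, enumerate_potential_orfs, screen_orfs

orfs = enumerate_potential_orfs("AUGAUGAAAUAA")   # [(0, 9), (3, 9)]
table = screen_orfs(sequence, reference, codon_subset=consensus, alpha=0.05)
```

## Layout

- `src/cubkit/codon_core.py` — codon alphabet, genetic code, counting
- `src/cubkit/io_formats.py` — FASTA / usage-table / reference / report I/O
- `src/cubkit/orf_screen.py` — enumeration + goodness-of-fit rejection
- `src/cubkit/feature_ranking.py` — lasso path, RF importance, consensus
- `src/cubkit/classify.py` — splitting, classifiers, metrics, clustering
- `src/cubkit/synthetic_data.py` — Dirichlet/multinomial generators
- `src/cubkit/cli.py` — the `cubkit` command
- `docs/methods.md` — models, assumptions, numerical choices
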
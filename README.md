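# phosite

Kinase-independent phosphorylation-site prediction from evolutionary
(PSI-BLAST PSSM) profiles.

A candidate site is any serine, threonine or tyrosine residue of a
protein.  For each candidate, the rows of the protein's L×20
position-specific scoring matrix inside a window of W consecutive
positions centered on the site are flattened into a 20·W feature vector
and classified by a per-residue RBF support vector machine (C = 1,
γ = 1/k with k = 20·W, hard ±1 labels).  Training data are built with:

- **a distance rule for negatives** — a non-annotated S/T/Y site is
  negative only if it is more than 50 residues away from every annotated
  phosphosite of its protein (any residue type); nearer sites are
  excluded from both classes;
- **stride subsampling for class balance** — negatives are reduced
  toward a target negatives-per-positive factor (2, 1.5, 1 or 0.5) by
  keeping every r-th negative, r = max(1, ⌊n/(factor·p)⌋), positives
  untouched;
- **stratified 3-fold cross-validation** reporting Ac, Sn, Sp, Mcc and
  FPR per (residue, window, ratio) cell, plus the (FPR, TPR) ROC point
  of each cell and benchmark sensitivity (Q3).

A synthetic-data module generates complete phosphoproteome fixtures
(FASTA, blastpgp-style ASCII PSSMs, annotation TSVs and gold labels)
with a planted, width-controlled window signal, so the full pipeline is
testable without PSI-BLAST, the nr database, or any external dataset.

## Command-line usage

```sh
# generate a synthetic fixture with a planted signal
phosite simulate --out fixtures/ --seed 1 --n-proteins 100 --effect-size 4

# label + window + balance instances for one residue type
phosite build --profiles fixtures/ --annotations fixtures/annotations.tsv \
    --residue S --window 9 --ratio 1 --out instances.svm

# the full ratio x window x residue cross-validation grid
phosite cv --profiles fixtures/ --annotations fixtures/annotations.tsv \
    --out cv/ --seed 1

# train the 15 default bundles (3 residues x 5 windows)
phosite train --profiles fixtures/ --annotations fixtures/annotations.tsv \
    --out models/ --seed 1

# predict every S/T/Y site of one protein (window 15 by default)
phosite predict --sequence P16386.seq --pssm P16386.pssm \
    --models models/ --out predictions.tsv

# score predictions against gold labels (Ac/Sn/Sp/Mcc/FPR + Q3)
phosite evaluate --predictions predictions.tsv --gold fixtures/gold.tsv \
    --out metrics.json
```

Input PSSMs are the ASCII matrices written by PSI-BLAST's
`blastpgp -Q` option; `phosite.profile_io.blastpgp_command()` prints the
exact external command for generating one (it is never executed by this
package).  Sequences may be FASTA or raw single-sequence text.
Annotation tables are TSV with columns `protein_id`, `position`
(1-based), `residue`.

Exit codes: 0 success, 2 configuration error, 3 data error,
4 missing/mismatched model.

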
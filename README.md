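# aquapred

Sequence-based prediction of aquaporins (AQPs) — the conserved channel
membrane proteins that transport water and small solutes — from protein
FASTA input. The package re-implements, as a tested and reusable library +
CLI, the classical pipeline for this problem:

1. **188D GPSD encoding.** Each sequence becomes a 188-dimensional global
   protein sequence descriptor: 20 amino-acid composition (AAC) frequencies
   plus, for each of 8 physicochemical properties (hydrophobicity, van der
   Waals volume, polarity, polarizability, charge, surface tension,
   secondary structure, solvent accessibility), a 21-feature
   composition/transition/distribution (CTD) block. A property partitions
   the 20 amino acids into 3 groups; C records group frequencies, T records
   cross-group adjacency frequencies, and D records the relative positions
   of the first/25%/50%/75%/last residue of each group. 188 = 20 + 8 × (3 +
   3 + 15).
2. **ANOVA F-score ranking + incremental feature selection (IFS).** Each
   feature is scored by F = MSB/MSW (between- over within-class mean
   square, two classes); IFS sweeps rank-ordered feature prefixes under
   cross-validated accuracy and keeps the smallest best prefix.
3. **Classification.** Six classifier families behind one interface —
   random forest (default), naive Bayes, SVM, gradient boosting (XGBoost),
   logistic regression, decision tree — evaluated by stratified k-fold
   cross-validation with Sn, Sp, Acc (percent), MCC and rank-based AUROC:

   Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/N,
   MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

Because the biological signal that separates AQPs from other proteins is
their six-transmembrane-helix architecture, the most informative features
are hydrophobicity-derived — canonically feature 21 (hydrophobic
composition) and feature 26 (neutral↔hydrophobic transition). The package's
feature ordering pins those indices, and its synthetic benchmark (below) is
built so a correct pipeline recovers exactly that signal.

It also ships a class-ratio dataset assembler (positives:negatives 1:1,
1:2, …, all) for imbalance experiments, and a synthetic sequence generator
producing transmembrane-like positives (hydrophobic segments alternating
with polar loops) and background-composition negatives, with a tunable
enrichment dial whose value 1 gives an exchangeable null benchmark.

Intended users: bioinformaticians building or auditing protein-family
predictors from physicochemical sequence descriptors, and anyone needing a
clean, tested 188D/CTD encoder.

## Worked example

```python
import aquapred as ap

records, _ = ap.gen_benchmark(ap.SynthConfig(seed=0))          # 150 + 150 sequences
fm = ap.encode_matrix(records)                                 # 300 x 188 matrix
ranking = ap.anova_f(fm)
top = int(ranking.order[0])
print(f"top ANOVA feature: #{top + 1} {fm.feature_names[top]} (F = {ranking.f_scores[top]:.1f})")
report = ap.stratified_kfold(fm, ap.ClassifierSpec(seed=42), k=10, seed=0)
m = report.mean
print(f"RF 10-fold CV: Sn {m.sn:.3f}%  Sp {m.sp:.3f}%  Acc {m.acc:.3f}%  MCC {m.mcc:.4f}  AUROC {m.auroc:.4f}")
```

prints

```
top ANOVA feature: #21 hydrophobicity.C.hydrophobic (F = 2418.0)
RF 10-fold CV: Sn 99.333%  Sp 99.333%  Acc 99.333%  MCC 0.9871  AUROC 1.0000
```

The top-ranked feature is the hydrophobic-group composition (feature 21) —
the generator injects its class signal only through hydrophobic-residue
enrichment inside segments, and ANOVA recovers it; the random forest then
separates the classes almost perfectly under 10-fold cross-validation
(Sn/Sp/Acc in percent, MCC and AUROC unit-scale).

## Command line

```sh
aquapred synth --n-pos 150 --n-neg 150 --seed 0 fixture/   # FASTA pair + truth.json
aquapred encode fixture/positive.fasta fixture/negative.fasta matrix.csv
aquapred ifs matrix.csv --classifier random_forest -k 10 --seed 0 run
aquapred predict run.model.joblib new_sequences.fasta predictions.tsv
aquapred ratio-sweep fixture/positive.fasta fixture/negative.fasta \
    --ratios 1,2 --classifiers random_forest,naive_bayes out.tsv
```

Results go to files (TSV/CSV/JSON, model files via joblib); logs go to
stderr; every command writes a JSON run manifest recording inputs, seeds
and package version.

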
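# rpiscore

Sequence-based scoring of RNA–protein interaction propensity.

Each RNA is encoded into three per-residue numeric channels (secondary-structure
pairedness over an ensemble of predicted foldings, hydrogen-bonding propensity,
van der Waals propensity) and each protein into five (Chou–Fasman propensity
selected by predicted secondary-structure state, plus Grantham, Zimmerman,
Kyte–Doolittle and Bull–Breese scales). Every channel is compressed to a fixed
number of cosine-series terms (default 10). Five (protein, RNA) channel
pairings are scored with bilinear forms trained as closed-form Fisher linear
discriminants on the flattened outer-product features; each raw score is
calibrated onto (0, 100) via an arctangent map anchored at the two class means,
and the calibrated scores are averaged into a final interaction score with a
natural decision cutoff of 50.

The package also contains the training-set construction machinery (chain
extraction from PDB-format complexes, least-atom-distance labeling at a strict
5 Å cutoff, RNA length filtering, sequence-identity redundancy removal,
evidence-code classification, negative-set shuffling), the evaluation measures
(discriminative power, MCC, accuracy, stratified k-fold cross-validation), and
deterministic synthetic generators used by the test suite.

## CLI

The console script `rpiscore` exposes the full workflow:

```sh
# build a labeled dataset from PDB-format files
rpiscore build-dataset --pdb-dir pdbs/ --cutoff 5.0 --out-prefix train

# train the five channel discriminants
rpiscore train --pairs train.pairs.tsv --rna train.rna.fa \
    --protein train.protein.fa --out model.json --dim 10 --nstruct 6

# score pairs (per-channel raw + calibrated scores and the fused final score)
rpiscore predict --model model.json --rna rna.fa --protein prot.fa \
    --pairs pairs.tsv --out scores.tsv

# evaluate / cross-validate
rpiscore evaluate --model model.json --pairs test.tsv --rna rna.fa \
    --protein prot.fa --out report.tsv
rpiscore crossval --pairs train.pairs.tsv --rna train.rna.fa \
    --protein train.protein.fa --k 4 --seed 7

# generate a planted-rule synthetic dataset
rpiscore simulate --n-pairs 400 --separation 4 --noise 0.1 --seed 1 \
    --out-prefix sim
```

A TOML config file (`rpiscore --config run.toml <cmd>`) overrides defaults and
flags override the file; every command writes its resolved configuration as
`<out>.config.json` next to its outputs, so runs are reproducible from the
emitted config plus seed.

Backends are pluggable: the built-in RNA folder is a maximum base-pairing
(Nussinov-style) co-optimal enumerator and the built-in protein
secondary-structure predictor uses propensity-window rules; adapters ingest
externally computed dot-bracket ensembles (`rpiscore.folding.PrecomputedFolder`)
and 3-state strings (`rpiscore.protein_ss.PrecomputedSsPredictor`). Propensity
tables ship as editable TSVs under `src/rpiscore/data/` and trained models
embed the exact tables used. The RNA hydrogen-bond / van der Waals tables are
provisional defaults (see the file headers); replace them with values derived
from interface contact statistics for exact reproduction of published scores.

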
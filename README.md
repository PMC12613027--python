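# lysocleave

Cleavage-site prediction and in-silico proteolytic digestion for lysosomal
proteases.

The package models protease specificity two ways, mirroring substrate
availability:

* **Scoring matrices** — for well-characterised proteases (CTSB, CTSD, CTSK,
  CTSL, CTSS, CTSV, LGMN), per-feature position-specific scoring matrices are
  trained from aligned 8-residue cleavage windows (P4–P4′) over five parallel
  character tracks: amino-acid identity, charge (`+`/`N`/`-`), hydropathy
  (`ζ`/`M`/`Φ`), secondary structure (`C`/`E`/`H`) and solvent accessibility
  (`0`–`9`). Positional log2 enrichment over background is min-max scaled to
  [0, 1]; a candidate site's score is the mean of its 8 lookups per feature
  (optionally a weighted sum using random-forest feature importances), and a
  decision threshold is calibrated from a precision–recall sweep.
* **Consensus patterns** — for low-substrate proteases (BACE1, CPQ, CTSC,
  CTSF, CTSH, CTSO, PRCP, SPPL2A/B, TPP1), slash-delimited 8-position
  patterns such as `EG/VIL/x/LF|x/AV/x/VF` are parsed and matched directly.

Predicted sites feed three digestion modes: **complete** (all cuts applied),
**partial** (all adjacent-segment combinations) and **sequential** (proteases
act in a user-given order; sites straddling an earlier cut are lost and a
minimum-length filter applies to the final output). Fragments are reported
with 1-based inclusive coordinates, molecular weight and isoelectric point.

A synthetic-data module generates seeded substrate corpora with planted
cleavage motifs and matching structural annotations, so training and
evaluation are fully testable offline.

## CLI

All subcommands are deterministic given `--seed` and their inputs; logs go to
stderr, artifacts to files.

```sh
# generate a synthetic corpus with a planted motif
lysocleave simulate --n-substrates 100 --seed 1 --out-prefix demo

# train a scoring model (substrate TSV: id, sequence, sites)
lysocleave train --substrates demo.substrates.tsv --protease DEMO \
    --mode set2 --threshold-criterion f1 --seed 1 --out models/DEMO.json

# report candidate sites (patterns from the registry need no model dir)
lysocleave predict --fasta input.fasta --protease DEMO --protease CTSH \
    --model-dir models --out sites.tsv

# simultaneous digestion (add --partial for adjacent combinations)
lysocleave digest --fasta input.fasta --protease CTSH --out fragments.tsv

# ordered sequential digestion with a minimum output length
lysocleave sequential --fasta input.fasta \
    --protease CTSD --protease CTSH --min-length 4 --out fragments.tsv

# confusion-matrix metrics on a labelled substrate table
lysocleave evaluate --model models/DEMO.json --substrates demo.substrates.tsv \
    --mode set1 --out metrics.tsv
```

Structural features (`--feature-set aa_physical|all`) consume per-residue
annotations from a TSV (`id, pos, residue, ss, rsa`); the package never
computes secondary structure or accessibility itself.

## File formats

* FASTA — input proteins and output fragments (`parent|start-end` headers).
* Substrate TSV — `id, sequence, sites` with `sites` a comma-joined list of
  1-based P1 indices.
* Annotation TSV — `id, pos, residue, ss, rsa`, one row per residue.
* Site report TSV — `sequence_id, protease, p1, window, score, confidence,
  positive`.
* Fragment TSV — `parent_id, start, end, length, sequence, score, mw, pi,
  steps`.
* Model JSON — all matrices, backgrounds, weights, threshold and training
  metadata; load → save round-trips byte-for-byte.

The protease registry and the charge/hydropathy/pKa/background tables ship as
editable TSVs under `src/lysocleave/data/`.

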
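# kturnfold

Analysis toolkit for RNA kink-turn (k-turn) motifs: positional annotation
with the standard nomenclature, the empirical 3b·3n sequence rules for
ion-induced folding, two-state Hill-model fitting of FRET titrations,
cohort-level 3b·3n distribution statistics, and detection of inner-sphere
metal–guanine-O6 coordination in RNA crystal structures.

## What it does

* **`kturnfold.kturn_model`** — parse two-strand k-turn sequences (bulged
  "b" strand + non-bulged "n" strand), assign position labels
  (`L1..L3`, `1b..`, `-1b..`, `1n..`), validate the standard consensus
  (3-nt loop, G·A/A·G pairs), and format ordered base pairs (`A·G`,
  `G-C`, ...).
* **`kturnfold.folding_rules`** — the two ordered classification rules for
  the 3b·3n pair: Watson–Crick or G-U → cannot fold in metal ions alone;
  otherwise 3n=G or 3b=C → folds in ions alone; remaining pairs are
  indeterminate. Includes the empirical category table with configurable
  ΔE_FRET thresholds and a rule-trace on every prediction.
* **`kturnfold.titration`** — the two-state model
  `E = E0 + ΔE·KA·cⁿ/(1+KA·cⁿ)`, nonlinear least-squares fitting,
  half-point `(1/KA)^(1/n)`, and residual-resampling bootstrap intervals.
* **`kturnfold.cohort_stats`** — Stockholm-alignment cohort reader with a
  label→column map, exact 16-pair count tables, summary fractions
  (A·G, 3n=G, 3b=C, folder/non-folder), and ranked folding-spectrum
  histograms.
* **`kturnfold.metal_coordination`** — PDB/mmCIF ingestion, metal-site
  detection with an inner-sphere cutoff (default 2.6 Å), octahedral
  geometry scoring from cis ligand angles, and guanine-O6 contact reports.
* **`kturnfold.synthetic_data`** — seeded generators for all of the above:
  noisy titration curves, the 16-variant 3b·3n scan of a template,
  riboswitch-like and spliceosome-like sequence cohorts, and minimal PDB
  geometry fixtures.

## CLI

```sh
# classify k-turns from a FASTA file (b/n record pairs)
kturnfold classify kturns.fasta

# simulate a titration and fit the two-state model
kturnfold simulate titration --half-point 70 --noise-sd 0.02 --out curve.tsv
kturnfold fit curve.tsv --boot 200 --seed 1

# generate and summarize a sequence cohort
kturnfold simulate cohort --profile sam --n 1000 --seed 1 --out cohort/
kturnfold cohort cohort/cohort.sto --column-map cohort/column_map.json --out tables/

# metal coordination report for a structure
kturnfold simulate structure --kind two_ion_kt7_like --out fixture.pdb
kturnfold metal fixture.pdb --cutoff 2.6
```

FASTA input uses two records per k-turn; the b-strand record's description
carries `strand=b loop_start=<i> loop_len=<k>` (0-based loop start) and its
partner carries `strand=n`.

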
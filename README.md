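# groomsyntax

Analysis of variation and variability in *Drosophila* grooming behavior
from ethograms — frame-by-frame behavioral records over a seven-action
alphabet: five grooming actions (front leg cleaning **F**, head grooming
**H**, abdomen grooming **A**, back leg cleaning **B**, wing grooming
**W**) and two non-grooming actions (walking **Wk**, standing **S**),
sampled at 30 Hz.

The package is written for behavioral neuroscientists and computational
ethologists who want to quantify, from categorical behavior time series:

* **variation** — differences *between* groups (species, stock lines,
  sexes), and
* **variability** — spread *within* a group or within one individual
  across repeated sessions.

## What it computes

Ethograms are first denoised (grooming bouts shorter than one leg sweep,
150 ms, are absorbed into their neighbors) and run-length encoded into
bouts. From there:

* **Feature families** — action proportions (7), progression vectors
  (proportions in 10 non-overlapping windows, 10 × 7 = 70), **syntax**
  (first-order bout transition probabilities `p_ij`, i ≠ j, 42 entries),
  and per-action bout-duration histograms (7 × 20 = 140, bin widths set
  separately for grooming and non-grooming actions).
* **Stereotypy** — the entropy rate of the syntax Markov chain,
  `H = −Σ_i w_i Σ_{j≠i} p_ij ln p_ij` (nats), with `exp(−H)` the
  probability of guessing the next action (H = 0: fully stereotyped;
  H = ln 6 ≈ 1.79: maximally unpredictable); and the normalized
  Levenshtein edit distance between anterior motif runs (the first
  continuous F/H stretch lasting ≥ 30 s), compared within flies across
  sessions or between flies.
* **Group statistics** — for every group pair and every one of the 42
  transitions, Wilcoxon rank-sum tests on per-fly transition
  probabilities (location) and Brown–Forsythe/Levene tests (variance),
  plus per-action two-sample Kolmogorov–Smirnov tests on pooled bout
  durations; each table is Holm-corrected as one family (5 groups × 42
  transitions = 420 comparisons; 4 groups = 252).
* **Classification** — cross-validated multinomial logistic regression
  from any feature family, with chance level estimated by label
  permutation (20% for 5 balanced classes, 25% for 4), and t-SNE
  embeddings for visualization.
* **Synthetic cohorts** — a seeded semi-Markov generator producing
  ethograms with the structure the analysis assumes: no bout-level
  self-transitions, grooming dwell times peaking between 500 and 750 ms,
  high within-motif coupling, a sigmoid anterior-to-posterior phase
  progression, per-group transition matrices with per-fly Dirichlet
  jitter, and an optogenetic paradigm with three 3-min anterior-driving
  stimulation windows.

## Worked example

```python
import numpy as np
from groomsyntax import synthetic as syn
from groomsyntax.classify import classify
from groomsyntax.ethogram import denoise, to_bouts
from groomsyntax.features import feature_table, syntax_vector
from groomsyntax.stereotypy import entropy_rate

# five species-scale groups, 13 flies each, 50,000-frame recordings
cohort = []
for tpl, ch in zip(syn.species_templates(recording_frames=50_000),
                   np.random.SeedSequence(42).spawn(5)):
    cohort += [denoise(e) for e in syn.simulate_population(tpl, 13, ch)]

X = feature_table(cohort, "syntax")          # 65 flies x 42 transitions
res = classify(X, [e.group_id for e in cohort], seed=0)
print("accuracy:", round(res.accuracy, 3))

H = [entropy_rate(syntax_vector(to_bouts(e))).H for e in cohort[:13]]
print("mean entropy:", round(float(np.mean(H)), 3))
```

prints

```
accuracy: 0.882
mean entropy: 1.411
```

meaning the five synthetic groups are separable by syntax alone at 88%
cross-validated accuracy (chance is 20%), and the base group's grooming
rules sit well between complete stereotypy (0) and complete
unpredictability (ln 6 ≈ 1.79) — a ~24% chance of predicting each next
action.

The same analyses are scriptable from the shell:

```bash
groomsyntax simulate --preset five-species-like --out fx --seed 1
groomsyntax features --manifest fx/manifest.tsv --family syntax --out syntax.tsv
groomsyntax compare  --manifest fx/manifest.tsv --test location --out cmp.tsv
groomsyntax run --experiment opto --out opto_run --seed 1
```

Ethograms are two-column CSVs (`frame_index,label`) with `# key: value`
metadata headers, one fly per file; cohorts are listed in a manifest TSV
(`fly_id  group_id  session_id  path`).

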
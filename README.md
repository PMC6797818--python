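# semtraj

Vector-space semantic trajectory analysis of feature-generation
transcripts. Given a word-embedding space and ordered multi-word
feature responses per trial, `semtraj`:

- scores each feature against its target word (mean per-word cosine)
  and each pair of features within a trial (mean pairwise cosine),
  organized by response position and by lag;
- fits Bayesian mixed-effects models (lognormal or normal response,
  group fixed effect, subject and target-word random intercepts) and
  two-level hierarchical power laws `f(x) = a * x**b` with per-group
  population parameters, reporting HP − CO posterior difference
  distributions, leave-one-out-by-subject robustness, and split-R-hat
  convergence diagnostics;
- generates all of its own inputs when needed: deterministic fixture
  embedding spaces, power-law datasets with known parameters, and full
  synthetic cohorts from a compound-retrieval-cue search simulator in
  which a restricted group (HP) cannot retrieve candidates below a
  floor of similarity to the target.

The samplers are implemented directly on `numpy` (exact Gibbs for the
mixed model; Gibbs plus adaptive Metropolis-within-Gibbs with
non-centered interweaving for the power law), so no probabilistic
programming backend is required.

## Test

```sh
python -m pytest -q
```

The suite is fully self-contained (all fixtures generated in-process)
and includes an acceptance tier in `tests/test_acceptance.py`:
exact worked aggregation examples, seeded parameter-recovery and
null-calibration checks for both model families, simulator signature
checks, and brute-force oracle equivalences.

## CLI

```sh
# generate a synthetic cohort (transcript TSV + embedding text + truth JSON)
semtraj simulate --seed 1 --out-dir cohort/

# similarity + lag records as tidy CSVs
semtraj score --embeddings cohort/embeddings.txt \
              --transcripts cohort/transcript.tsv --out-dir scored/

# hierarchical power-law fit on a records CSV
semtraj fit --records scored/position_records.csv --x-field position \
            --out fit.json

# full pipeline from a YAML config
semtraj run --config analysis.yaml

# group mean curves
semtraj plot --records scored/position_records.csv --out-dir figs/
```

Example `analysis.yaml`:

```yaml
embeddings:
  path: cohort/embeddings.txt
transcripts:
  path: cohort/transcript.tsv
out_dir: out
prep:
  exclusion_profile: extended   # or: strict
mcmc:
  chains: 4
  iterations: 4000
  seed: 1
analysis:
  leave_one_out: true
  make_plots: true
```

`run` writes tidy record CSVs, posterior draw CSVs, a `report.json`
with posterior summaries / difference distributions / convergence
reports / provenance, and a human-readable `summary.txt`.

## Input formats

- **Embeddings**: text layout, one `word f1 f2 ... fD` per line, UTF-8,
  no header. Vocabulary is lowercased by default; all-zero vectors are
  rejected.
- **Transcripts**: TSV (or CSV by extension) with columns
  `subject_id, group, target_word, position, feature_text`; group is
  `CO` or `HP`; positions are contiguous from 1 within each
  (subject, target) trial.

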
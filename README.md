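# regdesign

Quantitative prediction and de-novo design of promoter & RBS strength.

A fixed-length regulatory element (default 224 nt) is one-hot encoded (4
bits per base, A/G/C/T order) and mapped to its relative expression
strength by a single-hidden-layer backpropagation network with logistic
activations on both layers. Targets are normalized by the maximum training
strength so they fit the (0, 1) output range and predictions are scaled
back afterwards. On top of the trained model the package provides:

- **grid-search model selection** over training-set size x hidden-layer
  width x random restarts, with `NET{size}_{hidden}_{restart}` cell naming
  and per-size test-error summaries;
- **single-point mutation scanning**: all 3·L substitutions of the wild
  type are scored, and substitutions changing the predicted strength by
  >= 20% are classified as positive/negative key points;
- **two de-novo design procedures**: screening a random in-silico mutant
  library, or beam/exhaustive search over combinations of key-point
  mutations, both targeting a desired strength within a tolerance;
- **sequence analysis**: per-position information-content profiles and
  key-point mutation-type tallies (including the AT->GC aggregate);
- **a PWM baseline**: log2-odds position-weight-matrix scoring with an
  OLS fit of log-activity against score, for comparison with the network;
- **synthetic libraries**: a planted, saturating sequence-to-strength
  ground truth that emulates a ~100-member mutant library (strengths in
  [0, 3.559], wild type = 1, ~20% positive mutants) so the whole pipeline
  is testable end to end and recovery of planted key sites can be scored.

## CLI

Every subcommand writes a JSON manifest (parameters, seeds, SHA-256 of
each output) next to its outputs; identical seeds give byte-identical
reruns. A YAML file can supply per-subcommand defaults via `--config`
(explicit flags win).

```bash
# synthetic 100-member library of 224-nt mutants (FASTA + TSV + truth JSON)
regdesign simulate --n 100 --rate 0.2 --seed 1

# train the 896->19->1 network (best of 20 restarts)
regdesign train --fasta library.fasta --strengths library.tsv \
    --hidden 19 --restarts 20 --seed 1

# predict strengths for arbitrary same-length sequences
regdesign predict --model model.json --fasta library.fasta

# count the full hyperparameter grid without training
regdesign grid-search --sizes 40:90 --hidden 5:30 --restarts 1000 --count-only

# run a reduced grid
regdesign grid-search --fasta library.fasta --strengths library.tsv \
    --sizes 80:90 --hidden 15:22 --restarts 5 --seed 1

# scan all single-point mutations and classify key points
regdesign scan --model model.json --wt-fasta wt.fasta

# design sequences with a desired strength
regdesign design --model model.json --wt-fasta wt.fasta \
    --mode library --target 2.5 --tol 0.1 --n 10000 --seed 1
regdesign design --model model.json --wt-fasta wt.fasta \
    --mode keypoints --target 2.5 --tol 0.1 --max-mutations 5

# PWM baseline fit (best subset of all / high-strength / strength-weighted)
regdesign pwm-fit --fasta library.fasta --strengths library.tsv
```

Library format: FASTA of equal-length sequences plus a TSV with header
`id<TAB>relative_strength`; ids match the first whitespace-delimited token
of the FASTA headers. Trained models serialize to version-tagged JSON.

## Notes

- Training reproduces the classic batch gradient-descent trainer with
  momentum and an adaptive learning rate (grow x1.05 after improving
  epochs; shrink x0.7 and reject the step when the SSE grows by more than
  x1.04), stopping at SSE <= 0.2 on normalized targets or 5,000 epochs.
- Designs cannot target strengths above the maximum strength of the
  training library; the network output is bounded by that constant.
- The full 51 x 26 x 1000 grid is supported but desk-scale profiles
  (reduced ranges/restarts) are the default; `--count-only` verifies the
  planned cardinality instantly.
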
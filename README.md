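# multicue

A simulator of cross-situational word learning from multiple, variably
reliable environmental cues, built around a hub-and-spoke recurrent neural
network.

On every learning trial the network sees two word forms and two object
referents (one true word-object pairing, one foil of each) and must produce
the localist semantic representation of the target word. Three cues can
mark the target, each present on a trial with a configurable probability:

* **prosody** — doubles the activation of the target word form;
* **gesture** — doubles the activation of the target referent;
* **distributional** — a 2-unit input signaling the target's category
  (half the lexicon belongs to each of two categories).

The package generates the pseudopattern lexicon, trains the network with
backpropagation through time (six-step clamped-input dynamics, sum-squared
error on the output over steps 3-6, online SGD), tracks per-epoch accuracy
and a "5 consecutive perfect epochs" learning criterion, and measures
post-training **robustness**: accuracy when all cues are withdrawn. A stats
module provides the one-way repeated-measures ANOVA (with partial eta
squared) and Bonferroni-corrected paired post hocs used to analyze
time-to-criterion and robustness across cue conditions.

## Command-line interface

```sh
# reduced grid that finishes in minutes
multicue run --preset desk --out results/desk

# the full cue-reliability grid: 100 words, 20 replicates, 100k-epoch cap
multicue run --preset paper --out results/paper

# or a YAML config (see below)
multicue run --config my_config.yaml

# within-subject ANOVA + post hocs + predicted-ordering report
multicue analyze results/desk --plot

# debugging helpers
multicue dump-trial --master-seed 1 --condition prosodic_cue --epoch 2 --index 5
multicue gradcheck --seeds 5
```

`run` writes per-condition learning-curve CSVs, a `summary.json` with
per-replicate outcomes (epochs to criterion, robustness, seed bundles), and
a `manifest.json` carrying the config hash and master seed for exact
replay. Example config:

```yaml
preset: desk            # optional base preset
master_seed: 7
n_replicates: 5
output_dir: results/mine
hyperparameters:
  learning_rate: 0.05
conditions:
  - {name: no_cue}
  - {name: prosodic_cue, p_prosody: 1.0}
  - {name: combined_0.50, p_distributional: 0.5, p_prosody: 0.5, p_gesture: 0.5, max_epochs: 15000}
```

Every random stream (lexicon, initial weights, per-epoch trial order,
evaluation foils) derives from `(master_seed, condition, replicate, stream,
epoch)` spawn keys, so any single trial of any run can be reconstructed.

## Layout

* `multicue.lexicon` — pseudopattern lexicon (2-of-5 phonemes, 8-of-20
  referents, localist semantics, category split)
* `multicue.trials` — trial construction and cue application
* `multicue.network` — forward dynamics, SSE loss, BPTT, SGD (reference
  implementation); `multicue._fast` holds the numba-fused training kernel
  that the harness uses (verified equivalent by tests)
* `multicue.experiment` — conditions, epochs, criterion detection,
  robustness testing, replicates, matched-training control
* `multicue.stats` — repeated-measures ANOVA, Bonferroni pairwise tests
* `multicue.cli` / `multicue.config` — orchestration, presets, YAML configs
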
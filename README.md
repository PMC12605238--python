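# cogmi

Predicting a subject's **personalized motor-imagery (MI) action** from
short cognitive-task EEG.

MI brain–computer interfaces work best when each user trains with the
imagined action they can modulate most strongly, but identifying that
action through MI experiments alone is slow. `cogmi` implements a pipeline
that predicts it from cognitive-task EEG instead: per-trial brain networks
in three domains feed a spectral graph convolutional classifier whose
per-action votes select the subject's best action. The package targets
researchers in EEG decoding / BCI methods who want a fully testable,
dependency-light reference implementation; because the original
10-subject dataset is private, a first-class synthetic-data generator
reproduces the experiment's statistical structure so every stage runs and
is validated end-to-end.

## Method

For each cognitive trial `X ∈ R^{19×1000}` (19 channels, 1 s at 1 kHz
after 0.5–20 Hz filtering, baseline correction and cropping), three graphs
on the electrodes are built:

| domain | node features | edges |
|---|---|---|
| time | 40 block-averaged samples per channel (19×40) | `w_{h1,h2} = |corr(d_{h1}, d_{h2})|` (absolute Pearson) |
| frequency | mean Welch PSD in 1–4/4–8/8–13/13–20 Hz (19×4) | phase-locking value `PLV = |T^{-1} Σ_t e^{iΔφ(t)}|`, averaged over bands |
| spatial | log normalized variance of CSP components (19×1) | 1 − min-max-normalized `|s_{h1} − s_{h2}|` |

Each graph passes through two first-order Chebyshev graph convolutions
(`G^{(l+1)} = σ(D̃^{-1/2}(A+I)D̃^{-1/2} G^{(l)} W^{(l)})`, 32 → 16 units,
ReLU, dropout 0.5) and node-mean pooling; the three 16-vectors are
concatenated, batch-standardized and classified strong/weak by a softmax
layer. The action collecting the most "strong" votes over its 25 trials
is the predicted personalized action.

Ground truth is defined per subject from MI data: per action, 80 MI
trials (8–30 Hz, 12 channels) are decoded left-vs-right hand by CSP (2
filter pairs) + a 4-100-50-10-2 feed-forward network under stratified
ten-fold cross-validation; the action with the highest mean accuracy is
"strong". Evaluation is leave-one-subject-out (LOSO): CSP and classifier
never see the held-out subject. Metrics: F1, sensitivity, specificity,
accuracy, Cohen's kappa, and clustering-coefficient contrasts of the
strong/weak mean networks. See `docs/methods.md` for assumptions, open
design choices, and what the synthetic benchmark does and does not
establish.

## Worked example

```bash
cogmi run-all --out demo --seed 1 \
    --override simulation.n_subjects=4 --epochs 100
```

prints, after simulating a 4-subject cohort, labeling each subject's
actions from their MI data, and running LOSO evaluation:

```
subject 0: MI-ACC ['76.2%', '80.0%', '100.0%'] -> strong action 2
subject 1: MI-ACC ['100.0%', '71.2%', '65.0%'] -> strong action 0
subject 2: MI-ACC ['77.5%', '97.5%', '85.0%'] -> strong action 1
subject 3: MI-ACC ['100.0%', '72.5%', '77.5%'] -> strong action 0
pooled trial accuracy 100.00% over 300 trials; strong action recovered for 4/4 subjects
```

Reading: for subject 0, left-vs-right MI decodes at 100% under action 2
but only 76–80% under the others, so action 2 is that subject's strong
action; training only on the *other* subjects' cognitive EEG, the graph
classifier labels every held-out cognitive trial correctly strong/weak,
and majority voting recovers every subject's strong action. (Synthetic
cohorts with the default effect sizes are cleanly separable; real EEG is
not — see `docs/methods.md` for what this benchmark does and does not
establish.)
Artifacts land in `demo/`: `cohort.h5` (epochs container),
`labeling.json`, `reports.json`, `summary.csv`, condition-mean
connectivity matrices under `mean_networks/` with their
clustering-coefficient contrast in `network_contrast.json`, and a
provenance `run_log.jsonl` keyed by the configuration hash. The same pipeline is
available as a library (`simulate_cohort`, `label_subject`, `loso_cv`,
`summarize_reports`) and stage-by-stage on the CLI
(`simulate`/`label`/`networks`/`train`/`evaluate`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch — synthetic cohort
generation, MI-based strong/weak labeling, and LOSO evaluation of the
multi-domain graph classifier at reduced scale — printing the pooled
trial accuracy and per-subject action recovery, and writes the target
report to `--out`.
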
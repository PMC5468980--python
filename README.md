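# incident-triage

Multiclass triage of free-text incident reports with binary-classifier
ensembles. The pipeline reduces an `l`-class problem into binary sub-problems
— one-versus-one (`l(l-1)/2` pairwise discriminators, combined by majority
voting or by a tail-rejection decision DAG needing only `l-1` evaluations) or
one-versus-all (`l` one-vs-rest discriminators, argmax of calibrated
probability) — over bag-of-words features (binary / tf / tf-idf) extracted
from normalized, stopword-filtered, lemmatized and stemmed narratives.

Because real incident-report corpora are confidential, the package ships a
seeded synthetic corpus generator that reproduces the structural properties
the analysis depends on: fixed balanced compositions (11 incident types x
260 reports; 4 severity levels x 290), real-world stratified compositions,
truncated-normal report lengths, class-specific vocabularies with a tunable
overlap (confusability) knob, severity indicator phrases with adjacent-level
blending, and secondary-type term co-occurrence for documentation reports.

## Layout

| module | contents |
| --- | --- |
| `incident_triage.synthetic` | generator presets, `GeneratorConfig`, corpus summaries |
| `incident_triage.corpus` | `IncidentReport`, JSONL/CSV readers and writers |
| `incident_triage.preprocessing` | normalization, vendored stopword list, lemmatizer, Porter stemmer |
| `incident_triage.features` | vocabulary with document frequencies, binary/tf/tf-idf sparse vectorization |
| `incident_triage.base` | logistic regression / linear SVM / RBF SVM wrappers, Platt calibration, F-score grid tuning |
| `incident_triage.ensemble` | OvsO/OvsA decomposition, voting / DAG / argmax prediction, bundle persistence |
| `incident_triage.evaluation` | confusion matrices, per-class P/R/F, micro/macro averaging, model selection |
| `incident_triage.experiment` | 80/10/10 repeated random sub-sampling split plan, full factorial grid (27 configurations), external-corpus evaluation |

## CLI

```sh
# synthesize a labeled corpus (presets: balanced_type, balanced_severity,
# stratified_original, stratified_independent)
incident-triage generate --preset balanced_type --seed 7 --out corpus.jsonl

# train / predict / evaluate one configuration
incident-triage train --in corpus.jsonl --task type --strategy ovso \
    --decision dag --algorithm svm_rbf --weighting binary --model-dir model/
incident-triage predict --model model/ --in corpus.jsonl --out predictions.csv
incident-triage evaluate --model model/ --in corpus.jsonl

# full factorial comparison from a YAML config
incident-triage experiment --config experiment.yaml
```

Example `experiment.yaml`:

```yaml
corpus_source: balanced_type   # preset name or path to a .jsonl/.csv corpus
task: type
strategies: [ovso, ovsa]
algorithms: [logreg, svm_linear, svm_rbf]
weightings: [binary, tf, tfidf]
n_repetitions: 10
seed: 0
output_dir: results/
```

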
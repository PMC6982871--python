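# harens

Routine-partitioned neural-network ensembles for binary-sensor human
activity recognition in smart homes.

A single inhabitant's day is observed through 30 binary sensors (contact,
motion, pressure). The event stream is cut into 30-second windows, each
described by a 31-dimensional feature vector (one activation feature per
sensor plus a time-routine code). Four shallow feed-forward networks —
Morning, Afternoon, Evening and Mixed — each cover only the activity
classes of their time routine, and are additionally trained on a sampled
*complement class* so that a model can recognise foreign activities and
eliminate itself from the decision. The base models are fused by their
probability outputs; when two or more models claim an instance, one of four
conflict-resolution strategies decides:

| strategy | score per conflicting model |
|----------|-----------------------------|
| `alg2`   | largest probability `p1` |
| `alg3`   | margin `p1 − p2` |
| `alg4`   | `p1 × m` (m = number of model outputs) |
| `alg5`   | `p1 × m × training accuracy` |

The package also ships the catalog-restructuring pipeline (class merges,
under-representation filter, random held-out split), both complement
allocation schemes (per donor model / per donor class), an evaluation
harness that reports conflicts, accuracies and "right but incorrect"
counts over repeated folds, and a deterministic smart-home simulator so
the whole pipeline runs without any external dataset.

## Command line

```bash
# generate a synthetic labelled stream (12 classes, routine-scheduled)
harens simulate --scale paper_like --seed 0 --overlap 0.5 \
    --out-events events.csv --out-annotations annotations.csv

# window + featurize + restructure + split
harens prepare --events events.csv --annotations annotations.csv \
    --window-seconds 30 --feature-mode indicator

# repeated-fold ensemble experiment with conflict accounting
harens evaluate --complement class-level --strategies all --folds 10 --seed 0
```

`harens evaluate` without `--train` simulates a fresh dataset internally.

## Library sketch

```python
import harens as h

config = h.overlap_knob(h.default_config("paper_like", seed=0), 0.5)
events, annotations = h.generate(config)
dataset = h.build_dataset(events, annotations, h.SensorRegistry.default())

experiment = h.ExperimentConfig(dataset=dataset, catalog=config.catalog,
                                scheme="class_level", folds=10, base_seed=0)
results = h.run_experiment(experiment)
print(h.summarize(results))
```

## Layout

- `src/harens/events.py` — raw event stream + sensor registry I/O
- `src/harens/windows.py` — segmentation, features, window labelling
- `src/harens/restructure.py` — class merges, filtering, train/test split
- `src/harens/modelspec.py` — base-model partitions, complement allocation
- `src/harens/ensemble.py` — base network training and probability outputs
- `src/harens/conflict.py` — conflict detection and the four resolvers
- `src/harens/evaluate.py` — repeated-fold harness and verdict accounting
- `src/harens/synthetic.py` — deterministic smart-home simulator
- `src/harens/catalogs.py` — bundled sensor registry and class catalogs
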
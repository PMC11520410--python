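# Desk-scale end-to-end run: generate -> train -> predict -> evaluate -> plan.
generator:
  n_reactions: 60
  seed: 7
  n_chains: 1
model:
  preset: small
  dropout: 0.0
training:
  epochs: 20
  batch_size: 2
  augment: 4
  seed: 7
captioner:
  gamma: 1.0
  similarity: cosine
paths:
  data_dir: data
  train_file: data/train.txt
  test_file: data/train.txt     # desk demo evaluates on the training split
  checkpoint_dir: checkpoint
  predictions_file: predictions.tsv
  metrics_file: metrics.tsv
  stock_file: data/stock.txt
  route_file: route.json
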
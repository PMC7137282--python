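"""Apply the shipped pre-trained model to a new dataset without re-training.

The TU-state parameters of a trained model transfer across datasets: here
the packaged model (trained on the default synthetic fixture) decodes a
fresh genome simulated with a different seed. Bin-level precision/recall
against that genome's own planted truth show the transfer quality.
"""

from importlib import resources

import numpy as np

from epigene import SimulationConfig, call_tus, load_model, simulate_dataset
from epigene.grid import GenomicInterval, intervals_to_bin_mask
from epigene.pipeline import binarize_dataset

with resources.as_file(
    resources.files("epigene.data") / "synthetic_pretrained_model.json"
) as path:
    model = load_model(path)
print(f"loaded model: {model.k} states, marks: {model.marks}")

config = SimulationConfig(seed=99, contig_sizes={"chrNew": 1_000_000}, n_tus=20)
dataset = simulate_dataset(config)
class_matrix, _ = binarize_dataset(dataset)

tus = call_tus(model, class_matrix)
pred = intervals_to_bin_mask(
    [GenomicInterval(t.contig, t.start, t.end, t.strand) for t in tus], dataset.grid
)
truth = dataset.truth_tu_mask
tp = int(((pred == 1) & (truth == 1)).sum())
print(f"called {len(tus)} TUs on the new genome ({int(truth.sum())} truth TU bins)")
print(f"bin-level precision: {tp / pred.sum():.3f}, recall: {tp / truth.sum():.3f}")
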
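"""Cluster the eight checkpoint inhibitors on a 6x1 self-organizing map.

Trains the SOM on the published drug x category reporting-ratio matrix,
prints the unit assignment per drug, the label-invariant partition, the
quantization error, and the adjacent-unit weight distances (a text
U-matrix: small distances mean neighboring units hold similar profiles).
Because training is stochastic, the partition is stabilized as the most
frequent one over many seeds.
"""

from irae_som import SomConfig, load_category_matrix, partition_of, train
from irae_som.som import modal_partition, unit_distance_summary

matrix = load_category_matrix()
model = train(SomConfig(grid_rows=6, grid_cols=1, seed=0), matrix)

print("single-run unit assignments (seed 0):")
for drug, unit in sorted(model.assignments.items()):
    print(f"  {drug}: unit {unit}")
print(f"quantization error: {model.quantization_error:.2f} "
      "(mean distance of each drug profile to its unit)")

print("\nadjacent-unit weight distances (U-matrix surrogate):")
print(unit_distance_summary(model).to_string(index=False))

part, freq = modal_partition(SomConfig(grid_rows=6, grid_cols=1), matrix,
                             n_seeds=100)
print(f"\nmodal partition over 100 seeds (frequency {freq:.2f}):")
for group in sorted(sorted(g) for g in part):
    print(" ", group)
# drugs grouped together share an irAE reporting profile; the modal
# partition is what the stochastic clustering most often produces
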
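"""Build a participant's 2D cognitive map from similarity ratings.

A small thought inventory is paired exhaustively, rated for similarity
(here simulated from latent 2D positions), and embedded with nonmetric
MDS.  The stress-1 value says how faithfully the 2D map preserves the
rating structure (0 = perfect rank agreement); the partition shows which
thoughts the training engine will place the probe behind.
"""

import numpy as np

from steptrain import (
    classify_for_training,
    cognitive_map,
    generate_similarity,
    make_inventory,
    pair_schedule,
)

inventory = make_inventory("demo")
print(f"inventory: {len(inventory)} thoughts")

pairs = pair_schedule([s.stimulus_id for s in inventory], seed=1)
print(f"rating task: {len(pairs)} pairs, first three: {pairs[:3]}")

latent = np.random.default_rng(1).normal(size=(len(inventory), 2))
ratings = generate_similarity(inventory, latent, noise_sd=0.5, seed=1)
cmap = cognitive_map(ratings, seed=1)
print(f"2D map stress-1 = {cmap.stress:.4f} after {cmap.n_iterations} iterations")

partition = classify_for_training(inventory, cmap)
print(f"probe targets: {[s.stimulus_id for s in partition.probe_targets]}")
print(f"distractors:   {[s.stimulus_id for s in partition.distractors]}")
# Low stress means the ratings are nearly 2D-consistent; probe targets are the
# approach/neutral-oriented, positive/neutral-toned thoughts that training
# directs attention toward.
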
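"""Native contacts and PCA collective variables from a toy NMR-style ensemble.

Builds a small multi-model structure with a planned contact map, extracts
the consensus native contacts (< 6.5 Å in every model), converts a toy
coordinate trajectory into contact-distance features, and rotates them onto
principal components g = (g1, g2, g3) -> G = (G1, G2).
"""

import numpy as np

from foldflux import (
    build_distance_features,
    extract_native_contacts,
    fit_pca,
    generate_toy_structure,
    project,
    reduce_to_2d,
)

structure = generate_toy_structure(
    n_residues=10, n_models=3, contact_plan=[(0, 3), (1, 5), (2, 7), (4, 9)], seed=1
)
contacts = extract_native_contacts(structure, cutoff=6.5)
print(f"{len(contacts)} native contacts: {contacts.pairs}")

# a wobbling trajectory around model 1
rng = np.random.default_rng(0)
coords = structure.models[0] + rng.normal(0, 0.8, size=(200, 10, 3))
ensemble = build_distance_features([coords], contacts, frame_interval=2e-5)
print(f"feature matrix: {ensemble.trajectories[0].frames.shape} (frames x contacts)")

space = fit_pca(ensemble, n_components=4)
fractions = space.explained_variance_fractions
print("explained variance fractions:", np.round(fractions, 3))

cv3 = project(ensemble, space)
cv3 = cv3.map_frames(lambda f: f[:, :3])
cv3.feature_kind = "cv3"
cv2, weights = reduce_to_2d(cv3, space)
print(f"G2 weights: w2 = {weights.w2:.3f}, w3 = {weights.w3:.3f} (sum 1)")
print("first cv2 frame (A):", np.round(cv2.trajectories[0].frames[0], 3))
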
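"""End-to-end: segment a synthetic two-texture phantom and score it.

Generates a 400x400 phantom (coarse-texture ellipse on a fine-texture
background, multiplicative speckle), computes the 30 features for each
of the 400 patches, clusters them with k-means, and prints Dice,
sensitivity and specificity against the known ground truth.

Takes about a minute on one CPU.
"""
from artexus.segment import cluster_patches, evaluate, featurize_image
from artexus.synthdata import gen_phantom

SEED = 1

phantom = gen_phantom(seed=SEED)
print("phantom:", phantom.provenance())

features, grid = featurize_image(phantom.image)
print(f"feature matrix: {features.shape[0]} patches x {features.shape[1]} features")

result = cluster_patches(features, grid, seed=SEED)
metrics = evaluate(result, phantom.gt_mask)
print(f"Dice = {100 * metrics.dice:.2f}%  "
      f"SE = {metrics.sensitivity:.2f}  SP = {metrics.specificity:.2f}")
print(
    "\nDice is the pixel overlap between the clustered patch mask and the\n"
    "ellipse ground truth (oracle cluster-to-class assignment); errors sit\n"
    "almost entirely on boundary patches that straddle the two textures."
)
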
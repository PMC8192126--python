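"""Input-gradient saliency maps for trained classifiers.

A saliency map is the absolute gradient of the network's pre-sigmoid
output with respect to one input matrix (the final sigmoid is swapped
for a linear activation, which sharpens the map without changing which
entries matter).  Scenario-level maps average over a set of inputs.
"""

from __future__ import annotations

import numpy as np

from introscan.model import TrainedClassifier, _as_input


def saliency_map(classifier: TrainedClassifier, matrix: np.ndarray) -> np.ndarray:
    """|d(logit)/d(input)| for a single matrix; same shape as the input."""
    maps = saliency_maps(classifier, np.asarray(matrix)[None, ...])
    return maps[0]


def saliency_maps(classifier: TrainedClassifier, matrices: np.ndarray) -> np.ndarray:
    """Batched vanilla saliency: one gradient-magnitude map per input."""
    X = _as_input(matrices).astype(np.float32)
    if X.shape[1:3] != classifier.input_shape:
        raise ValueError(
            f"matrix shape {X.shape[1:3]} does not match model input "
            f"{classifier.input_shape}"
        )
    net = classifier.network
    net.forward(X, train=False)
    # gradient of the raw logit (linear output), one unit per item
    dy = np.ones((X.shape[0], 1), dtype=np.float32)
    dx = net.backward(dy)
    return np.abs(dx[..., 0])


def average_saliency(
    classifier: TrainedClassifier,
    matrices_by_scenario: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Element-wise mean saliency map per scenario."""
    out = {}
    for scenario, mats in matrices_by_scenario.items():
        mats = np.asarray(mats)
        if len(mats) < 1:
            raise ValueError(f"scenario {scenario!r} has no matrices")
        out[scenario] = saliency_maps(classifier, mats).mean(axis=0)
    return out


def block_attention(
    mean_map: np.ndarray, block_bounds: dict[str, tuple[int, int]]
) -> dict[str, float]:
    """Total attention mass per population block of an averaged map."""
    return {
        pop: float(mean_map[a:b].sum()) for pop, (a, b) in block_bounds.items()
    }
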
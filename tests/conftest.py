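import numpy as np
import pytest

from calmorph import MarkerConfig, detect_markers, segment_sequence
from calmorph.synth import SceneSpec, generate_sequence


@pytest.fixture(scope="session")
def default_scene():
    """The default synthetic scene (8 cells, 200 frames, seed 42) with its
    ground truth, plus the noiseless frame stack."""
    seq, truth, noiseless = generate_sequence(SceneSpec(), return_noiseless=True)
    return seq, truth, noiseless


@pytest.fixture(scope="session")
def default_segmentation(default_scene):
    """Markers and watershed labels of the default scene."""
    seq, truth, _ = default_scene
    markers = detect_markers(seq, MarkerConfig())
    labels = segment_sequence(seq, markers)
    return markers, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def component_centroids(mask: np.ndarray) -> np.ndarray:
    """Centroids of the 8-connected components of a boolean mask."""
    from scipy import ndimage as ndi

    lab, n = ndi.label(mask, structure=np.ones((3, 3), bool))
    if n == 0:
        return np.zeros((0, 2))
    return np.array(ndi.center_of_mass(mask, lab, range(1, n + 1)))


def match_counts(detected: np.ndarray, truth: np.ndarray, radius: float):
    """Component-level (n_matched_detections, n_matched_truths)."""
    n_prec = sum(
        1 for d in detected
        if truth.size and np.sqrt(((truth - d) ** 2).sum(1)).min() <= radius)
    n_rec = sum(
        1 for t in truth
        if detected.size and np.sqrt(((detected - t) ** 2).sum(1)).min() <= radius)
    return n_prec, n_rec
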
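import numpy as np
import pytest

from radialpolarity import (
    ImageRaster,
    RunConfig,
    SimulationConfig,
    analyze_field,
    simulate_field,
)
from radialpolarity.segmentation import extract_rois


def rasterize_disk(radius: int, pad: int = 4) -> np.ndarray:
    """Brute-force rasterized solid disk: pixels with x^2 + y^2 <= r^2."""
    size = 2 * radius + 2 * pad + 1
    yy, xx = np.mgrid[:size, :size]
    c = size // 2
    return ((yy - c) ** 2 + (xx - c) ** 2 <= radius * radius).astype(int)


@pytest.fixture
def disk_roi():
    """Factory: an AcinusROI that is a perfect disk, plus its grid shape."""

    def make(radius: int, pad: int = 4):
        labels = rasterize_disk(radius, pad)
        roi = extract_rois(labels)[0]
        return roi, labels.shape

    return make


@pytest.fixture
def simulate_pool():
    """Factory: run single-phenotype fields through the pipeline, pooling results."""

    def make(phenotype: str, n_results: int, seed0: int, gradient_strength: float = 1.0, **sim_kw):
        config = RunConfig(wavr_cutoff=0.0)
        results, pairs = [], []
        seed = seed0
        while len(results) < n_results:
            sim = SimulationConfig(
                phenotype_mix={phenotype: 1.0},
                seed=seed,
                gradient_strength=gradient_strength,
                **sim_kw,
            )
            pair, _ = simulate_field(sim)
            fa = analyze_field(pair, config)
            results.extend(fa.results)
            pairs.append(pair)
            seed += 1
        return results[:n_results], pairs

    return make


@pytest.fixture
def single_acinus_crops():
    """Factory: WAVR values of single-acinus fields, sharp or defocused."""

    def make(n: int, seed0: int, defocused: bool, defocus_sigma: float = 3.0):
        values = []
        seed = seed0
        while len(values) < n:
            sim = SimulationConfig(
                n_acini=1,
                image_size=(96, 96),
                radius_range=(15.0, 28.0),
                phenotype_mix={"apical": 1.0},
                defocus_fraction=1.0 if defocused else 0.0,
                defocus_sigma=defocus_sigma,
                seed=seed,
            )
            pair, _ = simulate_field(sim)
            fa = analyze_field(pair, RunConfig(wavr_cutoff=0.0, min_area=100))
            values.extend(roi.wavr for roi in fa.rois if roi.wavr is not None)
            seed += 1
        return np.array(values[:n])

    return make
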
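import numpy as np
import pandas as pd
import pytest

from petrad.io import Cohort, PatientRecord, PETVolume, VOIMask
from petrad.features.quantize import QuantizedVOI

SPACING = (2.73, 2.73, 3.27)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_volume(values, spacing=SPACING):
    return PETVolume(np.asarray(values, dtype=float), spacing)


def make_mask(mask, spacing=SPACING):
    return VOIMask(np.asarray(mask, dtype=bool), spacing)


def quantized_from_levels(levels, n_levels):
    """Build a QuantizedVOI directly from an integer level grid (0 = outside)."""
    levels = np.asarray(levels, dtype=np.int32)
    return QuantizedVOI(levels, n_levels, 0.0, float(n_levels), SPACING)


def embedded(core, pad=1, fill=0.0):
    """Embed a small array in a zero border so masks do not touch the edge."""
    core = np.asarray(core, dtype=float)
    out = np.full(tuple(n + 2 * pad for n in core.shape), fill)
    sl = tuple(slice(pad, pad + n) for n in core.shape)
    out[sl] = core
    return out


def toy_cohort(features: dict[str, np.ndarray], y, visual=None, scanners=None) -> Cohort:
    """Cohort from raw feature arrays and labels."""
    y = np.asarray(y, dtype=int)
    n = len(y)
    visual = np.zeros(n, dtype=int) if visual is None else np.asarray(visual, dtype=int)
    scanners = ["s1"] * n if scanners is None else list(scanners)
    frame = pd.DataFrame(features, index=[f"p{i:03d}" for i in range(n)])
    records = [
        PatientRecord(f"p{i:03d}", int(y[i]), int(visual[i]), scanners[i])
        for i in range(n)
    ]
    return Cohort(records).with_features(frame)


def random_quantized(rng, shape=(4, 4, 4), n_levels=4, p_mask=0.6):
    """Random VOI for fuzzing: random mask, random levels in 1..n_levels."""
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return quantized_from_levels(levels, n_levels)
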
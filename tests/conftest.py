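import numpy as np
import pandas as pd
import pytest

from cnadiff.normalization import Log2Profile
from cnadiff.probe_io import ProbeSet


def make_profile(values, chrom="chr1", sample_id="s", spacing=1000, start0=1000):
    """Single- or multi-chromosome Log2Profile from plain value arrays.

    ``values`` may be an array (one chromosome) or a dict chrom -> array.
    """
    if not isinstance(values, dict):
        values = {chrom: np.asarray(values, float)}
    frames, vals = [], []
    k = 0
    for c, v in values.items():
        v = np.asarray(v, float)
        starts = start0 + spacing * np.arange(len(v))
        frames.append(pd.DataFrame({
            "probe_id": [f"P{k + i:06d}" for i in range(len(v))],
            "chrom": c,
            "start": starts,
            "end": starts + 60,
        }))
        vals.append(v)
        k += len(v)
    return Log2Profile(sample_id, pd.concat(frames, ignore_index=True),
                       np.concatenate(vals), ["test"])


def make_probeset(test, ref, gc=None, chrom="chr1", sample_id="s"):
    test = np.asarray(test, float)
    ref = np.asarray(ref, float)
    n = len(test)
    if gc is None:
        gc = np.full(n, 0.5)
    starts = 1000 + 1000 * np.arange(n)
    df = pd.DataFrame({
        "probe_id": [f"P{i:06d}" for i in range(n)],
        "chrom": chrom,
        "start": starts,
        "end": starts + 60,
        "intensity_test": test,
        "intensity_ref": ref,
        "gc": np.asarray(gc, float),
    })
    return ProbeSet(sample_id, df)


@pytest.fixture(scope="session")
def small_design():
    from cnadiff.synthetic import generate_design

    return generate_design(n_probes=4_000, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
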
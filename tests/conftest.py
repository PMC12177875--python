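import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mxraman as mx

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_study():
    """A reduced two-channel 5-class study, preprocessed and fused.

    Generation at 256 axis points and 6 spectra per sample keeps the whole
    suite fast while preserving the full class/sample/channel structure.
    """
    design = mx.paper_like_design(n_points=256, n_spectra_per_sample=6)
    result = mx.generate(design, seed=3)
    fp = {}
    fluor = {}
    for ch, raw in result.channels.items():
        fp[ch], fluor[ch] = mx.run_pipeline(raw, result.blanks[ch])
    mxset = mx.concatenate([fp["532nm"], fp["785nm"]])
    return {
        "design": design,
        "result": result,
        "fingerprints": fp,
        "fluorescence": fluor,
        "mx": mxset,
    }


@pytest.fixture()
def tiny_dataset():
    """A 2-class, 2-sample toy dataset with hand-set values."""
    rng = np.random.default_rng(7)
    n_per = 6
    rows, labels, samples, acq = [], [], [], []
    for cls, sample, shift in [
        ("control", "C1", 0.0),
        ("control", "C2", 0.0),
        ("disease", "D1", 1.0),
        ("disease", "D2", 1.0),
    ]:
        for a in range(n_per):
            rows.append(rng.normal(shift, 0.3, size=8))
            labels.append(cls)
            samples.append(sample)
            acq.append(a)
    import pandas as pd

    return mx.SpectralDataset(
        np.vstack(rows),
        pd.DataFrame(
            {"class_label": labels, "sample_id": samples, "acquisition_index": acq}
        ),
        pd.DataFrame(
            {"channel": ["532nm"] * 8, "wavenumber": np.linspace(600, 700, 8)}
        ),
    )
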
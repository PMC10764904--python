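import numpy as np
import pytest

from chronofp.features import FeatureTable
from chronofp.model import GridSpec
from chronofp.pipeline import RunConfig, run_patient
from chronofp.synthetic import SyntheticConfig, generate_patient


@pytest.fixture(scope="session")
def small_recording():
    """2-channel desk-scale patient with the default three-stage cascade."""
    cfg = SyntheticConfig(n_channels=2, n_seizures=4, interictal_gap_min=40.0,
                          seed=7)
    return cfg, generate_patient(cfg)


def make_table(n_windows: int, n_features: int = 3, seed: int = 0,
               channel: str = "C3") -> FeatureTable:
    """Dummy feature table on the 5-s window grid, for geometry tests."""
    rng = np.random.default_rng(seed)
    manifest = [(channel, f"f{i}") for i in range(n_features)]
    return FeatureTable(
        values=rng.standard_normal((n_windows, n_features)),
        window_times=np.arange(n_windows) * 5.0,
        manifest=manifest,
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full three-approach patient run with a single-cell grid."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        synthetic=SyntheticConfig(n_channels=2, n_seizures=4,
                                  interictal_gap_min=80.0, seed=11),
        grid=GridSpec(k_grid=(10,), c_grid=(1.0,), sop_grid=(10,)),
        seed=11,
        outdir=str(outdir),
    )
    results = run_patient(cfg)
    return cfg, results, outdir
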
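import numpy as np
import pytest

from qrsbench import SynthSpec, generate_ecg, make_benchmark_fixture
from qrsbench.pipeline import RunConfig, run_sweep
from qrsbench.records import EcgRecord

FS = 360.0


@pytest.fixture(scope="session")
def clean_record():
    """30 s of normal-morphology synthetic ECG with exact ground truth."""
    return generate_ecg(SynthSpec(duration_s=30.0, seed=1, record_id="clean"))


@pytest.fixture(scope="session")
def pulse_train():
    """10 identical QRS-like pulses at 60 bpm on an otherwise flat signal."""
    n = int(10.3 * FS)
    t = np.arange(n) / FS
    x = np.zeros(n)
    centers = 0.5 + np.arange(10)
    for c in centers:
        x += 1.0 * np.exp(-0.5 * ((t - c) / 0.012) ** 2)
    truth = np.round(centers * FS).astype(np.int64)
    return EcgRecord(record_id="train", fs=FS, samples=x), truth


@pytest.fixture(scope="session")
def fixture_db(tmp_path_factory):
    """The on-disk synthetic mini-database (clean + mixed records)."""
    path = tmp_path_factory.mktemp("minidb")
    info = make_benchmark_fixture(path, seed=123)
    return path, info


@pytest.fixture(scope="session")
def sweep_grid(fixture_db):
    """Full evaluation grid over the mini-database, all four detectors."""
    path, _ = fixture_db
    config = RunConfig(
        db_dir=str(path), noise_path=str(path / "ma_synth.hea"), convention="power"
    )
    return run_sweep(config)
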
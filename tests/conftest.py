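import numpy as np
import pandas as pd
import pytest

import lagbeta as lb


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_fingerprint():
    """Two samples, three bands, unnormalized intensities."""
    return lb.FingerprintMatrix(
        pd.DataFrame(
            [[2.0, 1.0, 1.0], [0.0, 4.0, 0.0]],
            index=["s1", "s2"],
            columns=["b1", "b2", "b3"],
        ),
        normalized=False,
    )


@pytest.fixture(scope="session")
def desk_sim():
    """One simulated desk-scale study, shared across tests (seed fixed)."""
    scenario = lb.preset("desk-small", seed=20240915)
    fp, md, truth = lb.simulate_series(scenario)
    return scenario, fp, md, truth


@pytest.fixture
def sim_csvs(tmp_path, desk_sim):
    """The desk-scale study written out as the three standard CSV inputs."""
    scenario, fp, md, truth = desk_sim
    lb.write_fingerprint(fp, tmp_path / "fingerprint.csv")
    md_out = md.reset_index()
    md_out["date"] = md_out["date"].dt.strftime("%Y-%m-%d")
    md_out.to_csv(tmp_path / "metadata.csv", index=False)
    chem = lb.simulate_chemistry(scenario, md, truth).copy()
    chem["date"] = pd.to_datetime(chem["date"]).dt.strftime("%Y-%m-%d")
    chem.to_csv(tmp_path / "chemistry.csv", index=False)
    return tmp_path
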
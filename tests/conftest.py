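import warnings

import numpy as np
import pandas as pd
import pytest

from famnorm.datatypes import (
    IntensityMatrix,
    MethylDataset,
    ProbeAnnotation,
    SampleSheet,
)
from famnorm.qc import run_qc
from famnorm.simulate import SimulationConfig, simulate_dataset

warnings.filterwarnings("ignore", category=UserWarning)


def small_config(**overrides) -> SimulationConfig:
    """Reduced cohort/array for fast unit tests; defaults otherwise."""
    base = dict(
        n_probes=800,
        n_samples=18,
        n_families=3,
        n_replicate_pairs=3,
        n_idmr=60,
        n_snps=20,
        n_background_snps=120,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def sim_pair():
    """One small simulated dataset plus truth (QC not applied)."""
    return simulate_dataset(small_config(), seed=11)


@pytest.fixture(scope="session")
def qc_dataset(sim_pair):
    dataset, _ = sim_pair
    filtered, _ = run_qc(dataset)
    return filtered


def toy_dataset(meth: np.ndarray, unmeth: np.ndarray, design=None, stratum=None, **kwargs) -> MethylDataset:
    """Hand-built MethylDataset around explicit intensity matrices."""
    from famnorm.transforms import beta_from_intensities

    n, s = meth.shape
    probes = [f"cg{i:05d}" for i in range(n)]
    samples = [f"s{j}" for j in range(s)]
    design = ["II"] * n if design is None else list(design)
    stratum = ["open_sea"] * n if stratum is None else list(stratum)
    ann = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": probes,
                "design_type": design,
                "channel": ["both" if d == "II" else "red" for d in design],
                "chromosome": ["chr1"] * n,
                "position": np.arange(1, n + 1) * 100,
                "region_stratum": stratum,
                "is_idmr": [False] * n,
                "cpg_body_count": [1] * n,
            }
        )
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "batch": ["B1"] * s,
                "family_id": ["F1"] * s,
                "replicate_group": [None] * s,
                "age": np.linspace(25, 80, s),
                "sex": ["F"] * s,
            }
        )
    )
    intens = IntensityMatrix(
        meth=pd.DataFrame(meth, index=probes, columns=samples, dtype=float),
        unmeth=pd.DataFrame(unmeth, index=probes, columns=samples, dtype=float),
        **kwargs,
    )
    beta = beta_from_intensities(intens)
    return MethylDataset(beta=beta.beta, annotation=ann, samples=sheet, intensities=intens)
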
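import numpy as np
import pandas as pd
import pytest

from epimsap import msap_scoring, synthetic_data
from epimsap.types import FragmentMatrix, PeakTable, PhenotypeTable, SampleMetadata


@pytest.fixture
def small_peaks() -> PeakTable:
    return PeakTable(pd.DataFrame({
        "sample_id": ["S01", "S01", "S01", "S02", "S02", "S02"],
        "digest": ["HPA", "HPA", "MSP", "HPA", "MSP", "MSP"],
        "size": [120.3, 1600.0, 120.4, 250.0, 250.2, 40.0],
        "height": [55.0, 500.0, 41.0, 40.0, 90.0, 300.0],
    }))


@pytest.fixture
def tiny_fragment_matrix() -> FragmentMatrix:
    # 4 samples x 3 loci covering every digest pattern plus a missing cell
    hpa = np.array([
        [1, 1, 0],
        [1, 0, 0],
        [0, 1, 1],
        [0, np.nan, 1],
    ], dtype=float)
    msp = np.array([
        [1, 0, 1],
        [1, 1, 0],
        [0, 0, 1],
        [1, 1, 0],
    ], dtype=float)
    return FragmentMatrix(samples=["A", "B", "C", "D"], loci=["L1", "L2", "L3"], hpa=hpa, msp=msp)


@pytest.fixture(scope="session")
def monitoring_dataset():
    """One seeded monitoring-style dataset scored through the pipeline."""
    cfg = synthetic_data.SimConfig(seed=7)
    fm, truth = synthetic_data.gen_msap(cfg)
    fm = msap_scoring.filter_prevalence(fm)
    sm = msap_scoring.classify_states(fm)
    sm, report = msap_scoring.partition_msl(sm)
    pheno, _ = synthetic_data.gen_phenotypes(cfg, truth.meta, truth)
    return {"cfg": cfg, "fm": fm, "sm": sm, "report": report, "truth": truth, "pheno": pheno}


@pytest.fixture
def meta_two_sites() -> SampleMetadata:
    rows = []
    for i in range(12):
        rows.append({
            "sample_id": f"S{i:02d}",
            "site": "TG" if i < 6 else "PS",
            "season": "DRY" if i % 2 == 0 else "WET",
            "status": "NONE",
        })
    return SampleMetadata(pd.DataFrame(rows))
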
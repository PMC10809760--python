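"""Shared fixtures: small handcrafted tables and seeded synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from redoxlag.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def noisefree_dataset():
    """Six-site synthetic core without coverage noise (exact trajectories)."""
    return simulate_all(SimulationConfig(noise_sigma=0.0), seed=101)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default six-site synthetic core with lognormal sigma = 0.3 noise."""
    return simulate_all(SimulationConfig(), seed=202)


@pytest.fixture
def small_catalog():
    return pd.DataFrame(
        {
            "mag_id": pd.array(["M1", "M2", "M3"], dtype="string"),
            "taxonomy": pd.array(
                [
                    "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Woeseiales;f__Woeseiaceae;g__;s__",
                    "d__Archaea;p__Thermoproteota;c__Nitrososphaeria;o__Nitrosopumilales;f__Nitrosopumilaceae;g__;s__",
                    "d__Bacteria;p__Chloroflexota;c__Anaerolineae;o__;f__;g__;s__",
                ],
                dtype="string",
            ),
            "completeness": [92.0, 80.5, 75.0],
            "redundancy": [3.1, 0.0, 9.9],
        }
    )


@pytest.fixture
def small_metadata():
    rows = []
    for site, (o2, no3, omega) in {
        "S1": (3.0, 8.0, 0.29),
        "S2": (4.0, 8.0, 0.76),
    }.items():
        for k, (top, bottom) in enumerate([(0, 1), (4, 5), (10, 12.5)]):
            rows.append(
                {
                    "sample_id": f"{site}_{k}",
                    "site_id": site,
                    "depth_top_cm": float(top),
                    "depth_bottom_cm": float(bottom),
                    "water_depth_m": 8000.0,
                    "o2_penetration_cm": o2,
                    "no3_penetration_cm": no3,
                    "sedimentation_rate_mm_yr": omega,
                }
            )
    df = pd.DataFrame(rows)
    for c in ("sample_id", "site_id"):
        df[c] = df[c].astype("string")
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
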
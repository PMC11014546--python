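import numpy as np
import pandas as pd
import pytest

from pertmap import ProfileTable, from_dataframe


@pytest.fixture
def small_table() -> ProfileTable:
    """2 perturbations x 3 replicates + 6 controls, 2 features, hand-set."""
    rng = np.random.default_rng(42)
    rows = []
    for pert in ("a", "b"):
        for rep in range(3):
            rows.append(
                {
                    "Metadata_pert": pert,
                    "Metadata_control": False,
                    "Metadata_plate": f"p{rep + 1}",
                }
            )
    for _ in range(6):
        rows.append(
            {"Metadata_pert": "ctrl", "Metadata_control": True, "Metadata_plate": "p1"}
        )
    df = pd.DataFrame(rows)
    df["f1"] = rng.normal(size=len(df))
    df["f2"] = rng.normal(size=len(df))
    return from_dataframe(df)


@pytest.fixture
def plate_layout_table() -> ProfileTable:
    """2 perturbations, 6 replicates each as 2 wells x 3 plates, plus controls.

    Mirrors a screen where each perturbation sits in the same two well
    positions on three replicate plates.
    """
    rng = np.random.default_rng(7)
    rows = []
    for pert in ("g1", "g2"):
        for plate in ("P1", "P2", "P3"):
            for well in ("A1", "B2"):
                rows.append(
                    {
                        "Metadata_pert": pert,
                        "Metadata_plate": plate,
                        "Metadata_well": well,
                        "Metadata_control": False,
                    }
                )
    for plate in ("P1", "P2", "P3"):
        for well in ("C3", "D4"):
            rows.append(
                {
                    "Metadata_pert": "ctrl",
                    "Metadata_plate": plate,
                    "Metadata_well": well,
                    "Metadata_control": True,
                }
            )
    df = pd.DataFrame(rows)
    for j in range(4):
        df[f"f{j + 1}"] = rng.normal(size=len(df))
    return from_dataframe(df)
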
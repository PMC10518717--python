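import numpy as np
import pandas as pd
import pytest

import mdscreen as m


@pytest.fixture
def channel_map_10():
    """Channel map for a 10-channel 5-vs-5 reporter design."""
    rows = []
    for i in range(10):
        cond = "A" if i < 5 else "B"
        rows.append(
            {
                "label": f"{cond}{i % 5 + 1}",
                "column": f"Reporter intensity corrected {i + 1}",
                "condition": cond,
                "plex": 1,
                "bridge": False,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def protein_groups_file(tmp_path, channel_map_10):
    """Write a small MaxQuant-style proteinGroups.txt fixture."""
    rng = np.random.default_rng(11)
    n = 10
    df = pd.DataFrame(
        {
            "Protein IDs": [f"P{i};ALT{i}" for i in range(n)],
            "Gene names": [f"Gene{i}" for i in range(n)],
            "Unique peptides": [1 if i == 3 else 5 for i in range(n)],
            "MS/MS count": 20,
            "Potential contaminant": ["+" if i == 0 else "" for i in range(n)],
            "Reverse": ["+" if i == 1 else "" for i in range(n)],
            "Only identified by site": [
                "+" if i == 2 else "" for i in range(n)
            ],
        }
    )
    for col in channel_map_10["column"]:
        df[col] = rng.integers(1000, 100000, size=n).astype(float)
    # a zero reporter value (non-detection) and a sparse row
    df.loc[4, channel_map_10["column"][0]] = 0.0
    for col in channel_map_10["column"][:8]:
        df.loc[5, col] = 0.0
    path = tmp_path / "proteinGroups.txt"
    df.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def toy_matrix():
    """4-row 2-channel matrix with channel medians 10 and 40 and a
    pooled median of 20."""
    intensities = pd.DataFrame(
        {"c1": [5.0, 10.0, 10.0, 20.0], "c2": [20.0, 40.0, 40.0, 100.0]},
        index=pd.Index(["p1", "p2", "p3", "p4"], name="protein"),
    )
    channels = m.make_channel_table(["c1", "c2"])
    return m.ReporterMatrix(intensities, channels)
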
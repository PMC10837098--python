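import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from phosphoflow.model import SampleDesign


def _design_rows(n_channels: int, plex_id: str = "plex1", ref_last: bool = True):
    rows = []
    combos = [(g, t, tm) for g in ("WT", "quad") for t in ("mock", "flg22") for tm in (3, 15)]
    for k in range(n_channels - (1 if ref_last else 0)):
        g, t, tm = combos[k % len(combos)]
        rep = k // len(combos) + 1
        rows.append(
            dict(sample_id=f"{plex_id}_{g}_{t}_{tm}_r{rep}", genotype=g, treatment=t,
                 time_min=tm, replicate=rep, plex_id=plex_id, channel_id=str(k + 1),
                 is_reference=False)
        )
    if ref_last:
        rows.append(
            dict(sample_id=f"ref_{plex_id}", genotype="pool", treatment="pool",
                 time_min=0, replicate=0, plex_id=plex_id, channel_id=str(n_channels),
                 is_reference=True)
        )
    return rows


@pytest.fixture
def small_design() -> SampleDesign:
    """One 4-channel plex: 3 samples + 1 pooled reference."""
    return SampleDesign(pd.DataFrame(_design_rows(4)))


@pytest.fixture
def two_plex_design() -> SampleDesign:
    """Two 4-channel plexes sharing a pooled reference layout."""
    rows = _design_rows(4, "plex1") + _design_rows(4, "plex2")
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
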
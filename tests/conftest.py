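import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from miredit.io_formats import HairpinRecord, MatureAnnotation

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_reference():
    """Two hand-built hairpins, one mature arm each (3p), 1-based coords.

    h1: 3p mature = positions 21..41 (21 nt), with an adenosine at mature
    position 6 in a U_A_G context.
    """
    m1 = "CUCAUAGGGAAAAUCCACGUU"  # mature of h1; pos 5..7 = U A G
    m2 = "GGGCCCGGGCCCGGGCCCGGG"  # mature of h2; no adenosines
    h1 = "ACGUGGAUUUUCCCUAAUGAG" + "CGUACGUACGUA" + m1 + "ACG"
    h2 = "CCCGGGCCCGGGCCCGGGCCC" + "AUCGAUCGAUCG" + m2
    hairpins = {
        "h1": HairpinRecord("h1", h1),
        "h2": HairpinRecord("h2", h2),
    }
    annotations = [
        MatureAnnotation("m1-3p", "h1", 34, 54, "3p"),
        MatureAnnotation("m2-3p", "h2", 34, 54, "3p"),
    ]
    assert h1[33:54] == m1 and h2[33:54] == m2
    return hairpins, annotations


@pytest.fixture
def two_group_design():
    return pd.DataFrame(
        {
            "sample_id": [f"c{i}" for i in range(1, 4)] + [f"p{i}" for i in range(1, 4)],
            "group": ["control"] * 3 + ["case"] * 3,
        }
    )
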
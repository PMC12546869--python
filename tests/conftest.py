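from pathlib import Path

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def h3k36_golden() -> pd.DataFrame:
    """Published H3K36 PRM inclusion-list m/z values (golden file)."""
    return pd.read_csv(DATA_DIR / "h3k36_inclusion_golden.csv")
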
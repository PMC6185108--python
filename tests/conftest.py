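import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from glycoshift import CONTROL, MUTANT, ProteinRecord, QuantMatrix, SampleDesign

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def design_4v4() -> list[SampleDesign]:
    return [
        *(SampleDesign(f"C{i}", CONTROL, i) for i in range(1, 5)),
        *(SampleDesign(f"M{i}", MUTANT, i) for i in range(1, 5)),
    ]


@pytest.fixture()
def make_matrix(design_4v4):
    """Build a QuantMatrix from {feature_id: 8 raw values} (None = MISSING)."""

    def build(rows: dict, kind: str = "glycosite", design=None) -> QuantMatrix:
        design = design or design_4v4
        df = pd.DataFrame.from_dict(
            {k: [np.nan if v is None else float(v) for v in vals] for k, vals in rows.items()},
            orient="index",
            columns=[s.sample_id for s in design],
        )
        return QuantMatrix(df, design, kind)

    return build


@pytest.fixture()
def toy_protein() -> ProteinRecord:
    #             123456789012345
    return ProteinRecord("P1", "FANGSMANPTMNNSS")
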
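import numpy as np
import pandas as pd
import pytest

from metaboclust.io import IntensityTable


def make_table(
    values: np.ndarray,
    state: str = "raw",
    labels: list[str] | None = None,
    meta_extra: dict | None = None,
    metabolites: list[str] | None = None,
) -> IntensityTable:
    """Build an IntensityTable from a plain array (samples x metabolites)."""
    values = np.asarray(values, float)
    n, m = values.shape
    samples = [f"s{i}" for i in range(n)]
    metabolites = metabolites or [f"met{j}" for j in range(m)]
    if labels is None:
        labels = ["case"] * (n // 2) + ["control"] * (n - n // 2)
    meta = pd.DataFrame({"status": labels}, index=pd.Index(samples, name="sample_id"))
    for k, v in (meta_extra or {}).items():
        meta[k] = v
    return IntensityTable(
        values=pd.DataFrame(values, index=meta.index, columns=metabolites),
        sample_meta=meta,
        trait="status",
        case_label="case",
        state=state,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def intensity_csv(tmp_path):
    """A 3-sample, 2-metabolite CSV with one empty (missing) cell."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "sample_id,status,gender,ala,glc\n"
        "s1,case,F,4,7\n"
        "s2,control,M,2,\n"
        "s3,case,F,1,5\n"
    )
    return path
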
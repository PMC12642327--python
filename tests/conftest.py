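import numpy as np
import pandas as pd
import pytest

from diadetect.io import DIANN_DIALECT, REPORT_COLUMNS


@pytest.fixture
def annotations_4v5() -> pd.DataFrame:
    """A 4 Dep vs 5 Non-dep annotation table."""
    rows = [(f"Dep_{i}", "Dep", "F" if i % 2 else "M") for i in range(1, 5)]
    rows += [(f"NonDep_{i}", "NonDep", "F" if i % 2 else "M") for i in range(1, 6)]
    return pd.DataFrame(rows, columns=["run_id", "group", "sex"])


@pytest.fixture
def report_writer(tmp_path):
    """Write a canonical-column DataFrame as a DIA-NN-dialect TSV."""

    def _write(df: pd.DataFrame, name: str = "report.tsv"):
        out = df.copy()
        out.columns = [DIANN_DIALECT[c] for c in REPORT_COLUMNS]
        path = tmp_path / name
        out.to_csv(path, sep="\t", index=False)
        return path

    return _write


def make_report_df(rows) -> pd.DataFrame:
    """Rows of (run, protein, gene, precursor, quantity, q1, q2, q3)."""
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


@pytest.fixture(scope="session")
def study_like():
    """One shared realization of the study-shaped synthetic fixture."""
    from diadetect.simulate import make_study_like_fixture

    return make_study_like_fixture(seed=12345)
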
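import pandas as pd
import pytest

from capl2 import NormTable, load_config, load_norms


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def norms():
    return load_norms()


@pytest.fixture()
def toy_norms():
    """A tiny hand-built norms table with easy-to-reason-about intervals."""
    rows = []
    for gender in ("girl", "boy"):
        for age in range(8, 13):
            for category, lower, upper in [
                ("beginning", 0, 10),
                ("progressing", 10, 20),
                ("achieving", 20, 25),
                ("excelling", 25, 30),
            ]:
                rows.append(("pc", gender, age, category, lower, upper))
                rows.append(("pacer", gender, age, category, lower / 3, upper / 3))
    return NormTable(
        pd.DataFrame(rows, columns=["protocol", "gender", "age", "category", "lower", "upper"])
    )
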
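import numpy as np
import pandas as pd
import pytest

from p3rl.datamodel import ColumnSpec, RecordTable, Role
from p3rl.encryption import EncryptionConfig


@pytest.fixture
def small_schema():
    return [
        ColumnSpec("ID", Role.SITE_ID),
        ColumnSpec("SURNAME", Role.SENSITIVE_STRING),
        ColumnSpec("FIRSTNAME", Role.SENSITIVE_STRING),
        ColumnSpec("SEX", Role.PLAIN),
        ColumnSpec("DOB", Role.SENSITIVE_DATE),
    ]


def make_table(schema, rows, site_label="A"):
    df = pd.DataFrame(rows, columns=[c.name for c in schema], dtype=str)
    return RecordTable(schema, df, site_label=site_label)


@pytest.fixture
def small_table(small_schema):
    rows = [
        {"ID": "1", "SURNAME": "Grün", "FIRSTNAME": "Willi", "SEX": "m",
         "DOB": "13.05.1980"},
        {"ID": "2", "SURNAME": "Meier Huber", "FIRSTNAME": "Anna",
         "SEX": "f", "DOB": "01.12.1975"},
        {"ID": "3", "SURNAME": "von der Berg-Meyer", "FIRSTNAME": "Käthi",
         "SEX": "f", "DOB": "29.02.1980"},
    ]
    return make_table(small_schema, rows)


@pytest.fixture
def crypt_cfg():
    return EncryptionConfig(secret_key=b"shared-test-key",
                            test_word="heimlich", q=2, k=10, m=1000)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
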
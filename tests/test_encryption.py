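import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p3rl import _namepools
from p3rl.comparison import dice
from p3rl.datamodel import ProtocolViolation
from p3rl.encryption import (BloomFilterValue, ConfigError, EncryptionConfig,
                             bloom_encode, bloom_to_hex, encrypt_date,
                             encrypt_table, hex_to_bloom, make_validation,
                             qgrams, verify_validation)
from p3rl.masking import mask_table
from p3rl.preprocessing import compile_template, infer_structure, apply_template
from conftest import make_table


@pytest.mark.parametrize("s, q, pad, expected", [
    ("GRUEN", 2, False, ["GR", "RU", "UE", "EN"]),
    ("A", 2, True, ["_A", "A_"]),
    ("", 2, True, []),
    ("AB", 3, True, ["__A", "_AB", "AB_", "B__"]),
    ("ABC", 1, False, ["A", "B", "C"]),
])
def test_qgrams(s, q, pad, expected):
    assert qgrams(s, q, pad) == expected


def test_bloom_encode_deterministic(crypt_cfg):
    a = bloom_encode("GRUEN", crypt_cfg)
    b = bloom_encode("GRUEN", crypt_cfg)
    assert a == b
    assert a.m == crypt_cfg.m


def test_bloom_encode_popcount_bound():
    cfg = EncryptionConfig(b"k", q=2, k=2, m=28, pad_qgrams=False)
    bf = bloom_encode("ABCD", cfg)       # 3 bigrams, 2 hashes
    assert 1 <= bf.popcount <= 6


def test_bloom_encode_empty_is_all_zero(crypt_cfg):
    assert bloom_encode("", crypt_cfg).popcount == 0


def test_bloom_different_keys_give_random_overlap(rng):
    # under different keys the Dice of two encodings of the SAME name should
    # fall to the chance level implied by the fill fractions
    cfg1 = EncryptionConfig(b"key-one", q=2, k=10, m=1000)
    cfg2 = EncryptionConfig(b"key-two", q=2, k=10, m=1000)
    names = rng.choice(_namepools.SURNAMES, size=300)
    observed, expected = [], []
    for name in names:
        a, b = bloom_encode(name.upper(), cfg1), bloom_encode(name.upper(),
                                                              cfg2)
        observed.append(dice(a, b).d)
        f1, f2 = a.popcount / a.m, b.popcount / b.m
        expected.append(2 * f1 * f2 / (f1 + f2))
    assert abs(np.mean(observed) - np.mean(expected)) < 0.02


@pytest.mark.parametrize("bits, m, hexstr", [
    ([], 28, "0000000"),
    ([0], 8, "80"),
    ([7], 8, "01"),
    ([0, 4], 8, "88"),
])
def test_hex_coding_convention(bits, m, hexstr):
    arr = np.zeros(m, dtype=np.uint8)
    arr[bits] = 1
    assert bloom_to_hex(BloomFilterValue(arr)) == hexstr


def test_hex_round_trip_random_filters(rng):
    for m in (28, 800, 1000):
        for _ in range(50):
            bits = (rng.random(m) < 0.3).astype(np.uint8)
            bf = BloomFilterValue(bits)
            assert hex_to_bloom(bloom_to_hex(bf), m) == bf


def test_hex_length_mismatch_rejected():
    with pytest.raises(ConfigError):
        hex_to_bloom("00", 28)


def test_config_rejects_bad_parameters():
    with pytest.raises(ConfigError):
        EncryptionConfig(b"k", m=30)     # not a multiple of 4
    with pytest.raises(ConfigError):
        EncryptionConfig(b"k", k=0)


@settings(max_examples=100, deadline=None)
@given(st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ", max_size=12))
def test_bloom_hex_round_trip_property(s):
    cfg = EncryptionConfig(b"prop-key", q=2, k=5, m=256)
    bf = bloom_encode(s, cfg)
    assert hex_to_bloom(bloom_to_hex(bf), cfg.m) == bf


# ---------------------------------------------------------------------------
# Dates
# ---------------------------------------------------------------------------

def test_encrypt_date_neighbour_sections_use_calendar(crypt_cfg):
    dec31 = encrypt_date("1980-12-31", crypt_cfg)
    jan1 = encrypt_date("1981-01-01", crypt_cfg)
    assert dec31.h_plus1 == jan1.h_full
    assert jan1.h_minus1 == dec31.h_full
    feb28 = encrypt_date("2000-02-28", crypt_cfg)
    feb29 = encrypt_date("2000-02-29", crypt_cfg)
    assert feb28.h_plus1 == feb29.h_full   # leap year honoured


def test_encrypt_date_deterministic_across_sites(crypt_cfg):
    cfg2 = EncryptionConfig(secret_key=b"shared-test-key",
                            test_word="heimlich", q=2, k=10, m=1000)
    assert encrypt_date("1955-07-02", crypt_cfg) == encrypt_date("1955-07-02",
                                                                 cfg2)


def test_encrypt_date_missing_and_invalid(crypt_cfg):
    ed = encrypt_date("", crypt_cfg)
    assert ed.missing and ed.h_full == ""
    with pytest.raises(ValueError):
        encrypt_date("1980-02-31", crypt_cfg)


def test_date_sections_have_distinct_framings(crypt_cfg):
    # day 12 must never collide with month 12 in the dedicated sections
    ed = encrypt_date("1980-12-12", crypt_cfg)
    assert ed.h_day != ed.h_month
    assert ed.x_day == ed.x_month          # shared framing, same value


# ---------------------------------------------------------------------------
# Table encryption
# ---------------------------------------------------------------------------

def _cleaned(small_table):
    tpl = compile_template(infer_structure(mask_table(small_table)))
    return apply_template(small_table, tpl)


def test_encrypt_table_requires_cleaned_input(small_table, crypt_cfg):
    with pytest.raises(ProtocolViolation):
        encrypt_table(small_table, crypt_cfg)


def test_encrypt_table_column_layout(small_table, crypt_cfg):
    enc = encrypt_table(_cleaned(small_table), crypt_cfg)
    # 4 name slots -> 4 hex columns; 1 date -> year + sections
    assert list(enc.df.columns) == ["ID", "SURNAME1", "SURNAME2",
                                    "FIRSTNAME1", "FIRSTNAME2", "SEX",
                                    "DOB_year", "DOB_enc"]
    assert enc.df.loc[0, "DOB_year"] == "1980"
    assert len(enc.df.loc[0, "SURNAME1"]) == crypt_cfg.m // 4
    assert enc.df.loc[0, "SURNAME2"] == ""     # missing propagates


def test_encrypt_table_no_plaintext_leak(small_table, crypt_cfg):
    enc = encrypt_table(_cleaned(small_table), crypt_cfg)
    blob = enc.df.to_csv()
    for sentinel in ("GRUEN", "Grün", "MEIER", "WILLI", "1980-05-13",
                     "13.05.1980", "shared-test-key"):
        assert sentinel not in blob


def test_encrypt_table_cross_run_determinism(small_table, crypt_cfg, tmp_path):
    cleaned = _cleaned(small_table)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    encrypt_table(cleaned, crypt_cfg).to_csv(p1)
    encrypt_table(cleaned, crypt_cfg).to_csv(p2)
    assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# Validation token
# ---------------------------------------------------------------------------

def test_validation_pass_and_failure_modes(crypt_cfg):
    tok_a = make_validation(crypt_cfg)
    tok_b = make_validation(EncryptionConfig(b"shared-test-key",
                                             test_word="heimlich",
                                             q=2, k=10, m=1000))
    ok, _ = verify_validation(tok_a, tok_b)
    assert ok

    wrong_key = make_validation(EncryptionConfig(b"shared-test-kez",
                                                 test_word="heimlich",
                                                 q=2, k=10, m=1000))
    ok, reason = verify_validation(tok_a, wrong_key)
    assert not ok and "digest" in reason

    wrong_m = make_validation(EncryptionConfig(b"shared-test-key",
                                               test_word="heimlich",
                                               q=2, k=10, m=800))
    ok, reason = verify_validation(tok_a, wrong_m)
    assert not ok and "parameter" in reason and "m" in reason


def test_validation_token_never_contains_key(tmp_path, crypt_cfg):
    p = tmp_path / "val.json"
    make_validation(crypt_cfg).to_json(p)
    text = p.read_text()
    assert "shared-test-key" not in text and "heimlich" not in text


# ---------------------------------------------------------------------------
# Aggregate similarity properties
# ---------------------------------------------------------------------------

def _qgram_set_dice(a: str, b: str, q: int, pad: bool) -> float:
    sa, sb = set(qgrams(a, q, pad)), set(qgrams(b, q, pad))
    if not sa and not sb:
        return 1.0
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def test_bloom_dice_tracks_qgram_dice(rng):
    # measured unpadded: padding roughly doubles the set-bit count per name
    # and with it the chance-collision floor of the Dice estimate
    cfg = EncryptionConfig(b"shared-test-key", q=2, k=10, m=1000,
                           pad_qgrams=False)
    names = [s.upper() for s in _namepools.SURNAMES]
    diffs = []
    for _ in range(300):
        a, b = rng.choice(names), rng.choice(names)
        bd = dice(bloom_encode(a, cfg), bloom_encode(b, cfg)).d
        diffs.append(abs(bd - _qgram_set_dice(a, b, cfg.q, False)))
    assert np.mean(diffs) < 0.05


def test_bloom_dice_decreases_with_edit_distance(crypt_cfg, rng):
    # expected Dice over random name pairs is non-increasing in the number
    # of random single-character substitutions applied
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    names = [s.upper() for s in rng.choice(_namepools.SURNAMES, 200)]
    means = []
    for k_edits in range(5):
        vals = []
        for name in names:
            name = "".join(c for c in name if c in letters) or "MEIER"
            edited = list(name)
            pos = rng.choice(len(edited), size=min(k_edits, len(edited)),
                             replace=False)
            for p in pos:
                edited[p] = letters[rng.integers(26)]
            vals.append(dice(bloom_encode(name, crypt_cfg),
                             bloom_encode("".join(edited), crypt_cfg)).d)
        means.append(np.mean(vals))
    assert all(means[i] >= means[i + 1] - 0.01 for i in range(4))
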
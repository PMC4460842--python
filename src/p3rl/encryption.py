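"""Bloom-filter and keyed-hash encryption of cleaned linkage variables.

Names are encoded as field-level Bloom filters: each cleaned token is split
into overlapping q-grams and every q-gram sets k bit positions of an m-bit
array, with positions derived from two independent keyed hashes by double
hashing, ``p_i = (H1(g) + i*H2(g)) mod m``.  Two sites holding the same
secret key produce bit-identical filters for identical cleaned values, and
*similar* values share most of their q-grams, hence most of their set bits —
which is what makes Dice-coefficient comparison of encrypted names possible.

Dates are hashed section-wise with an HMAC (SHA-256, truncated to 160 bits):
plain year, keyed digests of day, month, full date and the calendar-correct
previous/next day, plus auxiliary digests of the bare two-digit day and month
under a shared framing so the linkage centre can test for swapped day/month
without ever seeing the components.

A validation token — the keyed digest of an agreed secret test word together
with the public parameter fingerprint — lets the linkage centre verify that
both sites encrypted identically before any comparison is attempted.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import hmac
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (MISSING, ColumnSpec, ProtocolViolation, RecordTable,
                        Role, config_fingerprint)

PAD_CHAR = "_"
_DIGEST_HEX = 40  # 160-bit sections, hex-coded

_HEX_NIBBLE = np.array([8, 4, 2, 1], dtype=np.uint8)


class ConfigError(ValueError):
    pass


@dataclass
class EncryptionConfig:
    """Site-agreed encryption parameters.

    ``secret_key`` and ``test_word`` are the shared secrets; ``q``/``k``/``m``
    are public and fingerprinted so parameter divergence between sites is
    detectable without revealing the key.
    """

    secret_key: bytes
    test_word: str = ""
    q: int = 2
    k: int = 10
    m: int = 1000
    pad_qgrams: bool = True
    mac: str = "hmac-sha256-160"

    def __post_init__(self) -> None:
        if isinstance(self.secret_key, str):
            self.secret_key = self.secret_key.encode()
        if self.q < 1 or self.k < 1:
            raise ConfigError("q and k must be >= 1")
        if self.m < 4 or self.m % 4:
            raise ConfigError("m must be a positive multiple of 4")

    def public_params(self) -> dict:
        return {"q": self.q, "k": self.k, "m": self.m,
                "pad": self.pad_qgrams, "mac": self.mac}

    def fingerprint(self) -> str:
        return config_fingerprint(self.public_params())

    # derived keys: one per context so name and date digests never collide
    def _subkey(self, label: bytes) -> bytes:
        return hmac.new(self.secret_key, label, hashlib.sha256).digest()


# ---------------------------------------------------------------------------
# Bloom filters
# ---------------------------------------------------------------------------

@dataclass
class BloomFilterValue:
    """Fixed-length bit array, the encrypted form of one name field."""

    bits: np.ndarray  # uint8 0/1, length m

    @property
    def m(self) -> int:
        return len(self.bits)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    @property
    def hex(self) -> str:
        return bloom_to_hex(self)

    def __eq__(self, other) -> bool:
        return (isinstance(other, BloomFilterValue)
                and np.array_equal(self.bits, other.bits))


def qgrams(s: str, q: int, pad: bool = True) -> list[str]:
    """Overlapping substrings of length q; optional boundary padding."""
    if not s:
        return []
    if pad:
        s = PAD_CHAR * (q - 1) + s + PAD_CHAR * (q - 1)
    if len(s) < q:
        return [s]
    return [s[i:i + q] for i in range(len(s) - q + 1)]


def bloom_encode(s: str, cfg: EncryptionConfig) -> BloomFilterValue:
    """Encode one cleaned token as a keyed Bloom filter (deterministic)."""
    bits = np.zeros(cfg.m, dtype=np.uint8)
    if s:
        k1 = cfg._subkey(b"P3RL-H1")
        k2 = cfg._subkey(b"P3RL-H2")
        for g in qgrams(s, cfg.q, cfg.pad_qgrams):
            gb = g.encode()
            h1 = int.from_bytes(hmac.new(k1, gb, hashlib.sha256).digest()[:8],
                                "big")
            h2 = int.from_bytes(hmac.new(k2, gb, hashlib.sha256).digest()[:8],
                                "big")
            for i in range(1, cfg.k + 1):
                bits[(h1 + i * h2) % cfg.m] = 1
    return BloomFilterValue(bits=bits)


def bloom_to_hex(bf: BloomFilterValue) -> str:
    """Hex-code a filter, four bits per character, bit 0 the MSB of nibble 0."""
    nibbles = bf.bits.reshape(-1, 4) @ _HEX_NIBBLE
    return "".join("0123456789ABCDEF"[v] for v in nibbles)


def hex_to_bloom(hexstr: str, m: int) -> BloomFilterValue:
    if len(hexstr) * 4 != m:
        raise ConfigError(
            f"hex length {len(hexstr)} does not match m={m}")
    vals = np.array([int(c, 16) for c in hexstr], dtype=np.uint8)
    bits = ((vals[:, None] >> np.array([3, 2, 1, 0])) & 1).astype(np.uint8)
    return BloomFilterValue(bits=bits.reshape(-1))


# ---------------------------------------------------------------------------
# Dates
# ---------------------------------------------------------------------------

@dataclass
class EncryptedDate:
    """Plain year plus keyed-hash sections of one date.

    ``h_day``/``h_month`` carry distinct framings ("D:", "M:") so a day digest
    can never match a month digest; ``x_day``/``x_month`` are auxiliary
    digests of the bare two-digit value under a shared framing ("X:") that
    exist solely to make the swapped-day/month test possible.
    """

    plain_year: int | None
    h_day: str = ""
    h_month: str = ""
    h_full: str = ""
    h_minus1: str = ""
    h_plus1: str = ""
    x_day: str = ""
    x_month: str = ""

    @property
    def missing(self) -> bool:
        return self.plain_year is None

    def sections(self) -> str:
        return "|".join([self.h_day, self.h_month, self.h_full,
                         self.h_minus1, self.h_plus1,
                         self.x_day, self.x_month])

    @classmethod
    def from_columns(cls, year: str, sections: str) -> "EncryptedDate":
        if year == MISSING or sections == MISSING:
            return cls(plain_year=None)
        parts = sections.split("|")
        if len(parts) != 7:
            raise ConfigError("malformed encrypted date sections")
        return cls(plain_year=int(year), h_day=parts[0], h_month=parts[1],
                   h_full=parts[2], h_minus1=parts[3], h_plus1=parts[4],
                   x_day=parts[5], x_month=parts[6])


def encrypt_date(iso_date: str, cfg: EncryptionConfig) -> EncryptedDate:
    """Section-wise keyed encryption of one ISO date (or missing)."""
    if iso_date == MISSING:
        return EncryptedDate(plain_year=None)
    d = _dt.date.fromisoformat(iso_date)  # raises on invalid input
    kd = cfg._subkey(b"P3RL-DATE")

    def dig(msg: str) -> str:
        return hmac.new(kd, msg.encode(),
                        hashlib.sha256).hexdigest()[:_DIGEST_HEX].upper()

    return EncryptedDate(
        plain_year=d.year,
        h_day=dig(f"D:{d.day:02d}"),
        h_month=dig(f"M:{d.month:02d}"),
        h_full=dig(f"F:{d.isoformat()}"),
        h_minus1=dig(f"F:{(d - _dt.timedelta(days=1)).isoformat()}"),
        h_plus1=dig(f"F:{(d + _dt.timedelta(days=1)).isoformat()}"),
        x_day=dig(f"X:{d.day:02d}"),
        x_month=dig(f"X:{d.month:02d}"),
    )


# ---------------------------------------------------------------------------
# Table encryption
# ---------------------------------------------------------------------------

class Encryptor:
    """Memoizing wrapper: identical tokens/dates hash once per table."""

    def __init__(self, cfg: EncryptionConfig):
        self.cfg = cfg
        self._blooms: dict[str, str] = {}
        self._dates: dict[str, EncryptedDate] = {}

    def bloom_hex(self, token: str) -> str:
        if token not in self._blooms:
            self._blooms[token] = bloom_to_hex(bloom_encode(token, self.cfg))
        return self._blooms[token]

    def date(self, iso: str) -> EncryptedDate:
        if iso not in self._dates:
            self._dates[iso] = encrypt_date(iso, self.cfg)
        return self._dates[iso]


def encrypt_table(t: RecordTable, cfg: EncryptionConfig) -> RecordTable:
    """Encrypt every sensitive column of a cleaned table.

    Name columns become hex-coded Bloom filters under their original names;
    each date column ``D`` becomes the pair ``D_year`` (plain) and ``D_enc``
    (the hash sections).  Site identifier and plain columns pass through.
    The secret key reaches no output; only the public parameter fingerprint
    is recorded.
    """
    if "cleaned" not in t.meta:
        raise ProtocolViolation(
            "encryption requires a template-cleaned table (audit flag absent)")
    enc = Encryptor(cfg)
    out_cols: list[ColumnSpec] = []
    data: dict[str, list[str]] = {}
    for spec in t.columns:
        vals = t.df[spec.name]
        if spec.role is Role.SENSITIVE_STRING:
            data[spec.name] = [enc.bloom_hex(v) if v != MISSING else MISSING
                               for v in vals]
            out_cols.append(ColumnSpec(spec.name, Role.PAYLOAD,
                                       declared_format=f"bloom_hex:m={cfg.m}"))
        elif spec.role is Role.SENSITIVE_DATE:
            eds = [enc.date(v) for v in vals]
            data[spec.name + "_year"] = [
                MISSING if e.missing else str(e.plain_year) for e in eds]
            data[spec.name + "_enc"] = [
                MISSING if e.missing else e.sections() for e in eds]
            out_cols.append(ColumnSpec(spec.name + "_year", Role.PLAIN,
                                       declared_format="date_year"))
            out_cols.append(ColumnSpec(spec.name + "_enc", Role.PAYLOAD,
                                       declared_format="date_sections"))
        else:
            data[spec.name] = list(vals)
            out_cols.append(spec)
    df = pd.DataFrame(data, dtype=str)
    out = RecordTable(out_cols, df, t.site_label, dict(t.meta))
    out.meta["encrypted"] = cfg.fingerprint()
    return out


# ---------------------------------------------------------------------------
# Validation token
# ---------------------------------------------------------------------------

@dataclass
class ValidationToken:
    """Proof that a site used the agreed key, word and public parameters."""

    digest: str
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"digest": self.digest, "params": self.params}, fh,
                      indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ValidationToken":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(digest=doc["digest"], params=doc["params"])


def make_validation(cfg: EncryptionConfig) -> ValidationToken:
    kd = cfg._subkey(b"P3RL-VALIDATE")
    digest = hmac.new(kd, cfg.test_word.encode(),
                      hashlib.sha256).hexdigest().upper()
    return ValidationToken(digest=digest, params=cfg.public_params())


def verify_validation(tok_a: ValidationToken,
                      tok_b: ValidationToken) -> tuple[bool, str]:
    """Pass iff digests and parameter fingerprints agree.

    The reason string names the diverging component without revealing keys.
    """
    try:
        da, db = tok_a.digest, tok_b.digest
        pa, pb = tok_a.params, tok_b.params
    except AttributeError:
        return False, "malformed token"
    if not (isinstance(da, str) and isinstance(db, str) and da and db):
        return False, "malformed token"
    if pa != pb:
        diff = sorted(set(pa.items()) ^ set(pb.items()))
        return False, f"parameter mismatch: {sorted({k for k, _ in diff})}"
    if not hmac.compare_digest(da, db):
        return False, "digest mismatch (different key or test word)"
    return True, "ok"
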
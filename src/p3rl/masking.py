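"""Masking and shuffling: disclose data structure without disclosing content.

Masking substitutes character classes in place — digits 1-9 become ``9``,
ASCII lower-case letters become ``z``, upper-case become ``Z`` — while the
first character of each cell, the digit zero, spaces and any character outside
ASCII alphanumerics (umlauts, accents, punctuation) pass through unchanged.
The masked copy reveals field lengths, separators, date layouts, embedded
digits and candidate missing-value codes, which is exactly what the linkage
centre needs to compile a cleaning template, and nothing more.

Shuffling additionally permutes each column independently so that the masked
cells of one row no longer belong to one person.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ColumnSpec, ProtocolViolation, RecordTable, Role

# Translation table for positions > 0.  Position 0 is exempt.
_MASK_TABLE = str.maketrans(
    "123456789" + "abcdefghijklmnopqrstuvwxyz" + "ABCDEFGHIJKLMNOPQRSTUVWXYZ",
    "9" * 9 + "z" * 26 + "Z" * 26,
)

# Characters that must not appear beyond position 0 of a masked cell.
_FORBIDDEN_MASKED = set("abcdefghijklmnopqrstuvwxy"
                        "ABCDEFGHIJKLMNOPQRSTUVWXY"
                        "12345678")


@dataclass(frozen=True)
class MaskConfig:
    shuffle: bool = False
    sample_size: int | None = None  # None means the entire population
    rng_seed: int = 0


def mask_value(text: str) -> str:
    """Mask one cell value; total, length-preserving and idempotent."""
    if len(text) <= 1:
        return text
    return text[0] + text[1:].translate(_MASK_TABLE)


def is_masked_value(text: str) -> bool:
    """True when no revealing character survives beyond position 0."""
    return not (_FORBIDDEN_MASKED & set(text[1:]))


def is_masked_table(t: RecordTable) -> bool:
    """True when every sensitive cell of ``t`` is in masked form."""
    for name in t.columns_with_role(Role.SENSITIVE_STRING,
                                    Role.SENSITIVE_DATE):
        if not all(is_masked_value(v) for v in t.df[name]):
            return False
    return True


def mask_table(t: RecordTable, cfg: MaskConfig | None = None) -> RecordTable:
    """Mask every sensitive cell; optionally sample rows first (seeded)."""
    cfg = cfg or MaskConfig()
    df = t.df
    if cfg.sample_size is not None:
        if cfg.sample_size > len(df):
            raise ValueError("sample_size exceeds table size")
        rng = np.random.default_rng(cfg.rng_seed)
        idx = rng.choice(len(df), size=cfg.sample_size, replace=False)
        df = df.iloc[np.sort(idx)].reset_index(drop=True)
    else:
        df = df.copy().reset_index(drop=True)
    for name in t.columns_with_role(Role.SENSITIVE_STRING,
                                    Role.SENSITIVE_DATE):
        df[name] = df[name].map(mask_value)
    out = RecordTable(list(t.columns), df, t.site_label, dict(t.meta))
    out.meta["masked"] = True
    if cfg.shuffle:
        out = shuffle_table(out, cfg.rng_seed)
    return out


def shuffle_table(t: RecordTable, rng_seed: int = 0) -> RecordTable:
    """Permute each column independently; drop original site identifiers.

    Refuses to run on a table whose sensitive columns are not masked — the
    protocol forbids shuffling (and hence exporting) plain content.
    """
    if not is_masked_table(t):
        raise ProtocolViolation(
            "refusing to shuffle a table with unmasked sensitive columns")
    df = t.df.copy().reset_index(drop=True)
    n = len(df)
    id_col = t.id_column
    for name in df.columns:
        if name == id_col:
            continue
        # one independent permutation per column, derived from (seed, name)
        col_seed = np.random.default_rng(
            [rng_seed, *name.encode()]).integers(2**31)
        perm = np.random.default_rng(col_seed).permutation(n)
        df[name] = df[name].to_numpy()[perm]
    df[id_col] = [str(i + 1) for i in range(n)]
    out = RecordTable(list(t.columns), df, t.site_label, dict(t.meta))
    out.meta["shuffled"] = True
    return out
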
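"""Structure inference from masked data, cleaning templates, harmonization.

The linkage centre never sees plain identifiers, yet the two sites' extracts
must be cleaned to the same quality and format before encryption or the Bloom
filters will not be comparable.  The bridge is the masked copy: from it this
module infers each column's structure (:func:`infer_structure`), compiles an
ordered, site-specific cleaning template (:func:`compile_template`), and the
sites then run the template locally (:func:`apply_template`) to produce
harmonized name slots and ISO dates ready for encryption.

Name standardization uppercases, transliterates language-specific characters
(ä→AE, é→E, ß→SS, ...), removes codes and digits, strips nobiliary affixes
(VON, DE, VAN DER, ...) into a separate slot, splits multiple names and
resolves nicknames against a sex-specific lookup table.  Dates are parsed
under the template's declared component order — the masked data decide
whether ``03.04.1950`` is March or April — and emitted as ``YYYY-MM-DD``.
"""

from __future__ import annotations

import datetime as _dt
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .datamodel import (MISSING, ColumnSpec, ProtocolViolation, RecordTable,
                        Role, SchemaError, config_fingerprint)
from .masking import is_masked_table

# ---------------------------------------------------------------------------
# Built-in rule library (defaults; every piece is template-overridable)
# ---------------------------------------------------------------------------

#: German/French transliteration map applied after upper-casing.
TRANSLITERATION: dict[str, str] = {
    "Ä": "AE", "Ö": "OE", "Ü": "UE", "ß": "SS", "ẞ": "SS",
    "É": "E", "È": "E", "Ê": "E", "Ë": "E",
    "À": "A", "Â": "A", "Á": "A", "Å": "A", "Æ": "AE",
    "Ç": "C", "Î": "I", "Ï": "I", "Í": "I", "Ì": "I",
    "Ô": "O", "Ò": "O", "Ó": "O", "Ø": "OE", "Õ": "O",
    "Ù": "U", "Û": "U", "Ú": "U", "Ñ": "N", "Ý": "Y",
}

#: Nobiliary/particle affixes stripped from the front of a name, longest first.
AFFIXES: tuple[str, ...] = (
    "VON DER", "VAN DER", "VAN DEN", "VON DEM", "DE LA", "DE LOS",
    "VON", "VAN", "DE", "DER", "DEN", "DI", "DA", "DU", "DOS",
    "LE", "LA", "TER", "TEN", "ZU", "AM", "IM",
)

#: Missing-value codes mapped to the uniform empty string during cleaning.
DEFAULT_MISSING_CODES: tuple[str, ...] = ("9", "99", "999", "9999",
                                          "-", ".", "?", "NA", "N/A", "NULL")

_MONTH_NAMES: dict[str, int] = {}
for _i, _names in enumerate([
    ("JANUARY", "JANUAR", "JANVIER", "JAN"),
    ("FEBRUARY", "FEBRUAR", "FEVRIER", "FEB"),
    ("MARCH", "MAERZ", "MARS", "MAR", "MRZ"),
    ("APRIL", "AVRIL", "APR"),
    ("MAY", "MAI"),
    ("JUNE", "JUNI", "JUIN", "JUN"),
    ("JULY", "JULI", "JUILLET", "JUL"),
    ("AUGUST", "AOUT", "AUG"),
    ("SEPTEMBER", "SEPTEMBRE", "SEP", "SEPT"),
    ("OCTOBER", "OKTOBER", "OCTOBRE", "OCT", "OKT"),
    ("NOVEMBER", "NOVEMBRE", "NOV"),
    ("DECEMBER", "DEZEMBER", "DECEMBRE", "DEC", "DEZ"),
], start=1):
    for _n in _names:
        _MONTH_NAMES[_n] = _i


def _transliterate(text: str) -> str:
    up = text.upper()
    return "".join(TRANSLITERATION.get(ch, ch) for ch in up)


@dataclass
class NameResult:
    tokens: list[str]
    affix: str = ""
    notes: list[str] = field(default_factory=list)


def normalize_name(text: str,
                   affixes: tuple[str, ...] = AFFIXES) -> NameResult:
    """Standardize one raw name cell into ordered clean tokens.

    Output alphabet is A-Z plus the space/hyphen token separators (the
    separators themselves are consumed by tokenization).  All-digit tokens
    and short code tokens co-occurring with digits (``DCO 1998``) are dropped
    with an audit note rather than half-cleaned.
    """
    notes: list[str] = []
    has_digit = any(ch.isdigit() for ch in text)
    up = _transliterate(text)
    raw_tokens = [tok for tok in re.split(r"[\s\-]+", up) if tok]
    tokens: list[str] = []
    for tok in raw_tokens:
        if tok.isdigit():
            notes.append("all-digit token removed")
            continue
        stripped = re.sub(r"[^A-Z]", "", tok)
        if not stripped:
            continue
        if has_digit and len(stripped) <= 4 and any(c.isdigit() for c in tok) is False:
            # a short letter code next to digits, e.g. "DCO 1998"
            notes.append("code token removed")
            continue
        tokens.append(stripped)
    # strip leading affixes, longest first, possibly several words
    affix_words: list[str] = []
    changed = True
    while changed and tokens:
        changed = False
        for aff in sorted(affixes, key=len, reverse=True):
            parts = aff.split()
            if len(tokens) > len(parts) and tokens[:len(parts)] == parts:
                affix_words.extend(parts)
                tokens = tokens[len(parts):]
                changed = True
                break
    return NameResult(tokens=tokens, affix=" ".join(affix_words), notes=notes)


# ---------------------------------------------------------------------------
# Dates
# ---------------------------------------------------------------------------

#: Supported component orders keyed by pattern mnemonic.
_ORDERS = {"DMY": ("D", "M", "Y"), "MDY": ("M", "D", "Y"),
           "YMD": ("Y", "M", "D"), "YDM": ("Y", "D", "M")}


def pattern_order(pattern: str) -> tuple[str, ...]:
    """Component order of a pattern like ``DD.MM.YYYY`` or ``MON DD YYYY``."""
    comps = re.findall(r"YYYY|MON|DD|MM|D|M|Y", pattern)
    out = []
    for c in comps:
        if c in ("YYYY", "Y"):
            out.append("Y")
        elif c in ("MM", "M", "MON"):
            out.append("M")
        else:
            out.append("D")
    if sorted(out) != ["D", "M", "Y"]:
        raise ValueError(f"unsupported date pattern: {pattern!r}")
    return tuple(out)


def normalize_date(text: str, pattern: str) -> tuple[str, str]:
    """Parse one raw date under a declared pattern; return (ISO, note).

    Month names are resolved against a German/French/English table; invalid
    calendar dates (``31.02.1980``) yield the empty string with a note.
    """
    raw = text.strip()
    if raw == MISSING:
        return MISSING, ""
    try:
        order = pattern_order(pattern)
    except ValueError:
        return MISSING, "unparseable pattern"
    pieces = [p for p in re.split(r"[^0-9A-Za-zÄÖÜäöü]+", raw) if p]
    if len(pieces) != 3:
        return MISSING, "unparseable value"
    comp: dict[str, str] = dict(zip(order, pieces))
    mon = comp["M"]
    if not mon.isdigit():
        month = _MONTH_NAMES.get(_transliterate(mon))
        if month is None:
            return MISSING, "unknown month name"
    else:
        month = int(mon)
    if not (comp["D"].isdigit() and comp["Y"].isdigit()):
        return MISSING, "unparseable value"
    day, year = int(comp["D"]), int(comp["Y"])
    if year < 100:
        return MISSING, "two-digit year"
    try:
        d = _dt.date(year, month, day)
    except ValueError:
        return MISSING, "invalid calendar date"
    return d.isoformat(), ""


_MON_ABBREV = ["JAN", "FEB", "MAR", "APR", "MAY", "JUN", "JUL",
               "AUG", "SEP", "OCT", "NOV", "DEC"]


def render_date(iso: str, pattern: str) -> str:
    """Render an ISO date under a display pattern (inverse of normalize)."""
    if iso == MISSING:
        return MISSING
    d = _dt.date.fromisoformat(iso)
    sub = {"YYYY": f"{d.year:04d}", "MON": _MON_ABBREV[d.month - 1],
           "DD": f"{d.day:02d}", "MM": f"{d.month:02d}",
           "D": str(d.day), "M": str(d.month), "Y": f"{d.year:04d}"}
    return re.sub(r"YYYY|MON|DD|MM|D|M|Y", lambda m: sub[m.group()], pattern)


# ---------------------------------------------------------------------------
# Structure inference from masked data
# ---------------------------------------------------------------------------

@dataclass
class ColumnStructure:
    """What the masked copy of one column reveals."""
    name: str
    role: str
    n_values: int = 0
    n_missing: int = 0
    embedded_digits: int = 0
    multi_name: int = 0
    separators: dict = field(default_factory=dict)
    special_chars: dict = field(default_factory=dict)
    missing_codes: list = field(default_factory=list)
    date_delimiter: str = ""
    date_order: str = ""          # "DMY" | "MDY" | "YMD" | "ambiguous"
    date_candidates: list = field(default_factory=list)
    leading_zero: bool = False
    warnings: list = field(default_factory=list)


@dataclass
class StructureReport:
    columns: dict[str, ColumnStructure]
    n_rows: int

    def to_dict(self) -> dict:
        return {"n_rows": self.n_rows,
                "columns": {k: vars(v) for k, v in self.columns.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "StructureReport":
        cols = {k: ColumnStructure(**v) for k, v in d["columns"].items()}
        return cls(columns=cols, n_rows=d["n_rows"])


def _detect_missing_codes(values: pd.Series) -> list[str]:
    n = max(len(values), 1)
    counts = Counter(v for v in values if re.fullmatch(r"[9.\-?]{1,4}", v))
    return sorted(v for v, c in counts.items() if c / n >= 0.01)


def _infer_date_column(values: list[str], cs: ColumnStructure) -> None:
    sigs = Counter()
    delims = Counter()
    first_chars = Counter()
    for v in values:
        groups = re.findall(r"[0-9]+", v)
        if len(groups) != 3:
            continue
        sigs[tuple(len(g) for g in groups)] += 1
        for ch in re.findall(r"[^0-9A-Za-z]", v):
            delims[ch] += 1
        first_chars[v[0]] += 1
        if any(len(g) == 2 and g[0] == "0" for g in groups):
            cs.leading_zero = True
    if not sigs:
        cs.warnings.append("no recognizable date structure")
        return
    sig = sigs.most_common(1)[0][0]
    cs.date_delimiter = delims.most_common(1)[0][0] if delims else ""
    year_pos = sig.index(4) if 4 in sig else None
    if year_pos is None:
        cs.warnings.append("no 4-digit year component")
        cs.date_order = "ambiguous"
        cs.date_candidates = ["DMY", "MDY"]
        return
    if year_pos == 0:
        cs.date_order = "YMD"        # ISO convention: month before day
        cs.date_candidates = ["YMD"]
    else:
        # year last: day-first vs month-first decided by cell-initial digits
        # (days 20-31 leave a visible 2/3 only in the cell's first position)
        if any(c in "23" for c in first_chars):
            cs.date_order = "DMY"
            cs.date_candidates = ["DMY"]
        else:
            cs.date_order = "ambiguous"
            cs.date_candidates = ["DMY", "MDY"]
            cs.warnings.append(
                "day/month order not distinguishable from masked sample")


def infer_structure(masked: RecordTable) -> StructureReport:
    """Census the masked extract; never stores a cell value verbatim
    (only short candidate missing codes, which are structural by design)."""
    if not is_masked_table(masked):
        raise ProtocolViolation("structure inference requires masked input")
    out: dict[str, ColumnStructure] = {}
    for spec in masked.columns:
        vals = masked.df[spec.name]
        cs = ColumnStructure(name=spec.name, role=spec.role.value,
                             n_values=len(vals),
                             n_missing=int((vals == MISSING).sum()))
        nonblank = [v for v in vals if v != MISSING]
        cs.missing_codes = _detect_missing_codes(vals)
        if spec.role is Role.SENSITIVE_DATE:
            _infer_date_column(nonblank, cs)
        elif spec.role is Role.SENSITIVE_STRING:
            seps = Counter()
            specials = Counter()
            for v in nonblank:
                if any(ch.isdigit() for ch in v):
                    cs.embedded_digits += 1
                if re.search(r"\S\s+\S", v):
                    cs.multi_name += 1
                    seps[" "] += 1
                if "-" in v:
                    seps["-"] += 1
                for ch in v:
                    if not (ch.isascii() and (ch.isalnum() or ch in " -")):
                        specials[ch] += 1
            cs.separators = dict(seps)
            cs.special_chars = dict(specials)
        out[spec.name] = cs
    return StructureReport(columns=out, n_rows=len(masked))


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CleaningRule:
    kind: str       # substitute_pattern | transliterate | strip_affix |
                    # split_multi | nickname_lookup | missing_code |
                    # date_normalize | case_fold
    params: tuple = ()


@dataclass
class TemplateColumn:
    source: str
    kind: str                      # "name" | "date" | "plain" | "id"
    outputs: list[str]
    rules: list[CleaningRule] = field(default_factory=list)
    missing_codes: list[str] = field(default_factory=list)
    date_patterns: list[str] = field(default_factory=list)
    nickname_lookup: bool = False
    warnings: list[str] = field(default_factory=list)


@dataclass
class PreprocessTemplate:
    """Ordered cleaning rules per column plus the cleaned output schema."""
    columns: list[TemplateColumn]
    sex_column: str = ""
    nickname_table: str = ""

    @property
    def output_names(self) -> list[str]:
        return [o for c in self.columns for o in c.outputs]

    def fingerprint(self) -> str:
        doc = [{"source": c.source, "kind": c.kind, "outputs": c.outputs,
                "missing_codes": c.missing_codes,
                "date_patterns": c.date_patterns,
                "nickname_lookup": c.nickname_lookup}
               for c in self.columns]
        return config_fingerprint({"columns": doc, "sex": self.sex_column})

    def to_yaml(self, path: str | Path) -> None:
        doc = {"sex_column": self.sex_column,
               "nickname_table": self.nickname_table,
               "columns": [{
                   "source": c.source, "kind": c.kind, "outputs": c.outputs,
                   "rules": [{"kind": r.kind, "params": list(r.params)}
                             for r in c.rules],
                   "missing_codes": c.missing_codes,
                   "date_patterns": c.date_patterns,
                   "nickname_lookup": c.nickname_lookup,
                   "warnings": c.warnings} for c in self.columns]}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PreprocessTemplate":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        cols = [TemplateColumn(
            source=c["source"], kind=c["kind"], outputs=c["outputs"],
            rules=[CleaningRule(r["kind"], tuple(r["params"]))
                   for r in c.get("rules", [])],
            missing_codes=c.get("missing_codes", []),
            date_patterns=c.get("date_patterns", []),
            nickname_lookup=c.get("nickname_lookup", False),
            warnings=c.get("warnings", [])) for c in doc["columns"]]
        return cls(columns=cols, sex_column=doc.get("sex_column", ""),
                   nickname_table=doc.get("nickname_table", ""))


def _date_pattern_from_structure(cs: ColumnStructure, order: str) -> str:
    delim = cs.date_delimiter or "."
    parts = {"D": "DD" if cs.leading_zero else "D",
             "M": "MM" if cs.leading_zero else "M", "Y": "YYYY"}
    if order == "YMD":
        parts = {"D": "DD", "M": "MM", "Y": "YYYY"}
    return delim.join(parts[c] for c in _ORDERS[order])


def compile_template(report: StructureReport,
                     schema: list[ColumnSpec] | None = None,
                     name_slots: int = 2) -> PreprocessTemplate:
    """Compile an ordered cleaning template from a structure report.

    Rule order per column: missing-code mapping first, then transliteration,
    affix handling, multi-name split, nickname lookup, case folding and —
    for date columns — normalization under the inferred pattern.  When the
    masked sample cannot separate day from month the template carries both
    candidate patterns and a warning.
    """
    cols: list[TemplateColumn] = []
    sex_col = ""
    for name, cs in report.columns.items():
        role = Role(cs.role)
        missing = sorted(set(cs.missing_codes) | set(DEFAULT_MISSING_CODES))
        if role is Role.SITE_ID:
            cols.append(TemplateColumn(name, "id", [name]))
        elif role is Role.SENSITIVE_DATE:
            if cs.date_order == "ambiguous":
                pats = [_date_pattern_from_structure(cs, o)
                        for o in cs.date_candidates]
                warn = list(cs.warnings)
            else:
                pats = [_date_pattern_from_structure(cs, cs.date_order)]
                warn = []
            rules = [CleaningRule("missing_code", tuple(missing)),
                     CleaningRule("date_normalize", tuple(pats))]
            cols.append(TemplateColumn(name, "date", [name], rules=rules,
                                       missing_codes=missing,
                                       date_patterns=pats, warnings=warn))
        elif role is Role.SENSITIVE_STRING:
            is_first = "FIRST" in name.upper() or "GIVEN" in name.upper()
            outputs = [f"{name}{i + 1}" for i in range(name_slots)]
            rules = [CleaningRule("missing_code", tuple(missing)),
                     CleaningRule("transliterate"),
                     CleaningRule("strip_affix", AFFIXES),
                     CleaningRule("split_multi", (" ", "-")),
                     CleaningRule("case_fold")]
            if is_first:
                rules.append(CleaningRule("nickname_lookup"))
            cols.append(TemplateColumn(name, "name", outputs, rules=rules,
                                       missing_codes=missing,
                                       nickname_lookup=is_first))
        else:
            if "SEX" in name.upper() or "GENDER" in name.upper():
                sex_col = name
            rules = [CleaningRule("missing_code", tuple(missing))]
            cols.append(TemplateColumn(name, "plain", [name], rules=rules,
                                       missing_codes=missing))
    return PreprocessTemplate(columns=cols, sex_column=sex_col)


# ---------------------------------------------------------------------------
# Nickname lookup
# ---------------------------------------------------------------------------

class NicknameTable:
    """Sex-specific nickname → canonical-name lookup; misses pass through."""

    def __init__(self, entries: list[tuple[str, str, str]]):
        self._map: dict[tuple[str, str], str] = {}
        for nick, sex, canon in entries:
            key = (nick.strip().upper(), sex.strip().lower())
            self._map[key] = canon.strip().upper()

    @classmethod
    def from_csv(cls, path: str | Path) -> "NicknameTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls(list(df[["nickname", "sex", "canonical"]]
                        .itertuples(index=False, name=None)))

    @classmethod
    def default(cls) -> "NicknameTable":
        from importlib.resources import files
        return cls.from_csv(files("p3rl.data") / "nicknames_de.csv")

    def lookup(self, token: str, sex: str = "") -> str:
        key = token.strip().upper()
        s = sex.strip().lower()
        return self._map.get((key, s)) or self._map.get((key, "")) or token

    def __len__(self) -> int:
        return len(self._map)


# ---------------------------------------------------------------------------
# Template application
# ---------------------------------------------------------------------------

def _clean_name_cell(value: str, col: TemplateColumn, sex: str,
                     nick: NicknameTable | None,
                     audit: Counter) -> list[str]:
    v = value.strip()
    if v in col.missing_codes or v == MISSING:
        if v != MISSING:
            audit[(col.source, "missing_code")] += 1
        return [MISSING] * len(col.outputs)
    res = normalize_name(v)
    for note in res.notes:
        audit[(col.source, note)] += 1
    if res.affix:
        audit[(col.source, "affix_stripped")] += 1
    tokens = res.tokens
    if col.nickname_lookup and nick is not None:
        looked = [nick.lookup(t, sex) for t in tokens]
        if looked != tokens:
            audit[(col.source, "nickname_resolved")] += 1
        tokens = looked
    n = len(col.outputs)
    slots = tokens[:n - 1] + ([" ".join(tokens[n - 1:])] if len(tokens) >= n
                              else tokens[n - 1:])
    slots += [MISSING] * (n - len(slots))
    if len(tokens) > 1:
        audit[(col.source, "multi_name_split")] += 1
    return slots


def _clean_date_cell(value: str, col: TemplateColumn,
                     audit: Counter) -> str:
    v = value.strip()
    if v in col.missing_codes or v == MISSING:
        if v != MISSING:
            audit[(col.source, "missing_code")] += 1
        return MISSING
    for pat in col.date_patterns or ["YYYY-MM-DD"]:
        iso, note = normalize_date(v, pat)
        if iso != MISSING:
            return iso
    audit[(col.source, note or "unparseable date")] += 1
    return MISSING


def apply_template(t: RecordTable, tpl: PreprocessTemplate,
                   nick: NicknameTable | None = None) -> RecordTable:
    """Run the template over a site extract; deterministic, audited.

    The audit log in ``result.meta['audit']`` counts rule firings per column
    and never contains a cell value, so it can be shared with the linkage
    centre.  Applying a template to its own output is the identity.
    """
    cleaned_already = set(t.df.columns) >= set(tpl.output_names)
    audit: Counter = Counter()
    out_cols: list[ColumnSpec] = []
    data: dict[str, list[str]] = {}
    sex_series = (t.df[tpl.sex_column] if tpl.sex_column in t.df.columns
                  else pd.Series([""] * len(t.df), dtype=str))

    for col in tpl.columns:
        if not cleaned_already and col.source not in t.df.columns:
            raise SchemaError(f"template source column {col.source!r} "
                              "absent from table")
        if col.kind == "id":
            src = col.source if col.source in t.df.columns else col.outputs[0]
            data[col.outputs[0]] = list(t.df[src])
            out_cols.append(ColumnSpec(col.outputs[0], Role.SITE_ID))
        elif col.kind == "name":
            if cleaned_already and col.source not in t.df.columns:
                # idempotent path: each output slot re-cleaned in place
                for o in col.outputs:
                    data[o] = [" ".join(_clean_name_cell(v, _slot_col(col, o),
                                                         s, nick, audit))
                               .strip()
                               for v, s in zip(t.df[o], sex_series)]
                    out_cols.append(ColumnSpec(o, Role.SENSITIVE_STRING))
                continue
            slots = [_clean_name_cell(v, col, s, nick, audit)
                     for v, s in zip(t.df[col.source], sex_series)]
            for i, o in enumerate(col.outputs):
                data[o] = [s[i] for s in slots]
                out_cols.append(ColumnSpec(o, Role.SENSITIVE_STRING))
        elif col.kind == "date":
            src = (col.source if col.source in t.df.columns
                   else col.outputs[0])
            # already-normalized ISO values re-parse under the fallback,
            # which keeps template application idempotent on its own output
            pats = list(col.date_patterns)
            if "YYYY-MM-DD" not in pats:
                pats.append("YYYY-MM-DD")
            eff = TemplateColumn(col.source, "date", col.outputs,
                                 missing_codes=col.missing_codes,
                                 date_patterns=pats)
            data[col.outputs[0]] = [_clean_date_cell(v, eff, audit)
                                    for v in t.df[src]]
            out_cols.append(ColumnSpec(col.outputs[0], Role.SENSITIVE_DATE,
                                       declared_format="YYYY-MM-DD"))
        else:  # plain
            src = col.source if col.source in t.df.columns else col.outputs[0]
            vals = []
            for v in t.df[src]:
                v = v.strip()
                if v in col.missing_codes:
                    audit[(col.source, "missing_code")] += 1
                    v = MISSING
                vals.append(v)
            data[col.outputs[0]] = vals
            out_cols.append(ColumnSpec(col.outputs[0], Role.PLAIN))

    df = pd.DataFrame(data, dtype=str)
    out = RecordTable(out_cols, df, t.site_label, dict(t.meta))
    out.meta["cleaned"] = tpl.fingerprint()
    out.meta["audit"] = {f"{c}:{r}": n for (c, r), n in sorted(audit.items())}
    return out


def _slot_col(col: TemplateColumn, output: str) -> TemplateColumn:
    """A single-slot view of a name column, used on already-split input."""
    return TemplateColumn(col.source, "name", [output],
                          missing_codes=col.missing_codes,
                          nickname_lookup=col.nickname_lookup)
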
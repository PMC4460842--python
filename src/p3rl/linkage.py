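"""Candidate generation, Fellegi-Sunter scoring, classification, link table.

Candidate pairs are produced under a multi-pass blocking scheme (union of
pairs agreeing on each pass key, e.g. birth year + sex, or the encrypted
day/month sections), scored by summing per-variable agreement and
disagreement weights ``w+ = log2(m/u)`` and ``w- = log2((1-m)/(1-u))``
over the comparison vector, and classified against an upper and lower
threshold into link / possible / nonlink.  Partial name agreements
contribute a weight interpolated linearly between ``w-`` and ``w+`` over the
similarity band above the cut-off; the recognized date-error categories
(swapped day/month, ±1 day, year digit errors) default to the midpoint.

A greedy one-to-one resolution then keeps, per identifier, the
highest-weight link (ties broken lexicographically) and demotes displaced
links to possible, which makes the output deterministic and auditable — the
clerical review a plain-text linkage would fall back on is impossible on
encrypted values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import log2
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison as cmp
from .comparison import (AgreementLevel, ComparisonVector, DateOutcome,
                         VariableSpec)
from .datamodel import (MISSING, LinkTable, ProtocolViolation, RecordTable,
                        config_fingerprint)
from .encryption import (EncryptedDate, ValidationToken, hex_to_bloom,
                         verify_validation)

PAIR_BUDGET_DEFAULT = 10**8


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MUWeights:
    """Conditional agreement probabilities for one variable."""
    m_prob: float
    u_prob: float

    def __post_init__(self) -> None:
        if not (0 < self.m_prob < 1 and 0 < self.u_prob < 1):
            raise ValueError("m and u must lie in (0, 1)")
        if self.u_prob > self.m_prob:
            raise ValueError("u must not exceed m for a linkage variable")

    @property
    def w_plus(self) -> float:
        return 0.0 if self.m_prob == self.u_prob else log2(self.m_prob
                                                           / self.u_prob)

    @property
    def w_minus(self) -> float:
        return 0.0 if self.m_prob == self.u_prob else log2(
            (1 - self.m_prob) / (1 - self.u_prob))

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.w_plus + self.w_minus)


@dataclass(frozen=True)
class Thresholds:
    upper: float
    lower: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower threshold exceeds upper")


@dataclass
class LinkageVariable:
    name: str
    kind: str                       # "name" | "date" | "plain"
    m_prob: float
    u_prob: float
    cutoff: float = 0.80
    column: str = ""                # source column; defaults to name

    def __post_init__(self) -> None:
        self.column = self.column or self.name
        self.weights = MUWeights(self.m_prob, self.u_prob)

    def spec(self) -> VariableSpec:
        return VariableSpec(self.name, self.kind, self.cutoff)


@dataclass
class BlockingScheme:
    """Union-of-passes blocking; each pass is a tuple of key expressions.

    A key expression is a column name, optionally with a derivation suffix:
    ``DOB:year`` / ``DOB:daymonth`` slice an ISO date or the encrypted date
    sections.  Records with an empty key component sit out that pass.
    An empty scheme means the full cross product.
    """
    passes: list[tuple[str, ...]] = field(default_factory=list)


@dataclass
class LinkageConfig:
    variables: list[LinkageVariable]
    thresholds: Thresholds
    blocking: BlockingScheme = field(default_factory=BlockingScheme)
    transposition_pairs: list[tuple[str, str]] = field(default_factory=list)
    date_category_weights: dict[str, float] = field(default_factory=dict)
    transposition_weight: float | None = None   # None -> per-slot midpoint
    pair_budget: int = PAIR_BUDGET_DEFAULT

    def fingerprint(self) -> str:
        return config_fingerprint({
            "variables": [(v.name, v.kind, v.m_prob, v.u_prob, v.cutoff,
                           v.column) for v in self.variables],
            "thresholds": (self.thresholds.upper, self.thresholds.lower),
            "blocking": [list(p) for p in self.blocking.passes],
            "transposition": [list(p) for p in self.transposition_pairs],
            "date_category_weights": self.date_category_weights,
        })

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LinkageConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        variables = [LinkageVariable(
            name=v["name"], kind=v["kind"], m_prob=v["m"], u_prob=v["u"],
            cutoff=v.get("cutoff", 0.80), column=v.get("column", ""))
            for v in doc["variables"]]
        th = Thresholds(upper=doc["thresholds"]["upper"],
                        lower=doc["thresholds"]["lower"])
        blocking = BlockingScheme(
            [tuple(p) for p in doc.get("blocking", [])])
        return cls(variables=variables, thresholds=th, blocking=blocking,
                   transposition_pairs=[tuple(p) for p in
                                        doc.get("transposition_pairs", [])],
                   date_category_weights=doc.get("date_category_weights", {}),
                   transposition_weight=doc.get("transposition_weight"),
                   pair_budget=doc.get("pair_budget", PAIR_BUDGET_DEFAULT))


# ---------------------------------------------------------------------------
# Blocking
# ---------------------------------------------------------------------------

def _key_series(t: RecordTable, expr: str) -> pd.Series:
    """Evaluate one blocking key expression against a table."""
    if ":" not in expr:
        if expr not in t.df.columns:
            raise KeyError(f"blocking key column {expr!r} not in table")
        return t.df[expr]
    col, part = expr.split(":", 1)
    vals = t.df[col]
    if part == "year":
        return vals.str.slice(0, 4)
    if part == "daymonth":
        def dm(v: str) -> str:
            if v == MISSING:
                return MISSING
            if "|" in v:                      # encrypted date sections
                p = v.split("|")
                return p[5] + p[6]
            return v[5:]                      # ISO date -> MM-DD
        return vals.map(dm)
    raise KeyError(f"unknown blocking derivation {part!r}")


def generate_pairs(t_a: RecordTable, t_b: RecordTable,
                   scheme: BlockingScheme,
                   pair_budget: int = PAIR_BUDGET_DEFAULT,
                   ) -> tuple[list[tuple[str, str]], dict]:
    """Candidate (id_a, id_b) pairs under the blocking scheme, deduplicated.

    Returns the sorted pair list plus per-pass counts; warns (in the stats,
    and via a RuntimeWarning) when the pair count exceeds the budget.
    """
    stats: dict = {"passes": {}, "budget": pair_budget}
    ids_a = t_a.df[t_a.id_column]
    ids_b = t_b.df[t_b.id_column]
    if not scheme.passes:
        pairs = set(itertools.product(ids_a, ids_b))
        stats["passes"]["cross_product"] = len(pairs)
    else:
        pairs: set[tuple[str, str]] = set()
        for p in scheme.passes:
            ka = pd.DataFrame({"id_a": ids_a})
            kb = pd.DataFrame({"id_b": ids_b})
            keep_a = pd.Series(True, index=ka.index)
            keep_b = pd.Series(True, index=kb.index)
            for i, expr in enumerate(p):
                sa = _key_series(t_a, expr).reset_index(drop=True)
                sb = _key_series(t_b, expr).reset_index(drop=True)
                ka[f"k{i}"] = sa
                kb[f"k{i}"] = sb
                keep_a &= sa != MISSING
                keep_b &= sb != MISSING
            keys = [f"k{i}" for i in range(len(p))]
            merged = ka[keep_a.to_numpy()].merge(kb[keep_b.to_numpy()],
                                                 on=keys)
            new = set(zip(merged["id_a"], merged["id_b"]))
            stats["passes"]["+".join(p)] = len(new)
            pairs |= new
    stats["n_pairs"] = len(pairs)
    if len(pairs) > pair_budget:
        import warnings
        warnings.warn(f"candidate pair count {len(pairs)} exceeds budget "
                      f"{pair_budget}", RuntimeWarning, stacklevel=2)
        stats["over_budget"] = True
    return sorted(pairs), stats


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def pair_weight(cv: ComparisonVector, weights: dict[str, MUWeights],
                cfg: LinkageConfig) -> float:
    """Total Fellegi-Sunter weight of one comparison vector."""
    if set(cv.outcomes) != set(weights):
        raise ValueError("comparison vector and weights cover "
                         "different variables")
    cutoffs = {v.name: v.cutoff for v in cfg.variables}
    contrib: dict[str, float] = {}
    for name, outcome in cv.outcomes.items():
        w = weights[name]
        if outcome in (AgreementLevel.FULL, DateOutcome.EXACT):
            contrib[name] = w.w_plus
        elif outcome in (AgreementLevel.MISSING, DateOutcome.MISSING):
            contrib[name] = 0.0
        elif outcome is AgreementLevel.PARTIAL:
            d = cv.dices[name]
            cut = cutoffs[name]
            contrib[name] = (w.w_minus
                             + (w.w_plus - w.w_minus) * (d - cut) / (1 - cut))
        elif isinstance(outcome, DateOutcome) and outcome in (
                DateOutcome.DAY_MONTH_SWAPPED, DateOutcome.PLUS_MINUS_ONE_DAY,
                DateOutcome.YEAR_ONE_DIGIT, DateOutcome.YEAR_TRANSPOSED):
            contrib[name] = cfg.date_category_weights.get(
                outcome.value, w.midpoint)
        else:
            contrib[name] = w.w_minus
    if cv.transposed:
        for fn, sn in cfg.transposition_pairs:
            if fn in contrib and sn in contrib:
                for slot in (fn, sn):
                    contrib[slot] = (cfg.transposition_weight
                                     if cfg.transposition_weight is not None
                                     else weights[slot].midpoint)
    return sum(contrib.values())


def classify(weight: float, th: Thresholds) -> str:
    if weight >= th.upper:
        return "link"
    if weight < th.lower:
        return "nonlink"
    return "possible"


def resolve_one_to_one(classified: pd.DataFrame) -> LinkTable:
    """Greedy one-to-one assignment among links, by descending weight.

    Each id_a and id_b backs at most one link; displaced links are demoted
    to possible.  Ties break on (id_a, id_b) lexicographic order, so the
    result is stable across runs.
    """
    df = classified.sort_values(["total_weight", "id_a", "id_b"],
                                ascending=[False, True, True],
                                kind="mergesort").reset_index(drop=True)
    used_a: set[str] = set()
    used_b: set[str] = set()
    decisions = []
    for row in df.itertuples(index=False):
        dec = row.decision
        if dec == "link":
            if row.id_a in used_a or row.id_b in used_b:
                dec = "possible"
            else:
                used_a.add(row.id_a)
                used_b.add(row.id_b)
        decisions.append(dec)
    df = df.assign(decision=decisions)
    df = df.sort_values(["id_a", "id_b"], kind="mergesort").reset_index(
        drop=True)
    return LinkTable(pairs=df)


# ---------------------------------------------------------------------------
# Record decoding
# ---------------------------------------------------------------------------

def _decode_encrypted(t: RecordTable, cfg: LinkageConfig) -> dict[str, dict]:
    """Per-record decoded values (Bloom arrays, date sections) keyed by id.

    Bloom hex strings are decoded once per distinct value — the name pools of
    realistic extracts repeat heavily, and two identical hex strings decode
    to the same immutable filter anyway.
    """
    bloom_cache: dict[str, object] = {}
    date_cache: dict[tuple[str, str], EncryptedDate] = {}
    out: dict[str, dict] = {}
    ids = list(t.df[t.id_column])
    cols: dict[str, list] = {}
    for var in cfg.variables:
        if var.kind == "name":
            vals = []
            for v in t.df[var.column]:
                if v == MISSING:
                    vals.append(None)
                else:
                    if v not in bloom_cache:
                        bloom_cache[v] = hex_to_bloom(v, len(v) * 4)
                    vals.append(bloom_cache[v])
            cols[var.name] = vals
        elif var.kind == "date":
            years = t.df[var.column + "_year"]
            secs = t.df[var.column + "_enc"]
            vals = []
            for y, s in zip(years, secs):
                key = (y, s)
                if key not in date_cache:
                    date_cache[key] = EncryptedDate.from_columns(y, s)
                vals.append(date_cache[key])
            cols[var.name] = vals
        else:
            cols[var.name] = list(t.df[var.column])
    for i, rid in enumerate(ids):
        out[rid] = {name: vals[i] for name, vals in cols.items()}
    return out


def _decode_plain(t: RecordTable, cfg: LinkageConfig) -> dict[str, dict]:
    out: dict[str, dict] = {}
    ids = list(t.df[t.id_column])
    cols = {var.name: list(t.df[var.column]) for var in cfg.variables}
    for i, rid in enumerate(ids):
        out[rid] = {name: vals[i] for name, vals in cols.items()}
    return out


# ---------------------------------------------------------------------------
# End-to-end linkage
# ---------------------------------------------------------------------------

def _score(pairs: list[tuple[str, str]], recs_a: dict, recs_b: dict,
           cfg: LinkageConfig, plain: bool) -> pd.DataFrame:
    specs = [v.spec() for v in cfg.variables]
    weights = {v.name: v.weights for v in cfg.variables}
    tp = cfg.transposition_pairs[0] if cfg.transposition_pairs else None
    build = (cmp.build_comparison_vector_plain if plain
             else cmp.build_comparison_vector)
    rows = []
    agree_freq: dict[str, dict] = {v.name: {} for v in cfg.variables}
    for id_a, id_b in pairs:
        cv = build(recs_a[id_a], recs_b[id_b], specs, tp)
        w = pair_weight(cv, weights, cfg)
        dec = classify(w, cfg.thresholds)
        rows.append((id_a, id_b, w, dec))
        for name, outcome in cv.outcomes.items():
            f = agree_freq[name]
            f[outcome.value] = f.get(outcome.value, 0) + 1
    df = pd.DataFrame(rows, columns=["id_a", "id_b", "total_weight",
                                     "decision"])
    df.attrs["agreement_frequencies"] = agree_freq
    return df


def run_linkage(enc_a: RecordTable, enc_b: RecordTable,
                val_a: ValidationToken, val_b: ValidationToken,
                cfg: LinkageConfig, plain: bool = False,
                ) -> tuple[LinkTable, dict]:
    """The linkage centre's pipeline over two encrypted site extracts.

    Aborts before any pair is formed unless the two validation tokens match
    — non-matching tokens mean the sites encrypted with different keys or
    parameters and the encryption must be redone.  Intermediate pair data
    are dropped before returning; only the link table and the aggregate
    report leave this function.
    """
    ok, reason = verify_validation(val_a, val_b)
    if not ok:
        raise ProtocolViolation(
            f"encryption must be redone before linkage can begin: {reason}")
    pairs, block_stats = generate_pairs(enc_a, enc_b, cfg.blocking,
                                        cfg.pair_budget)
    if plain:
        recs_a, recs_b = _decode_plain(enc_a, cfg), _decode_plain(enc_b, cfg)
    else:
        recs_a = _decode_encrypted(enc_a, cfg)
        recs_b = _decode_encrypted(enc_b, cfg)
    scored = _score(pairs, recs_a, recs_b, cfg, plain)
    lt = resolve_one_to_one(scored)
    counts = lt.pairs["decision"].value_counts().to_dict()
    hist_edges = np.arange(-40.0, 41.0, 2.0)
    hist, _ = np.histogram(lt.pairs["total_weight"], bins=hist_edges)
    report = {
        "config_fingerprint": cfg.fingerprint(),
        "encryption_fingerprint": enc_a.meta.get("encrypted", ""),
        "n_records_a": len(enc_a),
        "n_records_b": len(enc_b),
        "blocking": block_stats,
        "decision_counts": {d: int(counts.get(d, 0))
                            for d in ("link", "possible", "nonlink")},
        "weight_histogram": {"edges": hist_edges.tolist(),
                             "counts": hist.tolist()},
        "agreement_frequencies": scored.attrs["agreement_frequencies"],
    }
    lt.metadata.update(config_fingerprint=cfg.fingerprint(),
                       n_pairs=len(pairs))
    # teardown: drop per-pair intermediates before returning
    del scored, recs_a, recs_b, pairs
    return lt, report


def evaluate(lt: LinkTable, truth: set[tuple[str, str]]) -> dict:
    """Precision/recall/F1 of decision=link pairs against known truth."""
    links = set(zip(lt.links()["id_a"], lt.links()["id_b"]))
    tp = len(links & truth)
    precision = tp / len(links) if links else 0.0
    recall = tp / len(truth) if truth else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_links": len(links), "n_truth": len(truth),
            "true_positives": tp}
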
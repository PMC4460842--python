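import itertools
from math import log2

import numpy as np
import pandas as pd
import pytest

from p3rl.comparison import (AgreementLevel, ComparisonVector, DateOutcome)
from p3rl.datamodel import (ColumnSpec, LinkTable, ProtocolViolation,
                            RecordTable, Role, write_link_table)
from p3rl.encryption import EncryptionConfig, make_validation
from p3rl.linkage import (BlockingScheme, LinkageConfig, LinkageVariable,
                          MUWeights, Thresholds, classify, evaluate,
                          generate_pairs, pair_weight, resolve_one_to_one,
                          run_linkage)
from p3rl.pipeline import default_linkage_config, prepare_site
from p3rl.synthgen import ErrorModel, derive_sites, generate_population


def _table(rows, site="A", extra_cols=()):
    cols = [ColumnSpec("ID", Role.SITE_ID)] + [
        ColumnSpec(c, Role.PLAIN) for c in
        (list(rows[0].keys())[1:] if rows else extra_cols)]
    df = pd.DataFrame(rows, columns=[c.name for c in cols], dtype=str)
    return RecordTable(cols, df, site_label=site)


# ---------------------------------------------------------------------------
# Blocking
# ---------------------------------------------------------------------------

class TestGeneratePairs:
    def test_empty_scheme_full_cross_product(self):
        a = _table([{"ID": str(i), "SEX": "m"} for i in range(3)])
        b = _table([{"ID": str(i), "SEX": "m"} for i in range(2)], "B")
        pairs, stats = generate_pairs(a, b, BlockingScheme())
        assert len(pairs) == 6
        assert stats["n_pairs"] == 6

    def test_balanced_blocking_halves_pairs(self, rng):
        a = _table([{"ID": str(i), "SEX": "m" if i % 2 else "f"}
                    for i in range(40)])
        b = _table([{"ID": str(i), "SEX": "m" if i % 2 else "f"}
                    for i in range(40)], "B")
        pairs, _ = generate_pairs(a, b, BlockingScheme([("SEX",)]))
        assert len(pairs) == 800    # exactly half of 1600

    def test_missing_keys_sit_out_the_pass(self):
        a = _table([{"ID": "1", "SEX": ""}, {"ID": "2", "SEX": "m"}])
        b = _table([{"ID": "9", "SEX": ""}, {"ID": "8", "SEX": "m"}], "B")
        pairs, _ = generate_pairs(a, b, BlockingScheme([("SEX",)]))
        assert pairs == [("2", "8")]

    def test_union_of_passes_matches_brute_force(self, rng):
        # randomized schemes over a 50x50 fixture vs an exhaustive filter
        years = [str(1950 + i % 5) for i in range(50)]
        sexes = ["m" if i % 2 else "f" for i in range(50)]
        nats = ["CH" if i % 3 else "DE" for i in range(50)]
        mk = lambda site: _table(
            [{"ID": f"{site}{i}", "Y": years[i], "SEX": sexes[i],
              "NAT": nats[i]} for i in rng.permutation(50)], site)
        a, b = mk("A"), mk("B")
        keys = ["Y", "SEX", "NAT"]
        for _ in range(20):
            n_passes = int(rng.integers(1, 4))
            scheme = BlockingScheme([
                tuple(rng.choice(keys, size=int(rng.integers(1, 3)),
                                 replace=False))
                for _ in range(n_passes)])
            pairs, _ = generate_pairs(a, b, scheme)
            brute = set()
            for ra in a.df.itertuples(index=False):
                for rb in b.df.itertuples(index=False):
                    for p in scheme.passes:
                        if all(getattr(ra, k) == getattr(rb, k) for k in p):
                            brute.add((ra.ID, rb.ID))
                            break
            assert set(pairs) == brute

    def test_budget_warning(self):
        a = _table([{"ID": str(i), "SEX": "m"} for i in range(4)])
        b = _table([{"ID": str(i), "SEX": "m"} for i in range(4)], "B")
        with pytest.warns(RuntimeWarning):
            _, stats = generate_pairs(a, b, BlockingScheme(), pair_budget=10)
        assert stats["over_budget"]


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

def _cfg_one_var(m, u, kind="plain"):
    return LinkageConfig(
        variables=[LinkageVariable("V", kind, m_prob=m, u_prob=u)],
        thresholds=Thresholds(upper=1.0, lower=0.0))


class TestPairWeight:
    def test_full_agreement_closed_form(self):
        cfg = _cfg_one_var(0.9, 0.1)
        cv = ComparisonVector({"V": AgreementLevel.FULL}, {})
        w = pair_weight(cv, {"V": MUWeights(0.9, 0.1)}, cfg)
        assert w == pytest.approx(log2(9))

    def test_uninformative_variable_contributes_zero(self):
        cfg = _cfg_one_var(0.3, 0.3)
        for outcome in (AgreementLevel.FULL, AgreementLevel.DISAGREE):
            cv = ComparisonVector({"V": outcome}, {})
            assert pair_weight(cv, {"V": MUWeights(0.3, 0.3)}, cfg) == 0.0

    def test_all_missing_is_neutral(self):
        cfg = _cfg_one_var(0.9, 0.1)
        cv = ComparisonVector({"V": AgreementLevel.MISSING}, {})
        assert pair_weight(cv, {"V": MUWeights(0.9, 0.1)}, cfg) == 0.0

    def test_partial_interpolates_between_weights(self):
        cfg = _cfg_one_var(0.9, 0.1, kind="name")
        w = MUWeights(0.9, 0.1)
        lo = pair_weight(ComparisonVector({"V": AgreementLevel.PARTIAL},
                                          {"V": 0.80}), {"V": w}, cfg)
        hi = pair_weight(ComparisonVector({"V": AgreementLevel.PARTIAL},
                                          {"V": 0.99}), {"V": w}, cfg)
        assert w.w_minus <= lo < hi <= w.w_plus

    def test_date_category_defaults_to_midpoint(self):
        cfg = _cfg_one_var(0.9, 0.1, kind="date")
        w = MUWeights(0.9, 0.1)
        got = pair_weight(ComparisonVector(
            {"V": DateOutcome.PLUS_MINUS_ONE_DAY}, {}), {"V": w}, cfg)
        assert got == pytest.approx(w.midpoint)

    def test_configured_date_category_weight_wins(self):
        cfg = _cfg_one_var(0.9, 0.1, kind="date")
        cfg.date_category_weights = {"plus_minus_one_day": 2.25}
        got = pair_weight(ComparisonVector(
            {"V": DateOutcome.PLUS_MINUS_ONE_DAY}, {}),
            {"V": MUWeights(0.9, 0.1)}, cfg)
        assert got == 2.25

    def test_coverage_mismatch_rejected(self):
        cfg = _cfg_one_var(0.9, 0.1)
        cv = ComparisonVector({"OTHER": AgreementLevel.FULL}, {})
        with pytest.raises(ValueError):
            pair_weight(cv, {"V": MUWeights(0.9, 0.1)}, cfg)

    def test_monotone_in_single_variable_flip(self, rng):
        # flipping any one variable from disagree to full never lowers the
        # total, provided m > u
        variables = [LinkageVariable(f"V{i}", "plain",
                                     m_prob=0.8 + 0.03 * i,
                                     u_prob=0.05 * (i + 1)) for i in range(4)]
        cfg = LinkageConfig(variables=variables,
                            thresholds=Thresholds(upper=1, lower=0))
        weights = {v.name: v.weights for v in variables}
        for _ in range(30):
            base = {v.name: (AgreementLevel.FULL if rng.random() < 0.5
                             else AgreementLevel.DISAGREE)
                    for v in variables}
            w0 = pair_weight(ComparisonVector(dict(base), {}), weights, cfg)
            for v in variables:
                flipped = dict(base)
                flipped[v.name] = AgreementLevel.FULL
                w1 = pair_weight(ComparisonVector(flipped, {}), weights, cfg)
                assert w1 >= w0 - 1e-12


class TestMUWeights:
    def test_valid_range_enforced(self):
        with pytest.raises(ValueError):
            MUWeights(1.2, 0.1)
        with pytest.raises(ValueError):
            MUWeights(0.3, 0.5)

    def test_weight_signs(self):
        w = MUWeights(0.9, 0.1)
        assert w.w_plus > 0 > w.w_minus


# ---------------------------------------------------------------------------
# Classification and one-to-one resolution
# ---------------------------------------------------------------------------

class TestClassify:
    def test_boundaries(self):
        th = Thresholds(upper=10, lower=4)
        assert classify(10.0, th) == "link"        # boundary inclusive
        assert classify(6.0, th) == "possible"
        assert classify(3.99, th) == "nonlink"

    def test_degenerate_thresholds_leave_no_possible(self):
        th = Thresholds(upper=5, lower=5)
        assert classify(5.0, th) == "link"
        assert classify(4.999, th) == "nonlink"


class TestResolveOneToOne:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["id_a", "id_b", "total_weight",
                                           "decision"])

    def test_greedy_demotes_weaker_duplicate(self):
        lt = resolve_one_to_one(self._df([
            ("A1", "B1", 10.0, "link"), ("A1", "B2", 8.0, "link")]))
        got = dict(zip(zip(lt.pairs.id_a, lt.pairs.id_b), lt.pairs.decision))
        assert got[("A1", "B1")] == "link"
        assert got[("A1", "B2")] == "possible"

    def test_disjoint_links_unchanged(self):
        lt = resolve_one_to_one(self._df([
            ("A1", "B1", 10.0, "link"), ("A2", "B2", 8.0, "link")]))
        assert list(lt.pairs.decision) == ["link", "link"]

    def test_equal_weight_tie_breaks_lexicographically(self):
        lt = resolve_one_to_one(self._df([
            ("A1", "B2", 7.0, "link"), ("A1", "B1", 7.0, "link")]))
        got = dict(zip(zip(lt.pairs.id_a, lt.pairs.id_b), lt.pairs.decision))
        assert got[("A1", "B1")] == "link"
        assert got[("A1", "B2")] == "possible"


class TestEvaluate:
    def _lt(self, links):
        return LinkTable(pairs=pd.DataFrame(
            [(a, b, 10.0, "link") for a, b in links],
            columns=["id_a", "id_b", "total_weight", "decision"]))

    def test_perfect(self):
        truth = {("1", "9"), ("2", "8")}
        res = evaluate(self._lt(truth), truth)
        assert (res["precision"], res["recall"], res["f1"]) == (1, 1, 1)

    def test_empty_links_zero_recall(self):
        res = evaluate(self._lt([]), {("1", "9")})
        assert res["recall"] == 0.0

    def test_one_false_positive_in_hundred(self):
        truth = {(str(i), str(i)) for i in range(99)}
        links = set(truth) | {("x", "y")}
        res = evaluate(self._lt(links), truth)
        assert res["precision"] == pytest.approx(0.99)
        assert res["recall"] == 1.0


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

class TestRunLinkage:
    def _artifacts(self, n=60, seed=5, em=None, key=b"shared"):
        pop = generate_population(n, seed=seed)
        a, b, truth = derive_sites(pop, 0.5, em or ErrorModel.none(),
                                   seed=seed + 1)
        crypt = EncryptionConfig(key, "word")
        return prepare_site(a, crypt), prepare_site(b, crypt), truth

    def test_validation_mismatch_aborts_before_pairs(self):
        sa, sb, _ = self._artifacts()
        bad = make_validation(EncryptionConfig(b"sharee", "word"))
        with pytest.raises(ProtocolViolation, match="redone"):
            run_linkage(sa.encrypted, sb.encrypted, sa.validation, bad,
                        default_linkage_config())

    def test_clean_limit_perfect_linkage(self):
        sa, sb, truth = self._artifacts(n=120)
        lt, report = run_linkage(sa.encrypted, sb.encrypted, sa.validation,
                                 sb.validation, default_linkage_config())
        res = evaluate(lt, truth.pairs)
        assert res["precision"] == 1.0 and res["recall"] == 1.0
        assert report["decision_counts"]["link"] == len(truth.pairs)

    def test_end_to_end_deterministic_link_table_bytes(self, tmp_path):
        sa, sb, _ = self._artifacts(em=ErrorModel(), n=80)
        cfg = default_linkage_config()
        outs = []
        for i in (1, 2):
            lt, _ = run_linkage(sa.encrypted, sb.encrypted, sa.validation,
                                sb.validation, cfg)
            p = tmp_path / f"links{i}.csv"
            write_link_table(lt, p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_report_contains_no_record_level_content(self):
        sa, sb, _ = self._artifacts(n=40)
        _, report = run_linkage(sa.encrypted, sb.encrypted, sa.validation,
                                sb.validation, default_linkage_config())
        import json
        blob = json.dumps(report)
        for cell in sa.cleaned.df["SURNAME1"]:
            if cell:
                assert cell not in blob


def test_linkage_config_yaml_round_trip(tmp_path):
    doc = """
variables:
  - {name: SURNAME1, kind: name, m: 0.9, u: 0.005}
  - {name: DOB, kind: date, m: 0.95, u: 0.0005}
  - {name: SEX, kind: plain, m: 0.98, u: 0.5}
thresholds: {upper: 12, lower: 2}
blocking:
  - [DOB_year, SEX]
  - [SURNAME1]
transposition_pairs: []
"""
    p = tmp_path / "linkage.yaml"
    p.write_text(doc)
    cfg = LinkageConfig.from_yaml(p)
    assert [v.name for v in cfg.variables] == ["SURNAME1", "DOB", "SEX"]
    assert cfg.thresholds.upper == 12
    assert cfg.blocking.passes == [("DOB_year", "SEX"), ("SURNAME1",)]
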
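"""g<->e pair calls, position compositions, Asn statistics, sub-families."""

import numpy as np
import pytest

from bzipkit import dimerization as dz
from bzipkit import synth
from bzipkit.domain_scan import HeptadTable, scan_protein


def _table(rows, partial=None):
    return HeptadTable("p", rows, partial or [False] * len(rows))


def _heptad(a="Q", b="S", c="S", d="L", e="Q", f="S", g="Q"):
    return {"a": a, "b": b, "c": c, "d": d, "e": e, "f": f, "g": g}


class TestGePairCalls:
    @pytest.mark.parametrize(
        "g,e,expected",
        [
            ("E", "K", "attractive"),
            ("K", "E", "attractive"),
            ("K", "R", "repulsive"),
            ("D", "E", "repulsive"),
            ("K", "Q", "incomplete"),
            ("Q", "D", "incomplete"),
            ("Q", "S", "none"),
        ],
    )
    def test_pair_rules(self, g, e, expected):
        table = _table([_heptad(g=g), _heptad(e=e)])
        calls = dz.call_ge_pairs(table)
        assert len(calls) == 1
        assert calls[0].call == expected

    def test_histidine_neutral_by_default_configurable(self):
        table = _table([_heptad(g="H"), _heptad(e="E")])
        assert dz.call_ge_pairs(table)[0].call == "incomplete"
        assert dz.call_ge_pairs(table, include_his_basic=True)[0].call == "attractive"

    def test_partial_heptads_skipped(self):
        table = _table(
            [_heptad(g="E"), _heptad(e="K"), _heptad(e=None)],
            partial=[False, False, True],
        )
        assert len(dz.call_ge_pairs(table)) == 1

    def test_pair_count_conservation(self, scanned_cohort):
        _, _, truths, scanned = scanned_cohort
        for truth, (_, table) in zip(truths, scanned):
            calls = dz.call_ge_pairs(table)
            assert len(calls) == table.n_full - 1

    def test_planted_pair_classes_recovered(self, scanned_cohort):
        _, _, truths, scanned = scanned_cohort
        for truth, (_, table) in zip(truths, scanned):
            calls = dz.call_ge_pairs(table)
            assert [c.call for c in calls] == truth.pair_classes


class TestPositionComposition:
    def test_all_asn_cohort_is_pure_polar(self):
        tables = [_table([_heptad(a="N")] * 4) for _ in range(5)]
        comp = dz.position_composition(tables, "a")
        assert comp["polar"] == pytest.approx(1.0)

    def test_class_frequencies_sum_to_one(self, scanned_cohort):
        _, _, _, scanned = scanned_cohort
        tables = [t for _, t in scanned if t is not None]
        for pos in "gead":
            assert sum(dz.position_composition(tables, pos).values()) == pytest.approx(1.0)

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            dz.position_residue_frequencies([], "a")

    def test_x_and_empty_slots_excluded(self):
        tables = [_table([_heptad(a="X"), _heptad(a="N"), _heptad(a=None)],
                         partial=[False, False, True])]
        freqs = dz.position_residue_frequencies(tables, "a")
        assert freqs == {"N": 1.0}


class TestAsnByHeptad:
    def test_asn_planted_only_in_heptad_2(self):
        tables = [_table([_heptad(a="Q"), _heptad(a="N"), _heptad(a="Q")])
                  for _ in range(10)]
        fractions, share = dz.asn_a_by_heptad(tables)
        assert fractions[2] == 1.0
        assert fractions[1] == fractions[3] == 0.0
        assert share == 1.0  # every a-position Asn sits in heptad 2

    def test_parameter_recovery_within_binomial_ci(self):
        for p in (0.1, 0.23, 0.5):
            spec = synth.CohortSpec(
                n_proteins=200, asn_a_prob={i: p for i in range(1, 10)}
            )
            records, _ = synth.gen_protein_cohort(spec, seed=31)
            tables = [scan_protein(r)[1] for r in records]
            freqs = dz.position_residue_frequencies(tables, "a")
            n = sum(t.n_full for t in tables)
            half = 1.96 * np.sqrt(p * (1 - p) / n)
            assert abs(freqs.get("N", 0.0) - p) < half + 1e-12


class TestGeHistogram:
    def test_single_attractive_pair(self):
        table = _table([_heptad(g="E"), _heptad(e="K")])
        hist = dz.ge_histogram([dz.call_ge_pairs(table)])
        assert hist == {1: {"attractive": 1}}

    def test_categories_partition_all_pairs(self, scanned_cohort):
        _, _, _, scanned = scanned_cohort
        all_calls = [dz.call_ge_pairs(t) for _, t in scanned if t is not None]
        hist = dz.ge_histogram(all_calls)
        total = sum(sum(c.values()) for c in hist.values())
        assert total == sum(len(calls) for calls in all_calls)

    def test_monte_carlo_attract_rate_matches_generator(self):
        # attractive probability 0.5 planted at pair 1 only; the measured
        # histogram must equal the generator's realized draw exactly, and
        # the draw itself must sit in the pooled 95% binomial interval
        ge = {i: (0.0, 0.0, 0.0) for i in range(1, 9)}
        ge[1] = (0.5, 0.0, 0.0)
        spec = synth.CohortSpec(n_proteins=400, ge_probs=ge)
        measured = planted = total = 0
        for seed in (32, 33, 34):
            records, truths = synth.gen_protein_cohort(spec, seed=seed)
            tables = [scan_protein(r)[1] for r in records]
            hist = dz.ge_histogram([dz.call_ge_pairs(t) for t in tables])
            assert sum(hist[1].values()) == len(records)
            measured += hist[1].get("attractive", 0)
            planted += sum(t.pair_classes[0] == "attractive" for t in truths)
            total += len(records)
        assert measured == planted
        assert abs(measured / total - 0.5) < 1.96 * np.sqrt(0.25 / total)


class TestSubfamily:
    def test_all_attractive_all_asn_is_homo(self):
        rows = [_heptad(a="N", g="E"), _heptad(a="N", e="K", g="E"),
                _heptad(a="N", e="K")]
        profile = dz.profile_protein(_table(rows))
        assert profile.subfamily == "I"

    def test_all_repulsive_charged_a_is_hetero(self):
        rows = [_heptad(a="K", g="E"), _heptad(a="R", e="D", g="E"),
                _heptad(a="K", e="D")]
        profile = dz.profile_protein(_table(rows))
        assert profile.subfamily == "II"

    def test_neutral_profile_is_intermediate(self):
        profile = dz.profile_protein(_table([_heptad()] * 4))
        assert profile.subfamily == "III"

    def test_insufficient_zipper_flagged_iii(self):
        profile = dz.profile_protein(_table([_heptad()]))
        assert profile.subfamily == "III"
        assert "insufficient_zipper" in profile.flags

    def test_turning_a_none_pair_attractive_never_moves_toward_hetero(self):
        # flip one neutral g<->e pair to attractive in assorted profiles and
        # check the sub-family ordering II < III < I never decreases
        cfg = dz.SubfamilyConfig()
        order = {"II": 0, "III": 1, "I": 2}
        variants = [
            [_heptad(), _heptad(), _heptad()],
            [_heptad(a="K", g="E"), _heptad(e="D"), _heptad()],
            [_heptad(a="N"), _heptad(), _heptad(g="K"), _heptad(e="R")],
        ]
        for rows in variants:
            base = dz.profile_protein(_table([dict(r) for r in rows]), cfg)
            flipped = [dict(r) for r in rows]
            flipped[0]["g"] = "E"
            flipped[1]["e"] = "K"  # pair 1 becomes attractive
            extended = dz.profile_protein(_table(flipped), cfg)
            assert order[extended.subfamily] >= order[base.subfamily]
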
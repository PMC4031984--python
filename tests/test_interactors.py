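"""iBAQ abundances, median normalisation, and the specificity filters."""

import numpy as np
import pandas as pd
import pytest

from strucfind.interactors import (
    InteractorCriteria,
    PulldownTable,
    call_interactors,
    compute_ibaq,
    normalize_median,
)
from strucfind.seqkit import Sequence, count_theoretical_peptides

# a sequence with exactly 10 theoretical 6-30mer tryptic peptides
TEN_PEPTIDES = "AAAAAK" * 10 + "AK"
SIMPLE = "AAAAAAKCCCCCCR"  # two peptides in the 6-30 window


def make_table(counts, intensities, sequences=None):
    cdf = pd.DataFrame(counts).T
    idf = pd.DataFrame(intensities).T
    if sequences is None:
        sequences = {pid: Sequence(pid, SIMPLE) for pid in cdf.index}
    return PulldownTable(counts=cdf, intensities=idf, sequences=sequences)


def small_table(extra=None, n_exp=3):
    """bait + one partner (+ optional extra protein rows)."""
    exps = [f"e{i}" for i in range(1, n_exp + 1)] + ["ctrl"]
    counts = {
        "bait": dict.fromkeys(exps, 50) | {"ctrl": 0},
        "prey": dict.fromkeys(exps, 20) | {"ctrl": 0},
    }
    intens = {
        "bait": dict.fromkeys(exps, 3e9) | {"ctrl": 0.0},
        "prey": dict.fromkeys(exps, 1e9) | {"ctrl": 0.0},
    }
    if extra:
        for pid, (c, x) in extra.items():
            counts[pid] = c
            intens[pid] = x
    return make_table(counts, intens)


class TestIbaq:
    def test_formula(self):
        seqs = {"p": Sequence("p", TEN_PEPTIDES)}
        assert count_theoretical_peptides(seqs["p"]) == 10
        t = make_table({"p": {"e1": 5}}, {"p": {"e1": 3e9}}, seqs)
        assert compute_ibaq(t).loc["p", "e1"] == pytest.approx(3e8)

    def test_zero_intensity_gives_zero_abundance(self):
        t = make_table({"p": {"e1": 0}}, {"p": {"e1": 0.0}})
        assert compute_ibaq(t).loc["p", "e1"] == 0.0

    def test_zero_theoretical_peptides_excluded_with_warning(self):
        seqs = {"p": Sequence("p", "AAA"), "q": Sequence("q", SIMPLE)}
        t = make_table(
            {"p": {"e1": 3}, "q": {"e1": 3}},
            {"p": {"e1": 1e9}, "q": {"e1": 1e9}},
            seqs,
        )
        with pytest.warns(UserWarning, match="zero theoretical"):
            ibaq = compute_ibaq(t)
        assert list(ibaq.index) == ["q"]

    def test_equimolar_complex_ratios_near_planted(self, pulldown):
        """Synthetic equimolar partners: iBAQ ratios to bait within 3 CV
        of the planted molar ratios."""
        ibaq = compute_ibaq(pulldown.table)
        bait_exps = [e for e in pulldown.table.experiments if e not in pulldown.control_labels]
        partners = sorted(pulldown.planted_called - {pulldown.bait_id, pulldown.tag_id})
        for p in partners:
            ratios = ibaq.loc[p, bait_exps] / ibaq.loc[pulldown.bait_id, bait_exps]
            planted = pulldown.molar[p] / pulldown.molar[pulldown.bait_id]
            assert np.median(ratios) == pytest.approx(planted, rel=3 * 0.2)


class TestNormalizeMedian:
    def test_simple_case(self):
        s = pd.Series({"a": 2.0, "b": 4.0, "c": 8.0})
        out = normalize_median(s)
        assert list(out) == [0.5, 1.0, 2.0]

    def test_pairwise_ratios_preserved(self, rng):
        s = pd.Series(rng.uniform(0.1, 100, size=20))
        out = normalize_median(s)
        assert out[3] / out[11] == pytest.approx(s[3] / s[11])

    def test_median_exactly_one_on_random_tables(self, rng):
        for _ in range(50):
            s = pd.Series(10.0 ** rng.uniform(-3, 3, size=int(rng.integers(1, 30))))
            out = normalize_median(s)
            # even-length pools interpolate the median, leaving 1 ulp of slack
            assert float(out.median()) == pytest.approx(1.0, abs=1e-15)

    def test_all_zero_experiment_is_error(self):
        with pytest.raises(ValueError):
            normalize_median(pd.Series([0.0, 0.0]))


class TestCallInteractors:
    def test_four_total_peptides_not_called(self):
        extra = {"weak": ({"e1": 2, "e2": 1, "e3": 1, "ctrl": 0},
                          {"e1": 5e8, "e2": 5e8, "e3": 5e8, "ctrl": 0.0})}
        calls = {c.protein_id: c for c in call_interactors(small_table(extra), "bait", ["ctrl"])}
        assert not calls["weak"].called
        assert "low_peptides" in calls["weak"].reasons
        # five peptides passes the same filter
        extra5 = {"weak": ({"e1": 2, "e2": 2, "e3": 1, "ctrl": 0},
                           {"e1": 5e8, "e2": 5e8, "e3": 5e8, "ctrl": 0.0})}
        calls5 = {c.protein_id: c for c in call_interactors(small_table(extra5), "bait", ["ctrl"])}
        assert "low_peptides" not in calls5["weak"].reasons

    def test_sub_ratio_protein_not_called(self):
        extra = {"speck": ({"e1": 3, "e2": 3, "e3": 3, "ctrl": 0},
                           {"e1": 3e6, "e2": 3e6, "e3": 3e6, "ctrl": 0.0})}
        calls = {c.protein_id: c for c in call_interactors(small_table(extra), "bait", ["ctrl"])}
        assert calls["speck"].median_ratio_to_bait < 0.002
        assert calls["speck"].reasons == ("low_ratio",)

    def test_control_detection_eliminates(self):
        extra = {"sticky": ({"e1": 10, "e2": 10, "e3": 10, "ctrl": 4},
                            {"e1": 1e9, "e2": 1e9, "e3": 1e9, "ctrl": 5e8})}
        calls = {c.protein_id: c for c in call_interactors(small_table(extra), "bait", ["ctrl"])}
        assert calls["sticky"].reasons == ("control_present",)

    def test_inconsistent_detection_eliminates(self):
        extra = {"flaky": ({"e1": 10, "e2": 0, "e3": 0, "ctrl": 0},
                           {"e1": 1e9, "e2": 0.0, "e3": 0.0, "ctrl": 0.0})}
        calls = {c.protein_id: c for c in call_interactors(small_table(extra), "bait", ["ctrl"])}
        assert "inconsistent" in calls["flaky"].reasons

    def test_bait_absent_from_experiment_is_error(self):
        t = small_table()
        t.counts.loc["bait", "e2"] = 0
        t.intensities.loc["bait", "e2"] = 0.0
        with pytest.raises(ValueError, match="bait"):
            call_interactors(t, "bait", ["ctrl"])

    def test_reasons_are_exhaustive(self, pulldown):
        calls = call_interactors(
            pulldown.table, pulldown.bait_id, pulldown.control_labels, tag_id=pulldown.tag_id
        )
        for c in calls:
            assert c.called == (not c.reasons)
            if not c.called:
                assert len(c.reasons) >= 1

    def test_planted_recovery_exactly_ten(self, pulldown):
        """Default synthetic pulldown: exactly the 10 planted proteins
        (bait + tag + 8 equimolar partners) are called."""
        calls = call_interactors(
            pulldown.table, pulldown.bait_id, pulldown.control_labels, tag_id=pulldown.tag_id
        )
        called = {c.protein_id for c in calls if c.called}
        assert called == pulldown.planted_called
        assert len(called) == 10

    def test_calling_invariant_to_per_experiment_rescaling(self, pulldown):
        t = pulldown.table
        scaled = PulldownTable(
            counts=t.counts.copy(),
            intensities=t.intensities * pd.Series(
                {e: 10.0 ** ((i % 5) - 2) for i, e in enumerate(t.experiments)}
            ),
            sequences=t.sequences,
        )
        base = call_interactors(t, pulldown.bait_id, pulldown.control_labels, tag_id=pulldown.tag_id)
        resc = call_interactors(scaled, pulldown.bait_id, pulldown.control_labels, tag_id=pulldown.tag_id)
        assert [(c.protein_id, c.called, c.reasons) for c in base] == [
            (c.protein_id, c.called, c.reasons) for c in resc
        ]

    def test_tightening_never_adds_a_call(self, pulldown):
        loose = call_interactors(pulldown.table, pulldown.bait_id, pulldown.control_labels,
                                 tag_id=pulldown.tag_id)
        tight = call_interactors(
            pulldown.table,
            pulldown.bait_id,
            pulldown.control_labels,
            InteractorCriteria(min_peptides=30, min_ratio=0.05, min_experiments=5),
            tag_id=pulldown.tag_id,
        )
        assert {c.protein_id for c in tight if c.called} <= {c.protein_id for c in loose if c.called}

    def test_tsv_round_trip(self, pulldown):
        text = pulldown.table.to_tsv()
        back = PulldownTable.from_tsv(text, pulldown.table.sequences)
        pd.testing.assert_frame_equal(back.counts, pulldown.table.counts, check_names=False)
        pd.testing.assert_frame_equal(back.intensities, pulldown.table.intensities, check_names=False)
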
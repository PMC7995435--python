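"""Penalty construction: mutation classification, adjustment factors,
passenger-probability formulas, CNV thresholding, hybrid merging and the
simplified penalty variants."""

import math

import numpy as np
import pandas as pd
import pytest

from crso.matrix import binarize, format_code, validate_pair
from crso.penalties import (
    ControlGeneStats,
    MutationRecord,
    PenaltyBuildError,
    SubstitutionRateTable,
    classify_mutations,
    cnv_cell_probs,
    cnv_passenger_probs,
    control_gene_stats,
    gene_cnv_code,
    merge_hybrids,
    mutation_passenger_probs,
    parse_protein_position,
    patient_adjustments,
    simplified_penalties,
    threshold_cnv,
)

COHORT = [f"s{j}" for j in range(6)]


def rec(sample, gene, vclass, pos=None):
    return MutationRecord(sample, gene, vclass, pos)


class TestClassification:
    def test_position_in_three_samples_is_hotspot(self):
        records = [rec(f"s{j}", "BRAF", "missense", 600) for j in range(3)]
        m, hs = classify_mutations(records, ["BRAF"], COHORT)
        assert hs == {"BRAF": {600}}
        for j in range(3):
            assert m.codes[0][j] == frozenset({"HS"})

    def test_two_samples_at_position_is_not_hotspot(self):
        records = [rec(f"s{j}", "BRAF", "missense", 600) for j in range(2)]
        m, hs = classify_mutations(records, ["BRAF"], COHORT)
        assert hs == {}
        assert m.codes[0][0] == frozenset({"L"})

    def test_same_sample_counts_once_per_position(self):
        # two distinct substitutions at one position in one sample: 1 carrier
        records = [
            rec("s0", "BRAF", "missense", 600),
            rec("s0", "BRAF", "nonsense", 600),
            rec("s1", "BRAF", "missense", 600),
        ]
        _, hs = classify_mutations(records, ["BRAF"], COHORT)
        assert hs == {}

    def test_silent_only_stays_wild_type(self):
        records = [rec("s0", "TP53", "silent", 100)]
        m, _ = classify_mutations(records, ["TP53"], COHORT)
        assert m.codes[0][0] == frozenset()

    def test_silent_never_becomes_hotspot(self):
        records = [rec(f"s{j}", "TP53", "silent", 100) for j in range(5)]
        _, hs = classify_mutations(records, ["TP53"], COHORT)
        assert hs == {}

    def test_nonsense_plus_missense_off_hotspot_is_loss(self):
        records = [
            rec("s0", "TP53", "nonsense", 120),
            rec("s0", "TP53", "missense", 250),
        ]
        m, _ = classify_mutations(records, ["TP53"], COHORT)
        assert m.codes[0][0] == frozenset({"L"})

    def test_nonrecurrent_splice_substitution_is_s(self):
        records = [rec("s0", "TP53", "splice", 33)]
        m, _ = classify_mutations(records, ["TP53"], COHORT)
        assert m.codes[0][0] == frozenset({"S"})

    def test_recurrent_splice_substitution_becomes_hotspot(self):
        records = [rec(f"s{j}", "TP53", "splice", 33) for j in range(3)]
        m, _ = classify_mutations(records, ["TP53"], COHORT)
        assert m.codes[0][0] == frozenset({"HS"})

    def test_splice_without_position_is_loss_not_s(self):
        # no amino-acid annotation: excluded from hotspot tallies, coded L
        records = [rec("s0", "TP53", "splice", None)]
        m, _ = classify_mutations(records, ["TP53"], COHORT)
        assert m.codes[0][0] == frozenset({"L"})

    def test_inframe_indel_precedence_below_hotspot(self):
        records = [rec(f"s{j}", "KIT", "missense", 559) for j in range(3)]
        records.append(rec("s0", "KIT", "in-frame-indel", None))
        m, _ = classify_mutations(records, ["KIT"], COHORT)
        assert m.codes[0][0] == frozenset({"HS"})

    def test_protein_position_parsing(self):
        assert parse_protein_position("p.V600E") == 600
        assert parse_protein_position("p.*757L") == 757
        assert parse_protein_position("") is None
        assert parse_protein_position(None) is None


class TestPatientAdjustments:
    def test_identical_counts_give_unit_factors(self):
        records = [rec(s, "GENE1", "missense", 1) for s in COHORT]
        adj = patient_adjustments(records, ["TP53"], COHORT)
        assert np.allclose(adj.factors.to_numpy(), 1.0)

    def test_zero_count_floored_at_one(self):
        adj = patient_adjustments([], ["TP53"], COHORT)
        assert (adj.counts == 1).all()

    def test_hand_computed_factors(self):
        cohort = ["a", "b", "c"]
        records = (
            [rec("a", "G", "missense", 1)] * 2
            + [rec("b", "G", "missense", 1)] * 2
            + [rec("c", "G", "missense", 1)] * 4
        )
        adj = patient_adjustments(records, [], cohort)
        mean = (2 + 2 + 4) / 3
        assert adj.factors["a"] == pytest.approx(2 / mean)
        assert adj.factors["c"] == pytest.approx(4 / mean)

    def test_outlier_capped_at_ten_times_q75(self):
        cohort = [f"s{j}" for j in range(5)]
        counts = [10, 10, 10, 10, 1000]
        records = []
        for s, c in zip(cohort, counts):
            records += [rec(s, "G", "missense", 1)] * c
        adj = patient_adjustments(records, [], cohort)
        assert adj.counts["s4"] == pytest.approx(100.0)  # 10 x Q75(10)

    def test_smg_mutations_do_not_count(self):
        records = [rec("s0", "TP53", "missense", 1)] * 5
        adj = patient_adjustments(records, ["TP53"], COHORT)
        assert adj.counts["s0"] == 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(PenaltyBuildError):
            patient_adjustments([], [], [])


class TestMutationProbs:
    def _rates(self, rows, lengths=None):
        return SubstitutionRateTable(
            pd.DataFrame(rows, columns=["gene", "position", "rate"]),
            lengths or {"BRAF": 480},
        )

    def test_hotspot_probability_sums_hotspot_rates(self):
        records = [rec(f"s{j}", "BRAF", "missense", 600) for j in range(3)]
        m, hs = classify_mutations(records, ["BRAF"], COHORT)
        rates = self._rates(
            [("BRAF", 600, 1e-4), ("BRAF", 600, 2e-4), ("BRAF", 12, 5e-4)]
        )
        adj = patient_adjustments([], ["BRAF"], COHORT)  # all factors 1
        probs = mutation_passenger_probs(m, rates, ControlGeneStats(0.001, 0.001), adj, hs)
        assert probs[0, 0] == pytest.approx(3e-4)

    def test_loss_probability_excludes_hotspot_positions(self):
        records = [rec(f"s{j}", "BRAF", "missense", 600) for j in range(3)]
        records.append(rec("s3", "BRAF", "nonsense", 12))
        m, hs = classify_mutations(records, ["BRAF"], COHORT)
        rates = self._rates(
            [("BRAF", 600, 1e-4), ("BRAF", 12, 5e-4), ("BRAF", 20, 3e-4)]
        )
        adj = patient_adjustments([], ["BRAF"], COHORT)
        probs = mutation_passenger_probs(m, rates, ControlGeneStats(0.001, 0.001), adj, hs)
        assert probs[0, 3] == pytest.approx(8e-4)

    def test_protein_of_480_aa_has_unit_length_factor(self):
        records = [rec("s0", "BRAF", "in-frame-indel", None)]
        m, hs = classify_mutations(records, ["BRAF"], COHORT)
        adj = patient_adjustments([], ["BRAF"], COHORT)
        probs = mutation_passenger_probs(
            m, self._rates([("BRAF", 1, 1e-5)]), ControlGeneStats(0.002, 0.001), adj, hs
        )
        assert probs[0, 0] == pytest.approx(0.002)  # length 480 -> factor 1.0

    def test_patient_factor_multiplies_probability(self):
        records = [rec("s0", "BRAF", "in-frame-indel", None)]
        background = [rec("s0", "G", "missense", 1)] * 4 + [
            rec(s, "G", "missense", 1) for s in COHORT[1:]
        ]
        m, hs = classify_mutations(records, ["BRAF"], COHORT)
        adj = patient_adjustments(background, ["BRAF"], COHORT)
        probs = mutation_passenger_probs(
            m, self._rates([("BRAF", 1, 1e-5)]), ControlGeneStats(0.002, 0.001), adj, hs
        )
        assert probs[0, 0] == pytest.approx(0.002 * adj.factors["s0"])

    def test_missing_protein_length_raises(self):
        records = [rec("s0", "KRAS", "in-frame-indel", None)]
        m, hs = classify_mutations(records, ["KRAS"], COHORT)
        adj = patient_adjustments([], ["KRAS"], COHORT)
        with pytest.raises(PenaltyBuildError, match="protein length"):
            mutation_passenger_probs(
                m, self._rates([("KRAS", 1, 1e-5)]), ControlGeneStats(0.001, 0.001), adj, hs
            )

    def test_negative_rate_rejected(self):
        with pytest.raises(PenaltyBuildError, match="negative"):
            self._rates([("BRAF", 600, -1e-4)])

    def test_control_gene_stats(self):
        records = [rec("s0", "CTL1", "in-frame-indel"), rec("s1", "CTL2", "splice", 5)]
        stats = control_gene_stats(records, ["CTL1", "CTL2"], 10)
        assert stats.inframe_rate == pytest.approx(1 / 20)
        assert stats.splice_rate == pytest.approx(1 / 20)


class TestThresholdCnv:
    def _inputs(self):
        focal = pd.DataFrame(
            {
                "s0": [0.2, 0.5, -0.8],
                "s1": [1.2, 0.5, -0.1],
                "s2": [-0.5, -1.6, 0.4],
            },
            index=["G1", "G2", "G3"],
        )
        cutoffs = pd.DataFrame(
            {"low": [-1.3, -1.3, -1.3], "high": [1.0, 1.0, 1.0]},
            index=["s0", "s1", "s2"],
        )
        return focal, cutoffs

    def test_copy_neutral_band(self):
        assert gene_cnv_code(0.2, -1.3, 1.0) == "Z"
        assert gene_cnv_code(-0.3, -1.3, 1.0) == "Z"

    def test_strong_weak_boundaries(self):
        assert gene_cnv_code(1.2, -1.3, 1.0) == "SA"
        assert gene_cnv_code(0.5, -1.3, 1.0) == "WA"
        assert gene_cnv_code(-1.6, -1.3, 1.0) == "SD"
        assert gene_cnv_code(-0.8, -1.3, 1.0) == "WD"

    def test_extreme_method_takes_peak_maximum(self):
        focal, cutoffs = self._inputs()
        amp, _ = threshold_cnv(focal, cutoffs, {"PK": ["G1", "G2"]}, {})
        # s1: max(1.2, 0.5) = 1.2 > high cutoff 1.0 -> SA
        assert amp.codes[0][1] == frozenset({"SA"})

    def test_deletion_inside_amplification_peak_is_wild_type(self):
        focal, cutoffs = self._inputs()
        amp, _ = threshold_cnv(focal, cutoffs, {"PK": ["G1"]}, {})
        # s2: G1 = -0.5 (a deletion) inside an amplification peak -> Z
        assert amp.codes[0][2] == frozenset()

    def test_deletion_peak_takes_minimum(self):
        focal, cutoffs = self._inputs()
        _, dele = threshold_cnv(focal, cutoffs, {}, {"PK": ["G2", "G3"]})
        assert dele.codes[0][2] == frozenset({"SD"})  # min(-1.6, 0.4) < low

    def test_missing_peak_gene_raises(self):
        focal, cutoffs = self._inputs()
        with pytest.raises(PenaltyBuildError, match="absent"):
            threshold_cnv(focal, cutoffs, {"PK": ["NOPE"]}, {})


class TestCnvProbs:
    def test_rates_follow_printed_formulas(self):
        # 10 cytobands x 100 samples with known counts
        arr = np.full((10, 100), "Z", dtype=object)
        arr.flat[:5] = "SD"
        arr.flat[5:20] = "WD"
        ctl = pd.DataFrame(arr, columns=[f"s{j}" for j in range(100)])
        rates = cnv_passenger_probs(ctl)
        assert rates.mu_sd == pytest.approx(5 / 1000)
        assert rates.mu_wd == pytest.approx(20 / 1000)  # (5 + 15) / 1000
        assert rates.mu_wd >= rates.mu_sd and rates.mu_wa >= rates.mu_sa

    def test_zero_counts_still_give_positive_factors(self):
        arr = np.full((4, 5), "Z", dtype=object)
        arr[0, 0] = "WD"  # a single deletion somewhere
        ctl = pd.DataFrame(arr, columns=[f"s{j}" for j in range(5)])
        rates = cnv_passenger_probs(ctl)
        assert rates.mu_sd == 0.0
        assert (rates.f_del > 0).all() and (rates.f_amp > 0).all()

    def test_factor_formula_with_smoothing(self):
        # sample with zero deleted control cytobands, cohort mean 4
        arr = np.full((8, 2), "Z", dtype=object)
        arr[:8, 0] = "WD"  # sample 0 has 8 deletions, sample 1 none; mean 4
        ctl = pd.DataFrame(arr, columns=["s0", "s1"])
        rates = cnv_passenger_probs(ctl)
        assert rates.f_del["s1"] == pytest.approx(0.5 / 4.5)

    def test_empty_control_matrix_rejected(self):
        with pytest.raises(PenaltyBuildError):
            cnv_passenger_probs(pd.DataFrame())


def build_small_hybrid():
    """CDKN2A is both an SMG and a deletion peak; KRAS mutation only."""
    cohort = ["s0", "s1", "s2", "s3"]
    records = [
        rec("s0", "CDKN2A", "nonsense", 80),
        rec("s2", "KRAS", "missense", 12),
        rec("s2", "CDKN2A", "missense", 58),
    ]
    m_mut, hs = classify_mutations(records, ["CDKN2A", "KRAS"], cohort)
    adj = patient_adjustments([], ["CDKN2A", "KRAS"], cohort)
    rates = SubstitutionRateTable(
        pd.DataFrame(
            [("CDKN2A", 80, 2e-4), ("CDKN2A", 58, 1e-4), ("KRAS", 12, 5e-5)],
            columns=["gene", "position", "rate"],
        ),
        {"CDKN2A": 156, "KRAS": 189},
    )
    mut_probs = mutation_passenger_probs(m_mut, rates, ControlGeneStats(1e-3, 1e-3), adj, hs)
    focal = pd.DataFrame(
        {"s0": [-0.8], "s1": [-1.9], "s2": [0.0], "s3": [0.0]}, index=["CDKN2A"]
    )
    cutoffs = pd.DataFrame(
        {"low": [-1.3] * 4, "high": [1.0] * 4}, index=cohort
    )
    amp_m, del_m = threshold_cnv(focal, cutoffs, {}, {"CDKN2A": ["CDKN2A"]})
    arr = np.full((10, 4), "Z", dtype=object)
    arr[0, :] = "WD"
    ctl = pd.DataFrame(arr, columns=cohort)
    cyrates = cnv_passenger_probs(ctl)
    amp_probs = cnv_cell_probs(amp_m, cyrates)
    del_probs = cnv_cell_probs(del_m, cyrates)
    return m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs


class TestMergeHybrids:
    def test_hybrid_co_observation_sums_penalties(self):
        m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs = build_small_hybrid()
        m, d, p = merge_hybrids(m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs)
        i = d.event_labels.index("CDKN2A-MD")
        # s0 carries both a loss mutation and a weak deletion
        assert m.codes[i][0] == frozenset({"L", "WD"})
        expected = -math.log(mut_probs[0, 0]) + -math.log(del_probs[0, 0])
        assert p.penalties[i, 0] == pytest.approx(expected)

    def test_wild_type_in_both_sources_stays_zero(self):
        m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs = build_small_hybrid()
        m, d, p = merge_hybrids(m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs)
        i = d.event_labels.index("CDKN2A-MD")
        assert m.codes[i][3] == frozenset()
        assert p.penalties[i, 3] == 0.0

    def test_smg_without_peak_unchanged(self):
        m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs = build_small_hybrid()
        m, d, p = merge_hybrids(m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs)
        i = d.event_labels.index("KRAS-M")
        assert m.codes[i][2] == frozenset({"L"})
        assert p.penalties[i, 2] == pytest.approx(-math.log(mut_probs[1, 2]))

    def test_consumed_peak_removed_from_events(self):
        m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs = build_small_hybrid()
        _, d, _ = merge_hybrids(m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs)
        assert "CDKN2A-D" not in d.event_labels

    def test_zero_alignment_invariant_holds_after_build(self):
        m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs = build_small_hybrid()
        _, d, p = merge_hybrids(m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs)
        assert validate_pair(d, p).consistent

    def test_double_hybrid_without_exception_raises(self):
        m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs = build_small_hybrid()
        # also put CDKN2A in an amplification peak (artificial conflict)
        import copy

        from crso.matrix import CategoricalEventMatrix, EventDef

        amp2 = CategoricalEventMatrix(
            [EventDef("CDKN2A", "CDKN2A-A", "amplification")],
            list(amp_m.samples),
            [[frozenset()] * 4],
        )
        with pytest.raises(PenaltyBuildError, match="exception"):
            merge_hybrids(
                m_mut, amp2, del_m, mut_probs, np.ones((1, 4)), del_probs
            )
        # with an exception entry the build succeeds
        m, d, p = merge_hybrids(
            m_mut, amp2, del_m, mut_probs, np.ones((1, 4)), del_probs,
            exceptions={"CDKN2A": "mutdel"},
        )
        assert "CDKN2A-MD" in d.event_labels

    def test_doubling_probabilities_shifts_penalties_by_log2(self):
        m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs = build_small_hybrid()
        _, d1, p1 = merge_hybrids(m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs)
        _, d2, p2 = merge_hybrids(
            m_mut, amp_m, del_m, mut_probs * 2, amp_probs, del_probs
        )
        i = d1.event_labels.index("KRAS-M")
        delta = p1.penalties[i, 2] - p2.penalties[i, 2]
        assert delta == pytest.approx(math.log(2))


class TestSimplifiedPenalties:
    def _mp(self):
        m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs = build_small_hybrid()
        return merge_hybrids(m_mut, amp_m, del_m, mut_probs, amp_probs, del_probs)

    def test_uniform_mode_fixed_penalty(self):
        m, d, p = self._mp()
        u = simplified_penalties(m, p, "U")
        assert np.allclose(u.penalties[d.values & (np.ones_like(d.values))][:], -math.log(0.1))
        assert (u.penalties[~d.values] == 0).all()

    def test_fc_mode_assigns_type_means(self):
        m, d, p = self._mp()
        fc = simplified_penalties(m, p, "FC")
        # every single-code L cell takes the mean of all L penalties
        l_cells = [
            (i, j)
            for i in range(len(m.events))
            for j in range(len(m.samples))
            if m.codes[i][j] == frozenset({"L"})
        ]
        vals = [p.penalties[i, j] for i, j in l_cells]
        for i, j in l_cells:
            assert fc.penalties[i, j] == pytest.approx(np.mean(vals))

    def test_fg_mode_requires_global_means(self):
        m, d, p = self._mp()
        with pytest.raises(ValueError):
            simplified_penalties(m, p, "FG")
        fg = simplified_penalties(m, p, "FG", global_means={c: 2.0 for c in "HS L S I WA SA WD SD".split()})
        assert fg.penalties[0, 0] == pytest.approx(4.0)  # hybrid L,WD = 2 + 2

    def test_uniform_mode_invariant_to_chosen_probability(self):
        # downstream core rules identical for any fixed probability
        from crso import run_crso
        from crso.matrix import BinaryEventMatrix, PenaltyMatrix
        from crso.optimize import SearchConfig

        rng = np.random.default_rng(4)
        values = rng.random((8, 60)) < 0.4
        labels = [f"E{i}-M" for i in range(8)]
        samples = [f"s{j}" for j in range(60)]
        d = BinaryEventMatrix(labels, samples, values)
        results = []
        for prob in (0.1, 0.37):
            pen = np.where(values, -math.log(prob), 0.0)
            p = PenaltyMatrix(labels, samples, pen)
            cfg = SearchConfig(p1_spr=5, p2_mnrs=5000, p3_mrns=2000, p4_mrns=2000, msa=2)
            res = run_crso(d, p, seed=3, cfg=cfg, min_coverage=0.1, gc_iterations=10)
            results.append((res.core_k, set(res.core_rules)))
        assert results[0] == results[1]
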
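"""Tissue signatures, differential calls, chi-squared, cross-tissue patterns."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as scipy_chi2

from fibroprof import (
    TissueStateProfile,
    call_differential,
    chi_squared_counts,
    chronic_inflammation_report,
    classify_cross_tissue,
    derive_tissue_signatures,
)
from fibroprof.io_formats import FRACTIONS
from fibroprof.quantitation import build_profile_table


def make_profile(tissue, state, proteins):
    """proteins: accession -> fraction -> per-replicate peptide sets."""
    peptide_sets = {}
    for acc, fractions in proteins.items():
        for rep in (1, 2, 3):
            for fraction, sets in fractions.items():
                peps = sets[rep - 1] if rep - 1 < len(sets) else set()
                peptide_sets.setdefault(acc, {}).setdefault(rep, {})[fraction] = peps
    table = build_profile_table(
        peptide_sets,
        names={acc: acc.lower() for acc in proteins},
        n_observable={acc: 20 for acc in proteins},
        replicates=[1, 2, 3],
    )
    return TissueStateProfile(tissue, state, table)


def detections(n_start, count):
    """count peptides seen in all three replicates."""
    peps = {f"pep{n_start + i}" for i in range(count)}
    return [set(peps)] * 3


class TestChiSquared:
    def test_equal_counts_give_zero_and_one(self):
        stat, p = chi_squared_counts(5, 5)
        assert stat == 0.0
        assert p == 1.0

    def test_zero_versus_ten(self):
        stat, p = chi_squared_counts(0, 10)
        assert stat == pytest.approx(10.0)
        assert p == pytest.approx(0.00157, abs=5e-5)

    def test_two_versus_eight_not_significant(self):
        stat, p = chi_squared_counts(2, 8)
        assert stat == pytest.approx(3.6)
        assert p == pytest.approx(0.0578, abs=5e-4)

    def test_p_matches_survival_function_closely(self):
        for c, t in [(0, 10), (2, 8), (1.5, 6.25), (3.3, 3.3), (0.5, 12)]:
            stat, p = chi_squared_counts(c, t)
            e = (c + t) / 2
            expected_stat = (c - e) ** 2 / e + (t - e) ** 2 / e
            assert stat == pytest.approx(expected_stat, abs=1e-12)
            assert p == pytest.approx(scipy_chi2.sf(expected_stat, 1), abs=1e-10)

    def test_statistic_symmetric_under_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            c, t = rng.uniform(0.1, 20, size=2)
            assert chi_squared_counts(c, t)[0] == pytest.approx(
                chi_squared_counts(t, c)[0])

    def test_p_decreases_with_imbalance_at_fixed_total(self):
        total = 12.0
        ps = [chi_squared_counts(total / 2 - d, total / 2 + d)[1]
              for d in (0, 1, 2, 3, 4, 5)]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_counts(0, 0)


class TestSignatures:
    def build_profiles(self):
        skin = make_profile("skin", "control", {
            "P_SKIN": {"cytoplasm": detections(0, 4)},
            "P_PAIR": {"cytoplasm": detections(10, 3)},
            "P_ALL": {"cytoplasm": detections(20, 5)},
        })
        bm = make_profile("bone_marrow", "control", {
            "P_PAIR": {"cytoplasm": detections(10, 3)},
            "P_ALL": {"cytoplasm": detections(20, 5)},
        })
        lung = make_profile("lung", "control", {
            "P_ALL": {"cytoplasm": detections(20, 5)},
        })
        return {("skin", "control"): skin, ("bone_marrow", "control"): bm,
                ("lung", "control"): lung}

    def test_exclusive_and_shared_classes(self):
        entries = derive_tissue_signatures(self.build_profiles())
        by_acc = {e.accession: e for e in entries}
        assert by_acc["P_SKIN"].signature_class == "exclusive"
        assert by_acc["P_SKIN"].tissues == ("skin",)
        assert by_acc["P_PAIR"].signature_class == "shared"
        assert by_acc["P_PAIR"].tissues == ("bone_marrow", "skin")
        assert by_acc["P_PAIR"].absent_tissues == ("lung",)
        assert "P_ALL" not in by_acc  # present everywhere, no signature

    def test_classes_partition(self):
        entries = derive_tissue_signatures(self.build_profiles())
        accs = [e.accession for e in entries]
        assert len(accs) == len(set(accs))

    def test_single_tissue_rejected(self):
        profiles = {("skin", "control"): self.build_profiles()[("skin", "control")]}
        with pytest.raises(ValueError):
            derive_tissue_signatures(profiles)

    def test_planted_signatures_recovered(self, small_study):
        truth = small_study.truth
        entries = derive_tissue_signatures(small_study.profiles)
        exclusive = {e.accession: e.tissues[0] for e in entries
                     if e.signature_class == "exclusive"}
        for tissue, accs in truth.tissue_exclusive.items():
            for acc in accs:
                assert exclusive.get(acc) == tissue
        assert not set(truth.core) & set(exclusive)


class TestDifferential:
    def build_pair(self):
        control = make_profile("skin", "control", {
            "P_UP": {"secretome": [set(), set(), set()]},
            "P_FLAT": {"secretome": detections(0, 3)},
            "P_DOWN": {"secretome": detections(10, 4)},
        })
        treated = make_profile("skin", "il1b", {
            "P_UP": {"secretome": detections(20, 8)},
            "P_FLAT": {"secretome": detections(0, 3)},
            "P_DOWN": {"secretome": [set(), set(), set()]},
        })
        return control, treated

    def test_directions_from_bins(self):
        control, treated = self.build_pair()
        calls = call_differential(control, treated, "secretome").set_index("accession")
        assert calls.loc["P_UP", "direction"] == "up"
        assert calls.loc["P_UP", "control_bin"] == "-"
        assert calls.loc["P_UP", "treated_bin"] == "+++"
        assert calls.loc["P_FLAT", "direction"] == "unchanged"
        assert calls.loc["P_DOWN", "direction"] == "down"

    def test_undetected_on_both_sides_omitted(self):
        control, treated = self.build_pair()
        calls = call_differential(control, treated, "cytoplasm")
        assert calls.empty

    def test_antisymmetry_under_swap(self):
        control, treated = self.build_pair()
        fwd = call_differential(control, treated, "secretome").set_index("accession")
        rev = call_differential(
            TissueStateProfile("skin", "il1b", treated.table),
            TissueStateProfile("skin", "control", control.table),
            "secretome",
        ).set_index("accession")
        flip = {"up": "down", "down": "up", "unchanged": "unchanged"}
        for acc in fwd.index:
            assert rev.loc[acc, "direction"] == flip[fwd.loc[acc, "direction"]]

    def test_significance_requires_small_p(self):
        control, treated = self.build_pair()
        calls = call_differential(control, treated, "secretome")
        assert ((~calls["significant"]) | (calls["p_value"] < 0.05)).all()
        assert calls.set_index("accession").loc["P_UP", "significant"]

    def test_mismatched_cell_types_rejected(self):
        control, _ = self.build_pair()
        other = TissueStateProfile("lung", "il1b", control.table)
        with pytest.raises(ValueError, match="cell types"):
            call_differential(control, other, "secretome")

    def test_ambiguous_detection_flagged_low_confidence(self):
        control = make_profile("skin", "control", {
            "P_AMB": {"secretome": [set(), set(), {"pep1", "pep2"}]},
        })
        treated = make_profile("skin", "il1b", {
            "P_AMB": {"secretome": detections(10, 6)},
        })
        calls = call_differential(control, treated, "secretome")
        assert calls.iloc[0]["low_confidence"]


class TestCrossTissue:
    @pytest.mark.parametrize("directions, expected", [
        ({"skin": "up", "lung": "up", "bone_marrow": "up"}, "common-up"),
        ({"skin": "up", "lung": "up", "bone_marrow": "down"}, "oppositional"),
        ({"skin": "absent", "lung": "absent", "bone_marrow": "up"},
         "tissue-restricted(bone_marrow)"),
        ({"skin": "down", "lung": "down"}, "common-down"),
        ({"skin": "unchanged", "lung": "unchanged"}, "unchanged"),
    ])
    def test_pattern_labels(self, directions, expected):
        assert classify_cross_tissue(directions) == expected

    def test_needs_two_tissues(self):
        with pytest.raises(ValueError):
            classify_cross_tissue({"skin": "up"})


class TestChronicReport:
    def test_elevated_markers_flagged(self, small_study):
        truth = small_study.truth
        tumor = {t: p for (t, s), p in small_study.profiles.items() if s == "tumor"}
        control = {t: p for (t, s), p in small_study.profiles.items()
                   if s == "control"}
        report = chronic_inflammation_report(
            tumor, control, sorted(truth.tumor_markers))
        assert not report.empty
        elevated_rate = report["elevated"].mean()
        assert elevated_rate >= 0.8  # markers planted at 2 vs 8 expected peptides
        for fraction in FRACTIONS:
            assert report[f"{fraction}_intensity"].between(0, 1).all()

    def test_absent_marker_gives_dash_row(self, small_study):
        tumor = {t: p for (t, s), p in small_study.profiles.items() if s == "tumor"}
        control = {t: p for (t, s), p in small_study.profiles.items()
                   if s == "control"}
        report = chronic_inflammation_report(tumor, control, ["P99999"])
        assert (report["control_bin"] == "-").all()
        assert (report["tumor_bin"] == "-").all()
        assert (~report["elevated"]).all()
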
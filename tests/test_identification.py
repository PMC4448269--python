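"""Two-tier PSM filtering, FDR, peptide mapping and parsimony inference."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibroprof import (
    FilterThresholds,
    ProteinRecord,
    apply_evidence_rules,
    estimate_fdr,
    filter_psms,
    infer_proteins_exact,
    infer_proteins_greedy,
    map_peptides,
)


def _psm_row(score, flags=False, is_decoy=False):
    return {
        "sample_id": "s", "tissue": "skin", "state": "control", "replicate": 1,
        "fraction": "cytoplasm", "peptide": "AAAK", "score": score,
        "precursor_match": flags, "rt_match": flags, "ms2_match": flags,
        "is_decoy": is_decoy,
    }


class TestFilter:
    @pytest.mark.parametrize("score, flags, accepted", [
        (13.5, False, True),    # above 13 passes outright
        (10.0, True, True),     # rescue window with all flags
        (10.0, False, False),   # rescue window, a flag missing
        (13.0, True, True),     # boundary 13 goes through the rescue tier
        (13.0, False, False),
        (9.0, True, True),      # window is closed at both ends
        (8.9, True, False),
        (0.0, False, False),
    ])
    def test_two_tier_rule(self, score, flags, accepted):
        psms = pd.DataFrame([_psm_row(score, flags)])
        assert (len(filter_psms(psms)) == 1) is accepted

    def test_partial_flags_do_not_rescue(self):
        row = _psm_row(10.0, True)
        row["ms2_match"] = False
        assert filter_psms(pd.DataFrame([row])).empty

    def test_decoys_follow_the_same_rule(self):
        psms = pd.DataFrame([_psm_row(14.0, is_decoy=True),
                             _psm_row(5.0, is_decoy=True)])
        accepted = filter_psms(psms)
        assert accepted["is_decoy"].tolist() == [True]

    def test_empty_in_empty_out(self):
        psms = pd.DataFrame([_psm_row(10.0)]).iloc[:0]
        assert filter_psms(psms).empty

    def test_non_finite_score_rejected(self):
        with pytest.raises(ValueError):
            filter_psms(pd.DataFrame([_psm_row(float("nan"))]))

    @settings(derandomize=True, max_examples=60)
    @given(
        scores=st.lists(st.floats(0, 30, allow_nan=False), min_size=1, max_size=40),
        flagged=st.lists(st.booleans(), min_size=1, max_size=40),
        lo=st.floats(5, 20),
        hi=st.floats(0, 10),
    )
    def test_raising_threshold_never_accepts_more(self, scores, flagged, lo, hi):
        n = min(len(scores), len(flagged))
        psms = pd.DataFrame([_psm_row(s, f) for s, f in
                             zip(scores[:n], flagged[:n])])
        low = len(filter_psms(psms, FilterThresholds(accept_above=lo)))
        high = len(filter_psms(psms, FilterThresholds(accept_above=lo + hi)))
        assert high <= low


class TestFdr:
    def test_ratio_definition(self):
        accepted = pd.DataFrame({"is_decoy": [True] * 2 + [False] * 200})
        assert estimate_fdr(accepted) == pytest.approx(0.01)

    def test_no_decoys_is_zero(self):
        accepted = pd.DataFrame({"is_decoy": [False] * 10})
        assert estimate_fdr(accepted) == 0.0

    def test_no_targets_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_fdr(pd.DataFrame({"is_decoy": [True] * 3}))

    def test_alternative_estimator(self):
        accepted = pd.DataFrame({"is_decoy": [True] * 2 + [False] * 198})
        assert estimate_fdr(accepted, method="doubled") == pytest.approx(0.02)


class TestMapPeptides:
    DB = [
        ProteinRecord("P1", "first", "AAAKCCCR"),
        ProteinRecord("P2", "second", "AAAKWWWK"),
        ProteinRecord("DECOY_P1", "decoy", "RCCCKAAA", is_decoy=True),
    ]

    def test_shared_tryptic_peptide_maps_to_both(self):
        mapping, orphans = map_peptides(["AAAK", "CCCR"], self.DB[:2])
        assert mapping["AAAK"] == {"P1", "P2"}
        assert mapping["CCCR"] == {"P1"}
        assert orphans == []

    def test_decoy_peptide_maps_to_decoy_only(self):
        mapping, _ = map_peptides(["CCCK"], self.DB)
        assert mapping["CCCK"] == {"DECOY_P1"}

    def test_orphans_are_recorded_not_dropped(self):
        mapping, orphans = map_peptides(["QQQQQQ"], self.DB)
        assert mapping == {}
        assert orphans == ["QQQQQQ"]

    def test_non_tryptic_substring_does_not_match(self):
        # "AAA" occurs as a substring but is not a full tryptic peptide
        mapping, orphans = map_peptides(["AAA"], self.DB[:2])
        assert orphans == ["AAA"]


def brute_force_minimum_cover(peptide_map):
    """Independent oracle: smallest protein subset covering all peptides."""
    proteins = sorted({p for s in peptide_map.values() for p in s})
    peptides = set(peptide_map)
    best = None
    for k in range(1, len(proteins) + 1):
        for combo in itertools.combinations(proteins, k):
            covered = {pep for pep, prots in peptide_map.items()
                       if prots & set(combo)}
            if covered == peptides:
                return set(combo)
    return best


def random_instance(rng, max_proteins=8, max_peptides=16):
    n_prot = int(rng.integers(2, max_proteins + 1))
    n_pep = int(rng.integers(1, max_peptides + 1))
    proteins = [f"P{i}" for i in range(n_prot)]
    peptide_map = {}
    for j in range(n_pep):
        size = int(rng.integers(1, n_prot + 1))
        owners = rng.choice(proteins, size=size, replace=False)
        peptide_map[f"pep{j}"] = set(owners)
    return peptide_map


class TestInference:
    INSTANCE = {"a": {"P1"}, "b": {"P1", "P2"}, "c": {"P2", "P3"}}

    def test_greedy_textbook_instance(self):
        result = infer_proteins_greedy(self.INSTANCE)
        assert result.selected_proteins == {"P1", "P2"}
        assert not result.is_minimal_certified
        assert all(result.peptide_assignments[p] for p in self.INSTANCE)

    def test_single_covering_protein(self):
        result = infer_proteins_greedy({"a": {"P9"}, "b": {"P9"}})
        assert result.selected_proteins == {"P9"}

    def test_tie_breaks_lexicographically(self):
        result = infer_proteins_greedy({"a": {"PB", "PA"}, "b": {"PB", "PA"}})
        assert result.selected_proteins == {"PA"}

    def test_orphan_peptides_are_an_error(self):
        with pytest.raises(ValueError):
            infer_proteins_greedy({"a": {"P1"}, "b": set()})

    def test_exact_textbook_instance_is_certified(self):
        result = infer_proteins_exact(self.INSTANCE)
        assert len(result.selected_proteins) == 2
        assert result.is_minimal_certified

    def test_exact_disjoint_singletons_selects_all(self):
        peptide_map = {f"pep{i}": {f"P{i}"} for i in range(6)}
        result = infer_proteins_exact(peptide_map)
        assert result.selected_proteins == {f"P{i}" for i in range(6)}

    def test_exact_guards_instance_size(self):
        peptide_map = {f"pep{i}": {f"P{i:02d}"} for i in range(21)}
        with pytest.raises(ValueError, match="greedy"):
            infer_proteins_exact(peptide_map)

    def test_exact_agrees_with_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            peptide_map = random_instance(rng)
            exact = infer_proteins_exact(peptide_map)
            brute = brute_force_minimum_cover(peptide_map)
            assert len(exact.selected_proteins) == len(brute)

    def test_greedy_always_covers_and_is_near_minimal(self):
        rng = np.random.default_rng(23)
        matches = 0
        for _ in range(100):
            peptide_map = random_instance(rng, max_proteins=10, max_peptides=20)
            greedy = infer_proteins_greedy(peptide_map)
            exact = infer_proteins_exact(peptide_map)
            assert all(greedy.peptide_assignments[p] for p in peptide_map)
            assert len(greedy.selected_proteins) >= len(exact.selected_proteins)
            matches += (len(greedy.selected_proteins)
                        == len(exact.selected_proteins))
        assert matches >= 90


class TestEvidenceRules:
    def make_counts(self, data):
        return pd.DataFrame(data).T  # rows accessions, columns samples

    def test_single_peptide_rescued_by_other_sample(self):
        counts = pd.DataFrame(
            {"skin.control": {"P1": 1}, "bm.control": {"P1": 3}}
        ).fillna(0)
        retained = apply_evidence_rules(counts)
        assert "P1" in retained["skin.control"]
        assert "P1" in retained["bm.control"]

    def test_one_peptide_everywhere_removed_everywhere(self):
        counts = pd.DataFrame(
            {"s1": {"P1": 1}, "s2": {"P1": 1}, "s3": {"P1": 1}}
        )
        retained = apply_evidence_rules(counts)
        assert all("P1" not in accs for accs in retained.values())

    def test_two_peptides_retained_locally_only(self):
        counts = pd.DataFrame({"s1": {"P1": 2}, "s2": {"P1": 0}})
        retained = apply_evidence_rules(counts)
        assert retained == {"s1": {"P1"}, "s2": set()}
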
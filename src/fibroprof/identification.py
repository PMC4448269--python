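"""From raw peptide-spectrum matches to accepted protein identifications.

The acceptance logic mirrors a two-tier search-engine filter: a PSM passes
outright when its score exceeds 13, or through a rescue tier when its score
lies in [9, 13] *and* its precursor m/z, retention time and MS2 pattern all
match a previously accepted reference spectrum.  Decoy PSMs run through the
same rule so the accepted decoy/target ratio estimates the false discovery
rate.

Protein inference follows the minimal-explanation principle: report the
smallest set of proteins that explains all accepted peptides.  The greedy
set-cover heuristic is the production path; an exhaustive exact solver
(feasible up to ~20 candidate proteins) serves as a certified oracle.

Finally the two-peptide evidence rule is applied across the whole
experiment: a protein is kept in a sample when it has >= 2 distinct peptides
there, and a single-peptide identification is rescued when the same protein
reaches >= 2 distinct peptides in any other sample of the experiment set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ProteinRecord
from .quantitation import DEFAULT_DIGESTION, DigestionParams, digest_protein


@dataclass(frozen=True)
class FilterThresholds:
    """Two-tier score filter settings.

    accept_above
        Scores strictly above this pass unconditionally (default 13).
    rescue_low, rescue_high
        Closed score interval whose PSMs pass only when all three
        reference-match flags are set (default [9, 13]).  A score of exactly
        13 therefore needs the rescue flags.
    """

    accept_above: float = 13.0
    rescue_low: float = 9.0
    rescue_high: float = 13.0


@dataclass
class InferenceResult:
    """Outcome of parsimony protein inference.

    ``peptide_assignments`` maps every peptide to the selected proteins that
    contain it (always non-empty).  ``is_minimal_certified`` is True only
    when the exhaustive solver produced the result.
    """

    selected_proteins: set[str]
    peptide_assignments: dict[str, set[str]]
    is_minimal_certified: bool


def filter_psms(
    psms: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()
) -> pd.DataFrame:
    """Apply the two-tier score filter; decoys pass through the same rule."""
    scores = psms["score"].to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite PSM score")
    flags = (
        psms["precursor_match"].to_numpy(bool)
        & psms["rt_match"].to_numpy(bool)
        & psms["ms2_match"].to_numpy(bool)
    )
    accept = (scores > thresholds.accept_above) | (
        (scores >= thresholds.rescue_low)
        & (scores <= thresholds.rescue_high)
        & flags
    )
    return psms.loc[accept].reset_index(drop=True)


def estimate_fdr(accepted: pd.DataFrame, method: str = "decoy_over_target") -> float:
    """Decoy-based FDR estimate over accepted PSMs.

    ``decoy_over_target`` (default) returns D/T; ``doubled`` returns
    2D/(T+D).  Zero accepted targets is an error (ratio undefined).
    """
    n_decoy = int(accepted["is_decoy"].sum())
    n_target = int((~accepted["is_decoy"]).sum())
    if n_target == 0:
        raise ValueError("no accepted target PSMs; FDR undefined")
    if method == "decoy_over_target":
        return n_decoy / n_target
    if method == "doubled":
        return 2 * n_decoy / (n_target + n_decoy)
    raise ValueError(f"unknown FDR estimator {method!r}")


def build_peptide_index(
    database: Sequence[ProteinRecord],
    digestion: DigestionParams = DEFAULT_DIGESTION,
) -> dict[str, set[str]]:
    """Digest every database entry; map each tryptic peptide to its proteins."""
    index: dict[str, set[str]] = {}
    for record in database:
        for pep in set(digest_protein(record.sequence, digestion)):
            index.setdefault(pep, set()).add(record.accession)
    return index


def map_peptides(
    psms: pd.DataFrame | Iterable[str],
    database: Sequence[ProteinRecord],
    digestion: DigestionParams = DEFAULT_DIGESTION,
) -> tuple[dict[str, set[str]], list[str]]:
    """Map accepted peptides to the database proteins whose digest contains them.

    Returns ``(peptide_map, orphans)``.  Peptides matching no protein under
    the digestion rule are collected in the orphan list, never silently
    dropped.
    """
    if isinstance(psms, pd.DataFrame):
        peptides = sorted(set(psms["peptide"].astype(str)))
    else:
        peptides = sorted(set(psms))
    index = build_peptide_index(database, digestion)
    mapping: dict[str, set[str]] = {}
    orphans: list[str] = []
    for pep in peptides:
        hits = index.get(pep)
        if hits:
            mapping[pep] = set(hits)
        else:
            orphans.append(pep)
    return mapping, orphans


def _invert(peptide_map: Mapping[str, set[str]]) -> dict[str, set[str]]:
    for pep, prots in peptide_map.items():
        if not prots:
            raise ValueError(
                f"peptide {pep!r} has no candidate protein; "
                "route orphans to the orphan list before inference"
            )
    inverted: dict[str, set[str]] = {}
    for pep, prots in peptide_map.items():
        for acc in prots:
            inverted.setdefault(acc, set()).add(pep)
    return inverted


def _assignments(
    peptide_map: Mapping[str, set[str]], selected: set[str]
) -> dict[str, set[str]]:
    out = {pep: prots & selected for pep, prots in peptide_map.items()}
    uncovered = [pep for pep, prots in out.items() if not prots]
    assert not uncovered, f"cover misses peptides: {uncovered[:5]}"
    return out


def infer_proteins_greedy(peptide_map: Mapping[str, set[str]]) -> InferenceResult:
    """Greedy minimal-set-cover protein inference.

    Repeatedly selects the protein explaining the most still-unexplained
    peptides; ties break toward the lexicographically smaller accession.
    The result always covers every peptide.
    """
    prot_to_peps = _invert(peptide_map)
    uncovered = set(peptide_map)
    selected: set[str] = set()
    candidates = sorted(prot_to_peps)
    while uncovered:
        best_acc = None
        best_gain = 0
        for acc in candidates:
            gain = len(prot_to_peps[acc] & uncovered)
            if gain > best_gain:
                best_acc, best_gain = acc, gain
        assert best_acc is not None  # every peptide has >= 1 candidate
        selected.add(best_acc)
        uncovered -= prot_to_peps[best_acc]
    return InferenceResult(selected, _assignments(peptide_map, selected), False)


def infer_proteins_exact(
    peptide_map: Mapping[str, set[str]], max_proteins: int = 20
) -> InferenceResult:
    """Certified minimum protein cover by exhaustive subset search.

    Intended as an oracle for small instances; raises ``ValueError`` when
    more than ``max_proteins`` candidate proteins are involved (use the
    greedy path for production-size inputs).
    """
    prot_to_peps = _invert(peptide_map)
    candidates = sorted(prot_to_peps)
    if len(candidates) > max_proteins:
        raise ValueError(
            f"{len(candidates)} candidate proteins exceed max_proteins="
            f"{max_proteins}; use infer_proteins_greedy"
        )
    all_peptides = set(peptide_map)
    for k in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            covered: set[str] = set()
            for acc in combo:
                covered |= prot_to_peps[acc]
            if covered >= all_peptides:
                selected = set(combo)
                return InferenceResult(
                    selected, _assignments(peptide_map, selected), True
                )
    raise AssertionError("unreachable: full candidate set always covers")


def apply_evidence_rules(counts: pd.DataFrame) -> dict[str, set[str]]:
    """Two-peptide rule with cross-sample single-peptide rescue.

    Parameters
    ----------
    counts
        DataFrame of per-sample total distinct-peptide counts, indexed by
        accession with one column per sample (zeros for non-detection).

    Returns accession sets retained per sample: a protein is kept in sample
    S iff it has >= 2 distinct peptides in S, or exactly 1 in S while
    reaching >= 2 in at least one other sample of the experiment.  Proteins
    never reaching 2 peptides anywhere vanish everywhere.
    """
    arr = counts.to_numpy(dtype=float)
    retained: dict[str, set[str]] = {}
    for j, sample in enumerate(counts.columns):
        here = arr[:, j]
        if arr.shape[1] > 1:
            elsewhere = np.delete(arr, j, axis=1).max(axis=1)
        else:
            elsewhere = np.zeros(arr.shape[0])
        keep = (here >= 2) | ((here == 1) & (elsewhere >= 2))
        retained[str(sample)] = set(counts.index[keep])
    return retained
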
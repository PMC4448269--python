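"""Cross-tissue and cross-state comparison of proteome profiles.

Tissue signatures rest on presence/absence logic over the combined profiles
of all states of a tissue: a protein detected in exactly one tissue is
*exclusive* to it; a protein detected in two tissues but absent from the
third belongs to the *shared-pair* signature of those two.  Both classes are
reported separately — shared entries are never forced into a single-tissue
partition.

Differential regulation between a control and a treated (IL-1beta or
tumor-associated) state is called per sub-cellular fraction by comparing
semi-quantitative bins, with a 1-df goodness-of-fit chi-squared test on the
two replicate-mean distinct-peptide counts (equal expected counts, no
continuity correction) supplying the significance level (p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2

from .io_formats import FRACTIONS
from .quantitation import AMBIGUOUS_BIN, bin_abundance, bin_rank, color_intensity

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TissueStateProfile:
    """A proteome profile of one cell type in one functional state."""

    tissue: str
    state: str
    table: pd.DataFrame  # as produced by quantitation.build_profile_table


@dataclass(frozen=True)
class SignatureEntry:
    """A protein assigned to a tissue signature.

    ``signature_class`` is ``"exclusive"`` (one tissue) or ``"shared"``
    (a tissue pair, with the absent third tissue recorded).  ``bins`` holds
    the rendered display bin per (tissue, state), ``"-"`` where undetected.
    """

    accession: str
    signature_class: str
    tissues: tuple[str, ...]
    absent_tissues: tuple[str, ...]
    bins: Mapping[tuple[str, str], str]


def _tables(profiles: Mapping[tuple[str, str], object]) -> dict[tuple[str, str], pd.DataFrame]:
    out = {}
    for key, prof in profiles.items():
        out[key] = prof.table if isinstance(prof, TissueStateProfile) else prof
    return out


def derive_tissue_signatures(
    profiles: Mapping[tuple[str, str], "TissueStateProfile | pd.DataFrame"],
) -> list[SignatureEntry]:
    """Presence/absence signature derivation over all states of each tissue.

    ``profiles`` is keyed by (tissue, state).  A protein counts as detected
    in a tissue when its total distinct-peptide count is >= 1 in any state
    of that tissue (an ambiguous ``(+)`` detection still counts).  Requires
    profiles from at least two tissues.
    """
    tables = _tables(profiles)
    tissues = sorted({t for t, _ in tables})
    if len(tissues) < 2:
        raise ValueError("need profiles from at least two tissues to contrast")
    detected: dict[str, set[str]] = {t: set() for t in tissues}
    bins: dict[str, dict[tuple[str, str], str]] = {}
    for (tissue, state), table in tables.items():
        for _, row in table.iterrows():
            if row["peptides"] >= 1:
                detected[tissue].add(row["accession"])
            bins.setdefault(row["accession"], {})[(tissue, state)] = (
                row["display_bin"] if "display_bin" in row else
                bin_abundance(int(row["peptides"]))
            )
    entries: list[SignatureEntry] = []
    all_accessions = sorted(set().union(*detected.values()))
    for acc in all_accessions:
        present = tuple(t for t in tissues if acc in detected[t])
        absent = tuple(t for t in tissues if acc not in detected[t])
        if len(present) == 1:
            cls = "exclusive"
        elif len(present) == 2 and len(tissues) >= 3:
            cls = "shared"
        else:
            continue
        entries.append(SignatureEntry(
            accession=acc, signature_class=cls,
            tissues=present, absent_tissues=absent,
            bins=dict(sorted(bins.get(acc, {}).items())),
        ))
    entries.sort(key=lambda e: (e.signature_class, e.tissues, e.accession))
    return entries


def signatures_to_frame(entries: Sequence[SignatureEntry]) -> pd.DataFrame:
    """Flatten signature entries for the report TSV."""
    rows = []
    for e in entries:
        row = {
            "accession": e.accession,
            "signature_class": e.signature_class,
            "tissues": "+".join(e.tissues),
            "absent_tissues": "+".join(e.absent_tissues),
        }
        for (tissue, state), symbol in e.bins.items():
            row[f"bin_{tissue}_{state}"] = symbol
        rows.append(row)
    return pd.DataFrame(rows)


def chi_squared_counts(
    mean_control_count: float, mean_treated_count: float
) -> tuple[float, float]:
    """1-df goodness-of-fit chi-squared on two mean spectral counts.

    Expected count for each cell is the pooled mean (c + t) / 2; the
    statistic is ``(c-e)**2/e + (t-e)**2/e`` with no continuity correction,
    and the p-value comes from the chi-squared(1) survival function.
    """
    c, t = float(mean_control_count), float(mean_treated_count)
    if c < 0 or t < 0:
        raise ValueError("mean counts must be >= 0")
    if c == 0 and t == 0:
        raise ValueError("chi-squared undefined when both counts are zero")
    e = (c + t) / 2.0
    stat = (c - e) ** 2 / e + (t - e) ** 2 / e
    return stat, float(_chi2.sf(stat, df=1))


def call_differential(
    control: TissueStateProfile,
    treated: TissueStateProfile,
    fraction: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein regulation calls between two states of one cell type.

    Direction comes from comparing the fraction's distinct-peptide-count
    bins (bin order ``- < + < ++ < +++ < ++++``); the chi-squared test runs
    on the unrounded replicate-mean counts.  Proteins undetected in the
    fraction on both sides are omitted.  Ambiguous ``(+)`` detections on
    either side set ``low_confidence``.
    """
    if control.tissue != treated.tissue:
        raise ValueError(
            f"profiles are from different cell types: "
            f"{control.tissue!r} vs {treated.tissue!r}"
        )
    if fraction not in FRACTIONS:
        raise ValueError(f"unknown fraction {fraction!r}")
    cols = ["accession", "name", fraction, f"{fraction}_mean", "robustness"]
    left = control.table[cols].set_index("accession")
    right = treated.table[cols].set_index("accession")
    accessions = sorted(set(left.index) | set(right.index))
    rows = []
    for acc in accessions:
        c_count = int(left[fraction].get(acc, 0))
        t_count = int(right[fraction].get(acc, 0))
        if c_count == 0 and t_count == 0:
            continue
        c_mean = float(left[f"{fraction}_mean"].get(acc, 0.0))
        t_mean = float(right[f"{fraction}_mean"].get(acc, 0.0))
        c_bin = bin_abundance(c_count)
        t_bin = bin_abundance(t_count)
        delta = bin_rank(t_bin) - bin_rank(c_bin)
        direction = "up" if delta > 0 else "down" if delta < 0 else "unchanged"
        stat, p = chi_squared_counts(c_mean, t_mean)
        low_confidence = (
            str(left["robustness"].get(acc, "absent")) == "ambiguous"
            or str(right["robustness"].get(acc, "absent")) == "ambiguous"
        )
        name = left["name"].get(acc, None)
        if not isinstance(name, str) or not name:
            name = str(right["name"].get(acc, ""))
        rows.append({
            "accession": acc, "name": name, "fraction": fraction,
            "control_bin": c_bin, "treated_bin": t_bin,
            "mean_control_count": c_mean, "mean_treated_count": t_mean,
            "direction": direction,
            "chi2_statistic": stat, "p_value": p,
            "significant": bool(p < alpha),
            "low_confidence": low_confidence,
        })
    return pd.DataFrame(rows, columns=[
        "accession", "name", "fraction", "control_bin", "treated_bin",
        "mean_control_count", "mean_treated_count", "direction",
        "chi2_statistic", "p_value", "significant", "low_confidence",
    ])


def classify_cross_tissue(directions: Mapping[str, str]) -> str:
    """Label a protein's regulation pattern across tissues.

    ``directions`` maps tissue -> one of up/down/unchanged/absent.  Both an
    up and a down call make the pattern *oppositional*; regulation confined
    to a proper subset of tissues is *tissue-restricted* (the subset is
    listed); uniform regulation across every tissue is *common-up* /
    *common-down*; otherwise *unchanged*.
    """
    if len(directions) < 2:
        raise ValueError("need calls from at least two tissues")
    ups = sorted(t for t, d in directions.items() if d == "up")
    downs = sorted(t for t, d in directions.items() if d == "down")
    if ups and downs:
        return "oppositional"
    if ups:
        if len(ups) == len(directions):
            return "common-up"
        return f"tissue-restricted({'+'.join(ups)})"
    if downs:
        if len(downs) == len(directions):
            return "common-down"
        return f"tissue-restricted({'+'.join(downs)})"
    return "unchanged"


def chronic_inflammation_report(
    tumor_profiles: Mapping[str, "TissueStateProfile | pd.DataFrame"],
    control_profiles: Mapping[str, "TissueStateProfile | pd.DataFrame"],
    markers: Sequence[str],
    empai_scale_max: float = 9.0,
) -> pd.DataFrame:
    """Project chronic-inflammation candidate markers across cell types.

    For each marker accession and each tissue with both a control and a
    tumor-associated profile, reports the display bins, per-fraction tumor
    emPAI color intensities and whether the marker is elevated (tumor bin
    strictly above control bin).  A marker absent everywhere is logged as a
    warning and reported as a row of ``-``.  No new statistics are computed.
    """
    tumor = {t: (p.table if isinstance(p, TissueStateProfile) else p)
             for t, p in tumor_profiles.items()}
    control = {t: (p.table if isinstance(p, TissueStateProfile) else p)
               for t, p in control_profiles.items()}
    tissues = sorted(set(tumor) & set(control))
    rows = []
    for marker in markers:
        seen_anywhere = False
        for tissue in tissues:
            t_tab = tumor[tissue].set_index("accession")
            c_tab = control[tissue].set_index("accession")
            in_t, in_c = marker in t_tab.index, marker in c_tab.index
            seen_anywhere |= in_t or in_c
            c_bin = str(c_tab.loc[marker, "display_bin"]) if in_c else "-"
            t_bin = str(t_tab.loc[marker, "display_bin"]) if in_t else "-"
            c_count = int(c_tab.loc[marker, "peptides"]) if in_c else 0
            t_count = int(t_tab.loc[marker, "peptides"]) if in_t else 0
            row = {
                "accession": marker, "tissue": tissue,
                "control_bin": c_bin, "tumor_bin": t_bin,
                "elevated": bin_rank(bin_abundance(t_count))
                > bin_rank(bin_abundance(c_count)),
            }
            for fraction in FRACTIONS:
                empai = (
                    float(t_tab.loc[marker, f"{fraction}_empai"]) if in_t else 0.0
                )
                if not np.isfinite(empai):
                    empai = 0.0
                row[f"{fraction}_intensity"] = color_intensity(empai, empai_scale_max)
            rows.append(row)
        if not seen_anywhere:
            log.warning("marker %s not detected in any profile", marker)
    return pd.DataFrame(rows, columns=[
        "accession", "tissue", "control_bin", "tumor_bin", "elevated",
        *[f"{f}_intensity" for f in FRACTIONS],
    ])
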
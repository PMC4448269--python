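"""Semi-quantitative protein abundance from spectral counting.

Two complementary measures are computed for every identified protein:

* the number of *distinct* peptide sequences identified per protein
  (spectral multiplicity and charge states collapse to one), per
  sub-cellular fraction and combined across fractions; and
* the emPAI, the exponentially modified protein abundance index,
  ``10**(N_observed / N_observable) - 1``, where ``N_observable`` counts the
  protein's fully tryptic peptides whose monoisotopic mass falls inside the
  instrument-detectable window (500–4500 Da by default).

Counts are additionally mapped to the semi-quantitative bins used in
presence/absence comparisons: ``-`` (not detected), ``+`` (one peptide),
``++`` (2–5), ``+++`` (6–14), ``++++`` (>= 15).  A protein detected in some
but not all replicates of a cell state is flagged ambiguous and rendered
``(+)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

from .io_formats import FRACTIONS, STANDARD_RESIDUES

#: Monoisotopic mass of water, added once per peptide.
WATER_MONO = 18.010565

#: Carbamidomethylation of cysteine (iodoacetamide alkylation), Da.
CARBAMIDOMETHYL = 57.02146

#: Bin symbols in increasing abundance order.
BIN_ORDER = ("-", "+", "++", "+++", "++++")
AMBIGUOUS_BIN = "(+)"

_BIN_RANK = {symbol: i for i, symbol in enumerate(BIN_ORDER)}


@dataclass(frozen=True)
class DigestionParams:
    """In-silico trypsin digestion and observability settings.

    missed_cleavages
        Number of allowed missed cleavage sites (0 reproduces the classic
        emPAI observable-peptide count).
    fixed_modifications
        Residue -> monoisotopic mass delta (Da); default carbamidomethyl-C,
        matching iodoacetamide alkylation in the bench protocol.
    mass_range
        Closed [low, high] monoisotopic-mass window (Da) a peptide must fall
        in to count as observable.
    """

    missed_cleavages: int = 0
    fixed_modifications: Mapping[str, float] = field(
        default_factory=lambda: {"C": CARBAMIDOMETHYL}
    )
    mass_range: tuple[float, float] = (500.0, 4500.0)

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        low, high = self.mass_range
        if not (low < high):
            raise ValueError(f"mass range lower bound must be < upper: {self.mass_range}")
        for res, delta in self.fixed_modifications.items():
            if not math.isfinite(delta):
                raise ValueError(f"non-finite modification delta for {res!r}")


DEFAULT_DIGESTION = DigestionParams()


@dataclass(frozen=True)
class EmpaiResult:
    """emPAI for one protein: observed/observable peptide counts, PAI, emPAI."""

    n_observed: int
    n_observable: int
    pai: float
    empai: float


@dataclass(frozen=True)
class ReplicateSummary:
    """Replicate aggregation: mean distinct-peptide count and detection status.

    ``status`` is ``"robust"`` (detected in every replicate), ``"ambiguous"``
    (detected in some but not all — rendered ``(+)``) or ``"absent"``.
    """

    mean: float
    status: str


def digest_protein(
    sequence: str, params: DigestionParams = DEFAULT_DIGESTION
) -> list[str]:
    """Tryptic digest: cleave C-terminal of K/R unless followed by P.

    Returns peptides ordered by start position (then by length when missed
    cleavages are allowed).  With ``missed_cleavages == 0`` the returned
    peptides partition the sequence: their concatenation equals the input.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"illegal residue(s): {''.join(sorted(bad))}")
    cuts = [0]
    last = len(seq) - 1
    for i, aa in enumerate(seq):
        if aa in "KR" and i != last and seq[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(seq))
    base = [seq[cuts[i]: cuts[i + 1]] for i in range(len(cuts) - 1)]
    mc = params.missed_cleavages
    peptides: list[str] = []
    for i in range(len(base)):
        for j in range(i, min(i + mc + 1, len(base))):
            peptides.append("".join(base[i: j + 1]))
    return peptides


def peptide_mass(
    peptide: str, params: DigestionParams = DEFAULT_DIGESTION
) -> float:
    """Monoisotopic peptide mass (Da) including water and fixed modifications."""
    if not peptide:
        raise ValueError("empty peptide")
    bad = set(peptide) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"unknown residue(s): {''.join(sorted(bad))}")
    m = float(_ptmass.fast_mass(peptide))
    for res, delta in params.fixed_modifications.items():
        m += peptide.count(res) * delta
    return m


def count_observable_peptides(
    sequence: str, params: DigestionParams = DEFAULT_DIGESTION
) -> int:
    """Number of distinct digest peptides with mass inside the closed window."""
    low, high = params.mass_range
    return sum(
        1 for pep in set(digest_protein(sequence, params))
        if low <= peptide_mass(pep, params) <= high
    )


def observable_peptides(
    sequence: str, params: DigestionParams = DEFAULT_DIGESTION
) -> list[str]:
    """Sorted distinct digest peptides inside the detectable mass window."""
    low, high = params.mass_range
    return sorted(
        pep for pep in set(digest_protein(sequence, params))
        if low <= peptide_mass(pep, params) <= high
    )


def compute_empai(n_observed: int, n_observable: int) -> EmpaiResult:
    """emPAI = 10**(N_observed / N_observable) - 1.

    Raises ``ValueError`` when ``n_observable`` is zero (the protein has no
    peptide in the detectable window and is unquantifiable).
    """
    if n_observable < 1:
        raise ValueError("protein has no observable peptide; emPAI undefined")
    if n_observed < 0:
        raise ValueError("n_observed must be >= 0")
    pai = n_observed / n_observable
    return EmpaiResult(n_observed, n_observable, pai, 10.0 ** pai - 1.0)


def count_distinct_peptides(assigned_psms: pd.DataFrame) -> pd.DataFrame:
    """Distinct-peptide counts per (accession, sample, fraction).

    ``assigned_psms`` must carry an ``accession`` column (peptide-to-protein
    assignment already resolved).  Repeated spectra of one peptide count
    once.
    """
    if assigned_psms.empty:
        return pd.DataFrame(columns=["accession", "sample_id", "fraction", "peptides"])
    out = (
        assigned_psms.groupby(["accession", "sample_id", "fraction"], sort=True)
        ["peptide"].nunique().reset_index(name="peptides")
    )
    return out


def combine_fractions(peptide_sets: Mapping[str, Iterable[str]]) -> int:
    """Total distinct peptides across fractions: size of the set union."""
    union: set[str] = set()
    for peps in peptide_sets.values():
        union |= set(peps)
    return len(union)


def aggregate_replicates(counts: Sequence[float]) -> ReplicateSummary:
    """Mean distinct-peptide count over replicates plus a robustness flag.

    Zeros (non-detections) are included in the mean.  Detection in every
    replicate is robust; detection in only some replicates is ambiguous.
    """
    if len(counts) == 0:
        raise ValueError("need at least one replicate")
    detected = [c >= 1 for c in counts]
    if all(detected):
        status = "robust"
    elif any(detected):
        status = "ambiguous"
    else:
        status = "absent"
    return ReplicateSummary(float(np.mean(counts)), status)


def bin_abundance(count: int) -> str:
    """Map a total distinct-peptide count to its semi-quantitative bin."""
    c = int(count)
    if c != count:
        raise ValueError(f"count must be integral, got {count!r}")
    if c < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    if c == 0:
        return "-"
    if c == 1:
        return "+"
    if c <= 5:
        return "++"
    if c <= 14:
        return "+++"
    return "++++"


def bin_rank(symbol: str) -> int:
    """Position of a bin symbol in the abundance order (- < + < ++ < +++ < ++++)."""
    try:
        return _BIN_RANK[symbol]
    except KeyError:
        raise ValueError(f"not an orderable bin symbol: {symbol!r}") from None


def color_intensity(empai: float, scale_max: float) -> float:
    """Linear emPAI-to-color-intensity map, clipped to [0, 1]."""
    if scale_max <= 0:
        raise ValueError("scale_max must be > 0")
    if empai < 0:
        raise ValueError("empai must be >= 0")
    return min(empai / scale_max, 1.0)


def build_profile_table(
    peptide_sets: Mapping[str, Mapping[int, Mapping[str, set]]],
    names: Mapping[str, str],
    n_observable: Mapping[str, int],
    replicates: Sequence[int],
) -> pd.DataFrame:
    """Assemble a per-cell-state proteome profile from per-replicate peptide sets.

    Parameters
    ----------
    peptide_sets
        accession -> replicate -> fraction -> set of distinct peptides.
    names
        accession -> protein name.
    n_observable
        accession -> observable (in-mass-window) tryptic peptide count.
    replicates
        All replicate labels of the cell state; replicates with no entry
        contribute zeros to means and break robustness.

    Returns a DataFrame sorted by accession with per-fraction union counts,
    replicate-mean counts and mean emPAI, the combined total, the replicate
    robustness flag, the count bin and the rendered display bin (``(+)``
    when ambiguous).
    """
    if not replicates:
        raise ValueError("need at least one replicate label")
    rows = []
    for accession in sorted(peptide_sets):
        by_rep = peptide_sets[accession]
        row: dict = {"accession": accession, "name": names.get(accession, "")}
        rep_totals = []
        union_all: set = set()
        for fraction in FRACTIONS:
            frac_union: set = set()
            frac_counts = []
            frac_empai = []
            for rep in replicates:
                peps = set(by_rep.get(rep, {}).get(fraction, ()))
                frac_union |= peps
                frac_counts.append(len(peps))
                if n_observable.get(accession, 0) >= 1:
                    frac_empai.append(
                        compute_empai(len(peps), n_observable[accession]).empai
                    )
            row[fraction] = len(frac_union)
            row[f"{fraction}_mean"] = float(np.mean(frac_counts))
            row[f"{fraction}_empai"] = (
                float(np.mean(frac_empai)) if frac_empai else float("nan")
            )
            union_all |= frac_union
        for rep in replicates:
            per_fraction = by_rep.get(rep, {})
            rep_totals.append(combine_fractions(per_fraction))
        summary = aggregate_replicates(rep_totals)
        row["peptides"] = len(union_all)
        row["mean_peptides"] = summary.mean
        row["robustness"] = summary.status
        row["bin"] = bin_abundance(len(union_all))
        row["display_bin"] = (
            AMBIGUOUS_BIN if summary.status == "ambiguous" else row["bin"]
        )
        rows.append(row)
    columns = (
        ["accession", "name", *FRACTIONS, "peptides"]
        + [f"{f}_mean" for f in FRACTIONS]
        + [f"{f}_empai" for f in FRACTIONS]
        + ["mean_peptides", "robustness", "bin", "display_bin"]
    )
    return pd.DataFrame(rows, columns=columns)
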
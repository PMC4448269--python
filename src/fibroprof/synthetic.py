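"""Synthetic protein databases, experiment designs and PSM tables with
planted ground truth.

The generator emulates the statistical structure of a comparative fibroblast
profiling study — three tissue origins (skin, lung, bone marrow), three
functional states (control, IL-1beta-activated, tumor-associated), three
sub-cellular fractions and at least three biological replicates — so that
every downstream stage (filtering, FDR, inference, quantitation, signature
and differential calling) can be tested against known truth without any raw
LC-MS/MS data.

Planted structure:

* tissue-exclusive proteins (expressed only in one tissue, all states),
* shared-pair proteins (two tissues, absent from the third),
* a common core expressed everywhere (the shared fibroblast machinery),
* inflammation-induced secretome proteins (expressed only in the IL-1beta
  state of their tissue, never in control supernatants),
* tumor markers (elevated in the tumor state of every tissue), and
* background proteins present in all samples at modest abundance.

Per sample, the number of distinct peptides drawn for an expressed protein
is Poisson around its planted expectation, truncated at the protein's total
of observable tryptic peptides; one PSM is emitted per drawn peptide with a
score from the target score distribution.  Decoy PSMs are drawn from
reversed-sequence entries with scores from the decoy distribution.  All
randomness flows from a single integer seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import DECOY_PREFIX, FRACTIONS, PSM_COLUMNS, ProteinRecord
from .quantitation import DEFAULT_DIGESTION, DigestionParams, observable_peptides

_AMINO_ACIDS = sorted("ACDEFGHIKLMNPQRSTVWY")
#: K and R together make up 12% of residues, guaranteeing tryptic sites.
_KR_FREQUENCY = 0.12


@dataclass(frozen=True)
class SampleKey:
    """One biological sample: (tissue, state, replicate)."""

    tissue: str
    state: str
    replicate: int

    @property
    def sample_id(self) -> str:
        return f"{self.tissue}.{self.state}.r{self.replicate}"


@dataclass(frozen=True)
class SimulationParams:
    """Everything the generator needs; the seed fully determines all output."""

    n_proteins: int = 400
    protein_length_range: tuple[int, int] = (150, 400)
    tissues: tuple[str, ...] = ("bone_marrow", "lung", "skin")
    states: tuple[str, ...] = ("control", "il1b", "tumor")
    fractions: tuple[str, ...] = FRACTIONS
    n_replicates: int = 3
    # planted set sizes
    n_exclusive_per_tissue: int = 20
    n_shared_per_pair: int = 10
    n_core: int = 30
    n_induced_per_tissue: int = 10
    n_tumor_markers: int = 5
    n_background: int = 100
    # expected distinct-peptide counts (Poisson means)
    planted_expected_peptides: int = 8
    core_expected_peptides: int = 6
    tumor_marker_expected: tuple[int, int] = (2, 8)  # (non-tumor, tumor)
    background_expected_range: tuple[int, int] = (2, 8)
    # score model
    target_score_distribution: tuple = ("normal", 20.0, 3.0)
    decoy_score_distribution: tuple = ("normal", 5.0, 2.0)
    reference_match_probability: float = 0.8
    decoy_reference_match_probability: float = 0.01
    decoy_psms_per_sample: int = 60
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        low, high = self.protein_length_range
        if low < 1 or high < low:
            raise ValueError(f"invalid protein length range: {self.protein_length_range}")
        if self.n_replicates < 3:
            raise ValueError("designs use at least three independent replicates")
        for p in (self.reference_match_probability, self.decoy_reference_match_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("reference-match probabilities must lie in [0, 1]")

    def design(self) -> list[SampleKey]:
        """All samples of the tissue x state x replicate design, in order."""
        return [
            SampleKey(t, s, r)
            for t in self.tissues
            for s in self.states
            for r in range(1, self.n_replicates + 1)
        ]


@dataclass
class GroundTruth:
    """Planted truth for one simulated experiment.

    ``per_sample_abundance`` maps (accession, sample) to the expected
    distinct-peptide count; pairs absent from the map have expectation 0.
    ``home_fraction`` records the sub-cellular fraction each planted protein
    is emitted in (induced proteins always live in the secretome).
    """

    tissue_exclusive: dict[str, frozenset[str]]
    shared_pairs: dict[tuple[str, str], frozenset[str]]
    core: frozenset[str]
    inflammation_induced: dict[str, frozenset[str]]
    tumor_markers: frozenset[str]
    background: frozenset[str]
    home_fraction: dict[str, str]
    per_sample_abundance: dict[tuple[str, SampleKey], int]

    def expected_count(self, accession: str, sample: SampleKey) -> int:
        return self.per_sample_abundance.get((accession, sample), 0)

    def planted_accessions(self) -> set[str]:
        out: set[str] = set(self.core) | set(self.tumor_markers) | set(self.background)
        for s in self.tissue_exclusive.values():
            out |= s
        for s in self.shared_pairs.values():
            out |= s
        for s in self.inflammation_induced.values():
            out |= s
        return out


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    # independent streams per stage, all rooted at the single user seed
    return np.random.default_rng([stream, params.seed])


def generate_protein_database(params: SimulationParams) -> list[ProteinRecord]:
    """Random protein database over the 20 standard residues.

    K/R are enriched to 12% combined so that every realistic-length sequence
    carries internal tryptic cleavage sites; the other 18 residues are
    uniform.  Accessions are unique and deterministic under the seed.
    """
    rng = _rng(params, 1)
    weights = np.array([
        _KR_FREQUENCY / 2 if aa in "KR" else (1 - _KR_FREQUENCY) / 18
        for aa in _AMINO_ACIDS
    ])
    low, high = params.protein_length_range
    records = []
    for i in range(params.n_proteins):
        length = int(rng.integers(low, high + 1))
        seq = "".join(rng.choice(_AMINO_ACIDS, size=length, p=weights))
        records.append(ProteinRecord(
            accession=f"P{i + 1:05d}",
            name=f"synthetic protein {i + 1}",
            sequence=seq,
        ))
    return records


def make_decoy_database(proteins: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """One reversed-sequence decoy per target, accession-tagged ``DECOY_``."""
    if not proteins:
        raise ValueError("empty target database")
    if any(p.is_decoy for p in proteins):
        raise ValueError("refusing to build decoys of decoys")
    return [
        ProteinRecord(
            accession=DECOY_PREFIX + p.accession,
            name=f"decoy of {p.accession}",
            sequence=p.sequence[::-1],
            is_decoy=True,
        )
        for p in proteins
    ]


def plant_ground_truth(
    proteins: Sequence[ProteinRecord],
    design: Sequence[SampleKey],
    params: SimulationParams,
) -> GroundTruth:
    """Partition the database into the planted sets and build the abundance map.

    The planted sets are pairwise disjoint by construction.  Core proteins
    get expected counts >= 2 in every sample; inflammation-induced proteins
    get expected secretome counts >= 2 in the IL-1beta state and exactly 0
    in control (and tumor) states.
    """
    if any(p.is_decoy for p in proteins):
        raise ValueError("ground truth is planted in the target database only")
    tissues = sorted(params.tissues)
    pairs = list(itertools.combinations(tissues, 2))
    need = (
        len(tissues) * params.n_exclusive_per_tissue
        + len(pairs) * params.n_shared_per_pair
        + params.n_core
        + len(tissues) * params.n_induced_per_tissue
        + params.n_tumor_markers
        + params.n_background
    )
    if need > len(proteins):
        raise ValueError(
            f"planted sets need {need} proteins but database has {len(proteins)}"
        )
    rng = _rng(params, 2)
    accessions = [p.accession for p in proteins]
    order = list(rng.permutation(len(accessions)))
    pool = iter(accessions[i] for i in order)

    def take(n: int) -> frozenset[str]:
        return frozenset(itertools.islice(pool, n))

    exclusive = {t: take(params.n_exclusive_per_tissue) for t in tissues}
    shared = {pair: take(params.n_shared_per_pair) for pair in pairs}
    core = take(params.n_core)
    induced = {t: take(params.n_induced_per_tissue) for t in tissues}
    markers = take(params.n_tumor_markers)
    background = take(params.n_background)

    home_fraction: dict[str, str] = {}
    cycle = itertools.cycle(params.fractions)
    for acc in sorted(
        set().union(*exclusive.values(), *shared.values(), core, background)
    ):
        home_fraction[acc] = next(cycle)
    for acc in sorted(set().union(*induced.values()) | markers):
        home_fraction[acc] = "secretome"

    lam = params.planted_expected_peptides
    abundance: dict[tuple[str, SampleKey], int] = {}
    bg_lambda = {
        acc: int(rng.integers(params.background_expected_range[0],
                              params.background_expected_range[1] + 1))
        for acc in sorted(background)
    }
    for sample in design:
        for acc in sorted(exclusive.get(sample.tissue, ())):
            abundance[(acc, sample)] = lam
        for (t1, t2), accs in shared.items():
            if sample.tissue in (t1, t2):
                for acc in sorted(accs):
                    abundance[(acc, sample)] = lam
        for acc in sorted(core):
            abundance[(acc, sample)] = params.core_expected_peptides
        if sample.state == "il1b":
            for acc in sorted(induced.get(sample.tissue, ())):
                abundance[(acc, sample)] = lam
        marker_lam = (
            params.tumor_marker_expected[1]
            if sample.state == "tumor"
            else params.tumor_marker_expected[0]
        )
        for acc in sorted(markers):
            abundance[(acc, sample)] = marker_lam
        for acc, bl in bg_lambda.items():
            abundance[(acc, sample)] = bl

    return GroundTruth(
        tissue_exclusive=exclusive,
        shared_pairs=shared,
        core=core,
        inflammation_induced=induced,
        tumor_markers=markers,
        background=background,
        home_fraction=home_fraction,
        per_sample_abundance=abundance,
    )


def _draw_score(dist: tuple, rng: np.random.Generator) -> float:
    name = dist[0]
    if name == "normal":
        mu, sigma = dist[1], dist[2]
        return round(max(float(rng.normal(mu, sigma)), 0.0), 4)
    raise ValueError(f"unknown score distribution {name!r}")


def simulate_psms(
    proteins: Sequence[ProteinRecord],
    decoys: Sequence[ProteinRecord],
    truth: GroundTruth,
    params: SimulationParams,
    digestion: DigestionParams = DEFAULT_DIGESTION,
) -> pd.DataFrame:
    """Draw the PSM table for the whole design.

    For each sample and each expressed protein, a Poisson number of distinct
    observable tryptic peptides (truncated at the protein's observable-
    peptide total) is sampled without replacement; one PSM is emitted per
    peptide.  The three reference-match flags are set jointly (one Bernoulli
    event) for PSMs scoring in the rescue window [9, 13].  Decoy PSMs come
    from reversed sequences with the decoy score model.  Output is
    deterministic under the seed.
    """
    design = params.design()
    if not design:
        raise ValueError("empty experiment design")
    known = {p.accession for p in proteins}
    unknown = {acc for acc, _ in truth.per_sample_abundance} - known
    if unknown:
        raise ValueError(f"ground truth references unknown accessions: {sorted(unknown)[:5]}")

    obs: dict[str, list[str]] = {
        p.accession: observable_peptides(p.sequence, digestion) for p in proteins
    }
    decoy_pool = sorted(
        (d.accession, pep)
        for d in decoys
        for pep in observable_peptides(d.sequence, digestion)
    )
    rng = _rng(params, 3)
    rows: list[tuple] = []

    def flags(score: float, p_match: float) -> bool:
        if 9.0 <= score <= 13.0:
            return bool(rng.random() < p_match)
        return False

    for sample in design:
        expressed = sorted(
            acc for (acc, s), lam in truth.per_sample_abundance.items()
            if s == sample and lam > 0
        )
        for acc in expressed:
            peptides = obs[acc]
            if not peptides:
                continue
            lam = truth.per_sample_abundance[(acc, sample)]
            k = min(int(rng.poisson(lam)), len(peptides))
            if k == 0:
                continue
            chosen = rng.choice(peptides, size=k, replace=False)
            fraction = truth.home_fraction.get(acc, params.fractions[0])
            for pep in chosen:
                score = _draw_score(params.target_score_distribution, rng)
                joint = flags(score, params.reference_match_probability)
                rows.append((
                    sample.sample_id, sample.tissue, sample.state,
                    sample.replicate, fraction, str(pep), score,
                    joint, joint, joint, False,
                ))
        if decoy_pool:
            for _ in range(params.decoy_psms_per_sample):
                acc, pep = decoy_pool[int(rng.integers(len(decoy_pool)))]
                fraction = params.fractions[int(rng.integers(len(params.fractions)))]
                score = _draw_score(params.decoy_score_distribution, rng)
                joint = flags(score, params.decoy_reference_match_probability)
                rows.append((
                    sample.sample_id, sample.tissue, sample.state,
                    sample.replicate, fraction, pep, score,
                    joint, joint, joint, True,
                ))
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


def simulate_score_filter_table(
    n_targets: int,
    n_decoys: int,
    params: SimulationParams,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score/flag-only PSM table for filter and FDR studies.

    Draws ``n_targets`` target and ``n_decoys`` decoy PSMs from the score
    distributions in ``params``; reference-match flags are set jointly with
    the respective match probability for scores inside the rescue window.
    Peptide and sample labels are placeholders — only scores, flags and the
    decoy label matter here.
    """
    rng = np.random.default_rng([4, params.seed if seed is None else seed])
    frames = []
    for n, dist, p_match, is_decoy in (
        (n_targets, params.target_score_distribution,
         params.reference_match_probability, False),
        (n_decoys, params.decoy_score_distribution,
         params.decoy_reference_match_probability, True),
    ):
        name, mu, sigma = dist
        if name != "normal":
            raise ValueError(f"unknown score distribution {name!r}")
        scores = np.round(np.clip(rng.normal(mu, sigma, n), 0.0, None), 4)
        joint = (scores >= 9.0) & (scores <= 13.0) & (rng.random(n) < p_match)
        frames.append(pd.DataFrame({
            "sample_id": "sim.sim.r1", "tissue": "sim", "state": "sim",
            "replicate": 1, "fraction": "cytoplasm",
            "peptide": "SIMPEPTIDEK", "score": scores,
            "precursor_match": joint, "rt_match": joint, "ms2_match": joint,
            "is_decoy": is_decoy,
        }))
    return pd.concat(frames, ignore_index=True)[PSM_COLUMNS]


# ---------------------------------------------------------------------------
# Ground-truth serialization (plain-text key-value lines, for test harnesses)
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize planted truth as sorted tab-separated key-value lines."""
    lines: list[str] = []
    for tissue in sorted(truth.tissue_exclusive):
        for acc in sorted(truth.tissue_exclusive[tissue]):
            lines.append(f"exclusive\t{tissue}\t{acc}")
    for pair in sorted(truth.shared_pairs):
        for acc in sorted(truth.shared_pairs[pair]):
            lines.append(f"shared\t{pair[0]}|{pair[1]}\t{acc}")
    for acc in sorted(truth.core):
        lines.append(f"core\t.\t{acc}")
    for tissue in sorted(truth.inflammation_induced):
        for acc in sorted(truth.inflammation_induced[tissue]):
            lines.append(f"induced\t{tissue}\t{acc}")
    for acc in sorted(truth.tumor_markers):
        lines.append(f"tumor_marker\t.\t{acc}")
    for acc in sorted(truth.background):
        lines.append(f"background\t.\t{acc}")
    for acc in sorted(truth.home_fraction):
        lines.append(f"fraction\t{acc}\t{truth.home_fraction[acc]}")
    for (acc, sample), lam in sorted(
        truth.per_sample_abundance.items(),
        key=lambda kv: (kv[0][0], kv[0][1].sample_id),
    ):
        lines.append(
            f"abundance\t{acc}\t{sample.tissue}\t{sample.state}"
            f"\t{sample.replicate}\t{lam}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Inverse of :func:`write_ground_truth`."""
    exclusive: dict[str, set[str]] = {}
    shared: dict[tuple[str, str], set[str]] = {}
    core: set[str] = set()
    induced: dict[str, set[str]] = {}
    markers: set[str] = set()
    background: set[str] = set()
    home_fraction: dict[str, str] = {}
    abundance: dict[tuple[str, SampleKey], int] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        kind = parts[0]
        if kind == "exclusive":
            exclusive.setdefault(parts[1], set()).add(parts[2])
        elif kind == "shared":
            t1, t2 = parts[1].split("|")
            shared.setdefault((t1, t2), set()).add(parts[2])
        elif kind == "core":
            core.add(parts[2])
        elif kind == "induced":
            induced.setdefault(parts[1], set()).add(parts[2])
        elif kind == "tumor_marker":
            markers.add(parts[2])
        elif kind == "background":
            background.add(parts[2])
        elif kind == "fraction":
            home_fraction[parts[1]] = parts[2]
        elif kind == "abundance":
            acc, tissue, state, rep, lam = parts[1:6]
            abundance[(acc, SampleKey(tissue, state, int(rep)))] = int(lam)
        else:
            raise ValueError(f"unknown ground-truth record kind {kind!r}")
    return GroundTruth(
        tissue_exclusive={t: frozenset(s) for t, s in exclusive.items()},
        shared_pairs={p: frozenset(s) for p, s in shared.items()},
        core=frozenset(core),
        inflammation_induced={t: frozenset(s) for t, s in induced.items()},
        tumor_markers=frozenset(markers),
        background=frozenset(background),
        home_fraction=home_fraction,
        per_sample_abundance=abundance,
    )
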
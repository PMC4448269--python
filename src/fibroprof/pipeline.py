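"""End-to-end orchestration: simulate -> identify -> quantify -> compare.

One YAML config drives the whole run.  Every output file is plain text
(FASTA / TSV / JSON), opens with a comment header carrying the config hash,
seed and tool version, and the run ends with a manifest listing every
artifact with its row count and content hash — rerunning the same config
reproduces the manifest byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .comparative import (
    TissueStateProfile,
    call_differential,
    chronic_inflammation_report,
    classify_cross_tissue,
    derive_tissue_signatures,
    signatures_to_frame,
)
from .identification import (
    FilterThresholds,
    apply_evidence_rules,
    estimate_fdr,
    filter_psms,
    infer_proteins_greedy,
    map_peptides,
)
from .io_formats import (
    FRACTIONS,
    FormatError,
    ProteinRecord,
    read_fasta,
    read_profile_table,
    read_profile_xlsx,
    read_psm_table,
    write_fasta,
    write_profile_table,
    write_psm_table,
)
from .quantitation import (
    DEFAULT_DIGESTION,
    DigestionParams,
    build_profile_table,
    count_observable_peptides,
)
from .synthetic import (
    GroundTruth,
    SimulationParams,
    generate_protein_database,
    make_decoy_database,
    plant_ground_truth,
    simulate_psms,
    write_ground_truth,
)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Either ``simulation`` (generate everything) or both ``psm_table`` and
    ``database`` paths must be given.  The seed feeds every source of
    randomness and is recorded in every output header.
    """

    output_dir: str | Path = "fibroprof_out"
    seed: int = 1
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    digestion: DigestionParams = field(default_factory=DigestionParams)
    simulation: SimulationParams | None = None
    psm_table: str | None = None
    database: str | None = None
    fdr_estimator: str = "decoy_over_target"
    markers: tuple[str, ...] = ()
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.simulation is None and self.psm_table is None:
            raise ConfigError(
                "config needs either a simulation block or an input PSM table"
            )
        if self.simulation is None and self.database is None:
            raise ConfigError("an input PSM table requires a protein database")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs: dict = {}
        for key in ("output_dir", "seed", "psm_table", "database",
                    "fdr_estimator", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "markers" in raw:
            kwargs["markers"] = tuple(raw["markers"])
        if "thresholds" in raw:
            kwargs["thresholds"] = FilterThresholds(**raw["thresholds"])
        if "digestion" in raw:
            dig = dict(raw["digestion"])
            if "mass_range" in dig:
                dig["mass_range"] = tuple(dig["mass_range"])
            kwargs["digestion"] = DigestionParams(**dig)
        if "simulation" in raw:
            sim = dict(raw["simulation"] or {})
            for key in ("protein_length_range", "tissues", "states",
                        "fractions", "tumor_marker_expected",
                        "background_expected_range",
                        "target_score_distribution", "decoy_score_distribution"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim.setdefault("seed", raw.get("seed", 1))
            kwargs["simulation"] = SimulationParams(**sim)
        config = cls(**kwargs)
        config.validate()
        return config

    def config_hash(self) -> str:
        """Content hash of the semantic config (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        payload.pop("log_level")
        if payload.get("digestion"):
            payload["digestion"]["fixed_modifications"] = sorted(
                payload["digestion"]["fixed_modifications"].items()
            )
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    """In-memory results of one analysis run."""

    database: list[ProteinRecord]
    decoys: list[ProteinRecord]
    psms: pd.DataFrame
    accepted: pd.DataFrame
    fdr: float
    fdr_stats: dict
    assigned: pd.DataFrame          # accepted target PSMs x covering accession
    orphans: list[str]
    sample_counts: pd.DataFrame     # accession x sample_id total distinct counts
    retained: dict[str, set[str]]   # evidence-rule survivors per sample
    profiles: dict[tuple[str, str], TissueStateProfile]
    truth: GroundTruth | None = None


def analyze(
    psms: pd.DataFrame,
    database: Sequence[ProteinRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    digestion: DigestionParams = DEFAULT_DIGESTION,
    fdr_estimator: str = "decoy_over_target",
    replicates: Sequence[int] | None = None,
    decoys: Sequence[ProteinRecord] | None = None,
) -> StudyResult:
    """Run filtering, FDR, per-sample parsimony inference, the evidence
    rules and profile building on an existing PSM table."""
    targets = [p for p in database if not p.is_decoy]
    decoy_records = list(decoys) if decoys is not None else [
        p for p in database if p.is_decoy
    ]

    accepted = filter_psms(psms, thresholds)
    log.info("filter: %d of %d PSMs accepted", len(accepted), len(psms))
    fdr = estimate_fdr(accepted, method=fdr_estimator)
    fdr_stats = {
        "accepted_targets": int((~accepted["is_decoy"]).sum()),
        "accepted_decoys": int(accepted["is_decoy"].sum()),
        "fdr": fdr,
        "estimator": fdr_estimator,
    }

    target_psms = accepted.loc[~accepted["is_decoy"]].reset_index(drop=True)
    mapping, orphans = map_peptides(target_psms, targets, digestion)
    if orphans:
        log.info("%d accepted peptide(s) match no target protein", len(orphans))

    # per-sample parsimony inference, then expand PSMs by covering protein
    assigned_parts: list[pd.DataFrame] = []
    for sample_id, group in target_psms.groupby("sample_id", sort=True):
        sub_map = {
            pep: mapping[pep]
            for pep in set(group["peptide"]) if pep in mapping
        }
        if not sub_map:
            continue
        result = infer_proteins_greedy(sub_map)
        pairs = pd.DataFrame(
            [(pep, acc)
             for pep in sorted(result.peptide_assignments)
             for acc in sorted(result.peptide_assignments[pep])],
            columns=["peptide", "accession"],
        )
        assigned_parts.append(group.merge(pairs, on="peptide", how="inner"))
    assigned = (
        pd.concat(assigned_parts, ignore_index=True)
        if assigned_parts
        else pd.DataFrame(columns=list(target_psms.columns) + ["accession"])
    )

    # per-sample total distinct-peptide counts -> evidence rules
    sample_ids = sorted(psms["sample_id"].astype(str).unique())
    counts = (
        assigned.groupby(["accession", "sample_id"])["peptide"].nunique()
        .unstack(fill_value=0)
        .reindex(columns=sample_ids, fill_value=0)
        if len(assigned) else
        pd.DataFrame(columns=sample_ids)
    )
    retained = apply_evidence_rules(counts)
    keep_pairs = {
        (acc, sample) for sample, accs in retained.items() for acc in accs
    }
    if len(assigned):
        mask = [
            (acc, sid) in keep_pairs
            for acc, sid in zip(assigned["accession"], assigned["sample_id"])
        ]
        assigned = assigned.loc[mask].reset_index(drop=True)

    # profiles per (tissue, state)
    names = {p.accession: p.name for p in targets}
    n_observable = {
        p.accession: count_observable_peptides(p.sequence, digestion)
        for p in targets
    }
    if replicates is None:
        replicates = sorted(int(r) for r in psms["replicate"].unique())
    profiles: dict[tuple[str, str], TissueStateProfile] = {}
    group_keys = sorted(
        set(zip(psms["tissue"].astype(str), psms["state"].astype(str)))
    )
    for tissue, state in group_keys:
        part = assigned.loc[
            (assigned["tissue"] == tissue) & (assigned["state"] == state)
        ]
        peptide_sets: dict[str, dict[int, dict[str, set]]] = {}
        for (acc, rep, fraction), grp in part.groupby(
            ["accession", "replicate", "fraction"]
        ):
            peptide_sets.setdefault(acc, {}).setdefault(int(rep), {})[
                str(fraction)
            ] = set(grp["peptide"])
        table = build_profile_table(peptide_sets, names, n_observable, replicates)
        profiles[(tissue, state)] = TissueStateProfile(tissue, state, table)

    return StudyResult(
        database=list(targets), decoys=decoy_records, psms=psms,
        accepted=accepted, fdr=fdr, fdr_stats=fdr_stats, assigned=assigned,
        orphans=orphans, sample_counts=counts, retained=retained,
        profiles=profiles,
    )


def run_study(
    params: SimulationParams,
    thresholds: FilterThresholds = FilterThresholds(),
    digestion: DigestionParams = DEFAULT_DIGESTION,
    fdr_estimator: str = "decoy_over_target",
) -> StudyResult:
    """Simulate a full experiment and analyze it in memory."""
    targets = generate_protein_database(params)
    decoys = make_decoy_database(targets)
    truth = plant_ground_truth(targets, params.design(), params)
    psms = simulate_psms(targets, decoys, truth, params, digestion)
    result = analyze(
        psms, targets, thresholds, digestion, fdr_estimator,
        replicates=list(range(1, params.n_replicates + 1)), decoys=decoys,
    )
    result.truth = truth
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline per config; returns the artifact manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (
        f"fibroprof {__version__}\n"
        f"seed: {config.seed}\n"
        f"config_hash: {config.config_hash()}"
    )
    files: dict[str, dict] = {}

    def record(name: str, rows: int) -> None:
        digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
        files[name] = {"rows": int(rows), "sha256": digest}

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ConfigError, FormatError):
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    # ---- stage: inputs -----------------------------------------------------
    truth: GroundTruth | None = None
    if config.simulation is not None:
        params = dataclasses.replace(config.simulation, seed=config.seed)
        targets = stage("simulate", generate_protein_database, params)
        decoys = stage("simulate", make_decoy_database, targets)
        truth = stage("simulate", plant_ground_truth, targets,
                      params.design(), params)
        psms = stage("simulate", simulate_psms, targets, decoys, truth,
                     params, config.digestion)
        write_fasta(targets + decoys, out / "database.fasta")
        record("database.fasta", len(targets) + len(decoys))
        write_psm_table(psms, out / "psms.tsv", header_comment=header)
        record("psms.tsv", len(psms))
        write_ground_truth(truth, out / "ground_truth.tsv")
        record("ground_truth.tsv", len(truth.per_sample_abundance))
        database = targets + decoys
        replicates = list(range(1, params.n_replicates + 1))
    else:
        database = stage("load", read_fasta, config.database)
        psms = stage("load", read_psm_table, config.psm_table)
        replicates = None
    log.info("inputs: %d database entries, %d PSMs", len(database), len(psms))

    # ---- stage: identify + quantify ---------------------------------------
    result = stage(
        "analyze", analyze, psms,
        [p for p in database if not p.is_decoy],
        config.thresholds, config.digestion, config.fdr_estimator,
        replicates, [p for p in database if p.is_decoy],
    )
    result.truth = truth

    write_psm_table(result.accepted, out / "accepted_psms.tsv", header_comment=header)
    record("accepted_psms.tsv", len(result.accepted))
    (out / "fdr_summary.json").write_text(
        json.dumps(result.fdr_stats, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    record("fdr_summary.json", 1)
    (out / "orphan_peptides.txt").write_text(
        "".join(f"{pep}\n" for pep in result.orphans), encoding="utf-8"
    )
    record("orphan_peptides.txt", len(result.orphans))

    protein_rows = [
        {"sample_id": sample, "accession": acc}
        for sample in sorted(result.retained)
        for acc in sorted(result.retained[sample])
    ]
    pd.DataFrame(protein_rows, columns=["sample_id", "accession"]).to_csv(
        out / "accepted_proteins.tsv", sep="\t", index=False
    )
    record("accepted_proteins.tsv", len(protein_rows))

    for (tissue, state), profile in sorted(result.profiles.items()):
        name = f"profile_{tissue}_{state}.tsv"
        write_profile_table(profile.table, out / name, header_comment=header)
        record(name, len(profile.table))

    # ---- stage: compare ----------------------------------------------------
    signatures = stage("signatures", derive_tissue_signatures, result.profiles)
    sig_frame = signatures_to_frame(signatures)
    sig_frame.to_csv(out / "signatures.tsv", sep="\t", index=False)
    record("signatures.tsv", len(sig_frame))

    tissues = sorted({t for t, _ in result.profiles})
    diff_parts = []
    for tissue in tissues:
        control = result.profiles.get((tissue, "control"))
        treated = result.profiles.get((tissue, "il1b"))
        if control is None or treated is None:
            continue
        for fraction in FRACTIONS:
            calls = stage("differential", call_differential,
                          control, treated, fraction)
            calls.insert(0, "tissue", tissue)
            diff_parts.append(calls)
    differential = (
        pd.concat(diff_parts, ignore_index=True) if diff_parts else pd.DataFrame()
    )
    differential.to_csv(out / "differential.tsv", sep="\t", index=False,
                        float_format="%.6g")
    record("differential.tsv", len(differential))

    patterns = _cross_tissue_patterns(differential, tissues)
    patterns.to_csv(out / "cross_tissue_patterns.tsv", sep="\t", index=False)
    record("cross_tissue_patterns.tsv", len(patterns))

    markers = list(config.markers)
    if not markers and truth is not None:
        markers = sorted(truth.tumor_markers)
    tumor_profiles = {t: p for (t, s), p in result.profiles.items() if s == "tumor"}
    control_profiles = {t: p for (t, s), p in result.profiles.items() if s == "control"}
    if markers and tumor_profiles and control_profiles:
        report = stage("chronic_report", chronic_inflammation_report,
                       tumor_profiles, control_profiles, markers)
    else:
        report = pd.DataFrame()
    report.to_csv(out / "chronic_inflammation.tsv", sep="\t", index=False,
                  float_format="%.6g")
    record("chronic_inflammation.tsv", len(report))

    manifest = {
        "tool": "fibroprof",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "fdr": result.fdr,
        "files": dict(sorted(files.items())),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    log.info("wrote %d artifacts to %s", len(files) + 1, out)
    return manifest


def _cross_tissue_patterns(
    differential: pd.DataFrame, tissues: Sequence[str]
) -> pd.DataFrame:
    """Classify each protein's regulation pattern per fraction across tissues."""
    if differential.empty:
        return pd.DataFrame(columns=["accession", "fraction", "pattern"])
    rows = []
    for (acc, fraction), grp in differential.groupby(["accession", "fraction"]):
        directions = {t: "absent" for t in tissues}
        directions.update(dict(zip(grp["tissue"], grp["direction"])))
        if len(directions) < 2:
            continue
        rows.append({
            "accession": acc, "fraction": fraction,
            "pattern": classify_cross_tissue(directions),
        })
    return pd.DataFrame(rows, columns=["accession", "fraction", "pattern"])


def count_profile_proteins(path: str | Path) -> int:
    """Unique-accession count of a profile table (TSV or supplementary XLSX)."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        table = read_profile_xlsx(path)
        dup = table["accession"][table["accession"].duplicated()]
        if len(dup):
            raise FormatError(
                f"duplicate accession(s): {', '.join(sorted(set(dup)))}"
            )
    else:
        table = read_profile_table(path)
    return int(table["accession"].nunique())
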
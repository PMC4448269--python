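"""Readers and writers for every on-disk format the pipeline touches.

The pipeline's native formats are deliberately plain text: FASTA for protein
databases, tab-separated tables for peptide-spectrum matches (PSMs) and for
per-cell-state proteome profiles.  Parsing is strict — a malformed row raises
:class:`FormatError` carrying the offending line, never a silent drop —
because downstream protein counts depend bit-exactly on what was read.

An XLSX import shim (:func:`read_profile_xlsx`) accepts spreadsheets shaped
like published supplementary protein lists (columns ``Accession``, ``name``,
``peptides``); on a header mismatch it logs what it found and refuses to
guess.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Fixed vocabulary of sub-cellular fractions profiled per sample.
FRACTIONS = ("cytoplasm", "secretome", "nucleus")

#: Reserved accession prefix marking reversed-sequence decoy entries.
DECOY_PREFIX = "DECOY_"

#: Column order of the PSM table dialect.
PSM_COLUMNS = [
    "sample_id", "tissue", "state", "replicate", "fraction", "peptide",
    "score", "precursor_match", "rt_match", "ms2_match", "is_decoy",
]
_PSM_BOOL_COLUMNS = ["precursor_match", "rt_match", "ms2_match", "is_decoy"]

#: Columns every profile table must carry (extra columns are preserved).
PROFILE_REQUIRED_COLUMNS = ["accession", "name", *FRACTIONS, "peptides"]


class FormatError(ValueError):
    """A file violated the format contract (bad residue, missing column, ...)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein database entry.

    Parameters
    ----------
    accession : str
        Swiss-Prot-style identifier, unique within a database.  Decoy
        entries carry the ``DECOY_`` prefix.
    name : str
        Free-text protein name (may be empty).
    sequence : str
        Upper-case amino-acid string over the 20 standard residues.
    is_decoy : bool
        True for reversed-sequence decoy entries.
    """

    accession: str
    name: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.accession!r}: empty sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise FormatError(
                f"record {self.accession!r}: illegal residue(s) "
                f"{''.join(sorted(bad))}"
            )


@dataclass(frozen=True)
class ProfileRow:
    """One profile-table row: per-fraction distinct-peptide counts and total.

    The total is the size of the union of the per-fraction peptide sets, so
    it never exceeds the sum of the per-fraction counts (peptides observed in
    several fractions count once).
    """

    accession: str
    name: str
    fraction_counts: Mapping[str, int]
    total: int

    @classmethod
    def from_peptide_sets(
        cls, accession: str, name: str,
        peptide_sets: Mapping[str, "set[str] | frozenset[str]"],
    ) -> "ProfileRow":
        unknown = set(peptide_sets) - set(FRACTIONS)
        if unknown:
            raise FormatError(f"unknown fraction(s): {sorted(unknown)}")
        counts = {f: len(peptide_sets.get(f, ())) for f in FRACTIONS}
        union: set[str] = set()
        for peps in peptide_sets.values():
            union |= set(peps)
        return cls(accession, name, counts, len(union))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA; header format ``>accession name``.

    Raises :class:`FormatError` on duplicate accessions or residues outside
    the 20-letter standard alphabet.  Decoy status is recovered from the
    ``DECOY_`` accession prefix.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        if accession in seen:
            raise FormatError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        name = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(
            accession=accession,
            name=name,
            sequence=str(rec.seq).upper(),
            is_decoy=accession.startswith(DECOY_PREFIX),
        ))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapping sequence lines at 60 residues."""
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            raise FormatError(f"duplicate accession {rec.accession!r}")
        seen.add(rec.accession)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.name)
        for r in records
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        SeqIO.write(seq_records, handle, "fasta")


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read the PSM TSV dialect into a typed DataFrame.

    Booleans are serialized as 0/1; ``#``-prefixed header comments are
    skipped.  An unknown fraction label or missing column raises
    :class:`FormatError` (missing columns are listed by name, bad fractions
    by line number).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    df = df[PSM_COLUMNS].reset_index(drop=True)
    bad = ~df["fraction"].isin(FRACTIONS)
    if bad.any():
        i = int(bad.idxmax())
        raise FormatError(
            f"{path}: line {i + 2}: unknown fraction "
            f"{df['fraction'].iloc[i]!r} (expected one of {FRACTIONS})"
        )
    df["score"] = df["score"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    for c in _PSM_BOOL_COLUMNS:
        df[c] = df[c].astype(bool)
    for c in ("sample_id", "tissue", "state", "fraction", "peptide"):
        df[c] = df[c].astype(str)
    return df


def write_psm_table(
    table: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a PSM table as TSV; booleans as 0/1, scores at 4 decimals."""
    missing = [c for c in PSM_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    out = table[PSM_COLUMNS].copy()
    for c in _PSM_BOOL_COLUMNS:
        out[c] = out[c].astype(int)
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        _write_comment(handle, header_comment)
        out.to_csv(handle, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# Profile tables
# ---------------------------------------------------------------------------

def write_profile_table(
    rows: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a proteome-profile table (supplementary-list layout plus
    per-fraction columns) as TSV.

    Rows must be sorted by accession and accessions unique, so the
    unique-protein count of a profile is recoverable as the row count.
    """
    missing = [c for c in PROFILE_REQUIRED_COLUMNS if c not in rows.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    accs = list(rows["accession"])
    if accs != sorted(accs):
        raise FormatError("profile rows must be sorted by accession")
    if len(set(accs)) != len(accs):
        dup = sorted({a for a in accs if accs.count(a) > 1})
        raise FormatError(f"duplicate accession(s): {', '.join(dup)}")
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        _write_comment(handle, header_comment)
        rows.to_csv(handle, sep="\t", index=False, float_format="%.4f")


def read_profile_table(path: str | Path) -> pd.DataFrame:
    """Read a profile TSV back; duplicate accessions raise FormatError."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PROFILE_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    dup = df["accession"][df["accession"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate accession(s): {', '.join(sorted(set(dup)))}")
    df["accession"] = df["accession"].astype(str)
    df["name"] = df["name"].fillna("").astype(str)
    return df.reset_index(drop=True)


def read_profile_xlsx(path: str | Path) -> pd.DataFrame:
    """Import a supplementary-style XLSX protein list.

    Expects (case-insensitively) columns ``accession``, ``name`` and
    ``peptides`` in the first worksheet's header row.  On mismatch the
    observed header is logged and a :class:`FormatError` raised — the shim
    never guesses column meanings.
    """
    from openpyxl import load_workbook

    wb = load_workbook(str(path), read_only=True, data_only=True)
    try:
        ws = wb.worksheets[0]
        rows = ws.iter_rows(values_only=True)
        try:
            raw_header = next(rows)
        except StopIteration:
            raise FormatError(f"{path}: empty worksheet") from None
        header = [str(h).strip().lower() if h is not None else "" for h in raw_header]
        wanted = ["accession", "name", "peptides"]
        if not set(wanted) <= set(header):
            log.error("%s: unrecognized header %r (need %r)", path, header, wanted)
            raise FormatError(
                f"{path}: header {header!r} does not contain {wanted!r}"
            )
        idx = {w: header.index(w) for w in wanted}
        data = [
            {w: row[idx[w]] for w in wanted}
            for row in rows
            if row is not None and row[idx["accession"]] is not None
        ]
    finally:
        wb.close()
    df = pd.DataFrame(data, columns=["accession", "name", "peptides"])
    df["accession"] = df["accession"].astype(str)
    df["name"] = df["name"].fillna("").astype(str)
    df["peptides"] = df["peptides"].astype(int)
    return df


def _write_comment(handle, comment: str | None) -> None:
    if comment:
        for line in comment.splitlines():
            handle.write(f"# {line}\n")
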
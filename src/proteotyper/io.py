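"""Readers and writers for the tabular and FASTA formats.

All TSV outputs start with a ``# proteotyper <version>`` comment line;
readers skip comment lines, so the files round-trip.  FASTA handling
goes through pyteomics; custom-database headers carry taxon
provenance as ``>accession organism=<species_id>``.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable

import pandas as pd
from pyteomics import fasta as _fasta

from . import __version__
from .index import ReferenceProteinRecord
from .proteotyping import PsmRecord

PSM_COLUMNS = ["run", "spectrum_id", "peptide", "score", "intensity"]


def write_tsv(frame: pd.DataFrame, path) -> None:
    """TSV with the producing-version comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# proteotyper {__version__}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ------------------------------------------------------------------- PSMs


def write_psm_table(psms: pd.DataFrame, path) -> None:
    missing = {"run", "spectrum_id", "peptide", "score"} - set(psms.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    write_tsv(psms, path)


def read_psm_table(path) -> list[PsmRecord]:
    """Parse a PSM TSV into records.

    Expected columns: run, spectrum_id, peptide, score, and optionally
    intensity.  (run, spectrum_id) pairs must be unique.
    """
    frame = read_tsv(path, dtype={"run": str, "spectrum_id": str, "peptide": str})
    missing = {"run", "spectrum_id", "peptide", "score"} - set(frame.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    if frame.duplicated(subset=["run", "spectrum_id"]).any():
        dupes = frame[frame.duplicated(subset=["run", "spectrum_id"])]
        raise ValueError(
            "duplicate (run, spectrum_id) pairs: "
            + ", ".join(
                f"{r}/{s}"
                for r, s in dupes[["run", "spectrum_id"]].head(5).itertuples(
                    index=False
                )
            )
        )
    has_intensity = "intensity" in frame.columns
    return [
        PsmRecord(
            run_id=row.run,
            spectrum_id=row.spectrum_id,
            peptide=row.peptide,
            score=None if pd.isna(row.score) else float(row.score),
            intensity=(
                float(row.intensity)
                if has_intensity and not pd.isna(row.intensity)
                else None
            ),
        )
        for row in frame.itertuples(index=False)
    ]


def read_quant_table(path) -> pd.DataFrame:
    frame = read_tsv(path, dtype={"protein_group": str, "member_accessions": str})
    missing = {"protein_group", "member_accessions"} - set(frame.columns)
    if missing:
        raise ValueError(f"quant table missing columns: {sorted(missing)}")
    return frame


# ------------------------------------------------------------------ FASTA


def read_fasta(path) -> list[ReferenceProteinRecord]:
    """Read a proteome FASTA.

    The accession is the first whitespace-delimited token of the
    header; an ``organism=<id>`` token, if present, sets the source
    organism (custom-database dialect).  Records without one get an
    empty organism and must be joined to a taxonomy externally.
    """
    records = []
    with _fasta.read(str(path)) as reader:
        for header, sequence in reader:
            tokens = header.split()
            accession = tokens[0]
            organism = ""
            for token in tokens[1:]:
                if token.startswith("organism="):
                    organism = token[len("organism="):]
            records.append(
                ReferenceProteinRecord(
                    accession=accession,
                    sequence=str(sequence).upper(),
                    organism=organism,
                )
            )
    return records


def write_fasta(records: Iterable[ReferenceProteinRecord], path) -> None:
    """Write records with provenance-tagged headers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    entries = [
        (f"{r.accession} organism={r.organism}", r.sequence) for r in records
    ]
    _fasta.write(entries, str(path), file_mode="w")


def write_custom_fasta(database, path) -> None:
    write_fasta(database.records, path)


# ------------------------------------------------------------- checksums


def sha256_file(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()
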
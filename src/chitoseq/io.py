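"""File-format adapters: FASTA + annotation TSV, MGF peak lists, reports."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .msannotate import Peak, Spectrum
from .screen import ProteinRecord


class InputFormatError(ValueError):
    """Malformed or empty input file."""


# ---------------------------------------------------------------------------
# Protein collections


def read_fasta(path, annotations: dict | None = None) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ann = (annotations or {}).get(rec.id, {})
        records.append(ProteinRecord(rec.id, str(rec.seq), ann))
    if not records:
        raise InputFormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


ANNOTATION_COLUMNS = ("family", "complete_gene", "domain_count",
                      "sp_start", "sp_end")


def read_annotations(path) -> dict:
    """Per-protein annotation TSV: id plus any of family / complete_gene /
    domain_count / sp_start / sp_end."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise InputFormatError(f"{path}: annotation TSV needs an 'id' column")
    out: dict = {}
    for _, row in df.iterrows():
        ann = {}
        for col in ANNOTATION_COLUMNS:
            if col in df.columns and pd.notna(row[col]):
                ann[col] = row[col]
        out[str(row["id"])] = ann
    return out


# ---------------------------------------------------------------------------
# MGF spectra


def read_mgf(path) -> list[Spectrum]:
    """MS2 spectra from an MGF peak list (BEGIN IONS / PEPMASS dialect)."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            pepmass = entry["params"].get("pepmass")
            precursor = float(pepmass[0]) if pepmass else None
            peaks = [
                Peak(float(mz), float(inten))
                for mz, inten in zip(entry["m/z array"],
                                     entry["intensity array"])
            ]
            spectra.append(
                Spectrum(peaks=peaks, ms_level=2, precursor_mz=precursor)
            )
    if not spectra:
        raise InputFormatError(f"{path}: no MS2 blocks")
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    entries = []
    for i, s in enumerate(spectra, start=1):
        entries.append(
            {
                "m/z array": [p.mz for p in s.peaks],
                "intensity array": [p.intensity for p in s.peaks],
                "params": {"title": f"spectrum_{i}",
                           "pepmass": s.precursor_mz},
            }
        )
    _mgf.write(entries, str(path), file_mode="w")
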
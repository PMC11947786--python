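"""Readers and writers for the pipeline's on-disk formats.

Protein libraries are plain FASTA with a ``>accession|gene_symbol``
header dialect (the gene symbol defaults to the accession when absent,
since accessions map many-to-one onto gene symbols). All spectra —
sample runs, blank injections, and random-spectrum controls — travel as
Mascot Generic Format (MGF); results are tab-separated tables. A run
manifest TSV ties the MGF files to instrument and run-kind labels.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .constants import VALID_RESIDUES

logger = logging.getLogger(__name__)

INSTRUMENT_LABELS = ("OIT_LIKE", "LIT_LIKE")
RUN_KINDS = ("SAMPLE", "BLANK", "RANDOM")


class ParseError(ValueError):
    """Raised for malformed FASTA/MGF input."""


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    gene_symbol: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ParseError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ParseError(
                f"{self.accession}: invalid residue(s) {sorted(bad)}"
            )
        if not self.gene_symbol:
            raise ParseError(f"{self.accession}: empty gene symbol")


@dataclass
class Spectrum:
    """One MS/MS event: precursor plus fragment peak list.

    ``mz`` and ``intensity`` are parallel arrays sorted ascending in m/z.
    """

    spectrum_id: str
    run_id: str
    instrument_label: str
    run_kind: str
    precursor_mz: float
    precursor_charge: int
    precursor_intensity: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.mz.size and self.mz[0] <= 0:
            raise ValueError(f"{self.spectrum_id}: non-positive fragment m/z")
        if self.precursor_charge not in (2, 3):
            raise ValueError(
                f"{self.spectrum_id}: precursor charge must be 2 or 3, "
                f"got {self.precursor_charge}"
            )

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class RunManifest:
    run_id: str
    instrument_label: str
    run_kind: str
    spectrum_count: int
    file_path: str


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein library.

    Header dialect: ``>accession|gene_symbol optional description``;
    without the ``|gene_symbol`` part the accession doubles as the gene
    symbol. Duplicate accessions and residues outside the 20-letter
    alphabet are rejected.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header = None
    header_line = 0
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(f"line {header_line}: entry '{header}' has no sequence")
        token = header.split()[0]
        if not token:
            raise ParseError(f"line {header_line}: malformed FASTA header")
        acc, _, gene = token.partition("|")
        if acc in seen:
            raise ParseError(f"line {header_line}: duplicate accession '{acc}'")
        seen.add(acc)
        records.append(ProteinRecord(acc, gene or acc, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise ParseError(f"line {lineno}: empty FASTA header")
            else:
                if header is None:
                    raise ParseError(f"line {lineno}: sequence before any header")
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}|{rec.gene_symbol}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# MGF

def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra as MGF; run/instrument labels ride in header params.

    Peak m/z is kept to 6 decimal places and intensities in scientific
    notation, preserving the E3-E10 dynamic range of detector counts.
    """
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.spectrum_id,
                    "pepmass": (s.precursor_mz, s.precursor_intensity),
                    "charge": [s.precursor_charge],
                    "runid": s.run_id,
                    "instrument": s.instrument_label,
                    "runkind": s.run_kind,
                },
            }
        )
    _mgf.write(
        entries,
        str(path),
        fragment_format="{:.6f} {:.6e}",
        use_numpy=False,
        param_formatters={
            "pepmass": lambda key, v: f"PEPMASS={v[0]:.6f} {v[1]:.6e}",
            "charge": lambda key, v: f"CHARGE={v[0]}+",
        },
        file_mode="w",
    )


def read_mgf(path, default_run_id: str | None = None) -> list[Spectrum]:
    """Read an MGF file.

    The PEPMASS second token, when present, is the precursor intensity
    (0 otherwise). Blocks without a CHARGE line are skipped with a
    logged warning; a malformed peak line raises :class:`ParseError`.
    """
    path = Path(path)
    run_id = default_run_id or path.stem
    out: list[Spectrum] = []
    try:
        blocks = list(_mgf.read(str(path), convert_arrays=1, read_charges=False))
    except Exception as exc:  # pyteomics raises various ValueErrors
        raise ParseError(f"{path}: {exc}") from exc
    for i, block in enumerate(blocks):
        params = block["params"]
        title = str(params.get("title", f"{run_id}:{i:06d}"))
        charge = params.get("charge")
        if not charge:
            logger.warning("spectrum %s: missing CHARGE, skipped", title)
            continue
        pepmass = params.get("pepmass", (0.0, None))
        intensity = pepmass[1] if len(pepmass) > 1 and pepmass[1] is not None else 0.0
        out.append(
            Spectrum(
                spectrum_id=title,
                run_id=str(params.get("runid", run_id)),
                instrument_label=str(params.get("instrument", "OIT_LIKE")),
                run_kind=str(params.get("runkind", "SAMPLE")),
                precursor_mz=float(pepmass[0]),
                precursor_charge=int(charge[0]),
                precursor_intensity=float(intensity),
                mz=block["m/z array"],
                intensity=block["intensity array"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tabular results, manifest, config

def write_results_table(records: Sequence, path, fields: Sequence[str] | None = None) -> None:
    """Write dataclass records (PSMs, protein results, ...) as TSV.

    With zero records a ``fields`` list is required to emit the header.
    """
    if records:
        rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r) for r in records]
        df = pd.DataFrame(rows)
        if fields is not None:
            df = df[list(fields)]
    else:
        if fields is None:
            raise ValueError("fields required to write an empty table")
        df = pd.DataFrame(columns=list(fields))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(manifests: Sequence[RunManifest], path) -> None:
    write_results_table(
        manifests, path,
        fields=["run_id", "instrument_label", "run_kind", "spectrum_count", "file_path"],
    )


def read_manifest(path) -> list[RunManifest]:
    df = read_results_table(path)
    return [
        RunManifest(
            run_id=str(r.run_id),
            instrument_label=str(r.instrument_label),
            run_kind=str(r.run_kind),
            spectrum_count=int(r.spectrum_count),
            file_path=str(r.file_path),
        )
        for r in df.itertuples()
    ]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
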
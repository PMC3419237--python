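"""File formats and run manifests.

Text formats only: spectra as two-column CSV with ``#`` header comments,
sequences as FASTA, trees as Newick (supports as internal node labels),
tables as TSV, configurations and manifests as JSON.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .epr_sim import Spectrum
from .errors import DataFormatError

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_tsv_table",
    "write_tsv_table",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def write_spectrum(spectrum: Spectrum, path) -> None:
    """Two-column CSV (field_mT, intensity) with ``# key: value`` headers."""
    with open(path, "w", newline="\n") as fh:
        for key, value in spectrum.meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("field_mT,intensity\n")
        for b, i in zip(spectrum.field_mT, spectrum.intensity):
            fh.write(f"{float(b)!r},{float(i)!r}\n")


def read_spectrum(path, require_frequency: bool = False) -> Spectrum:
    """Read a spectrum CSV; ``#``-prefixed headers become metadata.

    Analysis modes need the microwave frequency to convert fields to
    g-values; pass ``require_frequency=True`` to make its absence an
    error naming the header key.
    """
    meta: dict = {}
    rows: list[tuple[float, float]] = []
    try:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line[1:].strip()
                    if ":" in body:
                        key, _, value = body.partition(":")
                        meta[key.strip()] = value.strip()
                    continue
                if line.lower().startswith("field"):
                    continue
                parts = line.split(",")
                if len(parts) != 2:
                    raise DataFormatError(
                        f"{path}:{lineno}: expected two comma-separated columns")
                try:
                    rows.append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise DataFormatError(f"{path}:{lineno}: {exc}") from exc
    except OSError as exc:
        raise DataFormatError(str(exc)) from exc
    if not rows:
        raise DataFormatError(f"{path}: no data rows")
    if "frequency_GHz" in meta:
        meta["frequency_GHz"] = float(meta["frequency_GHz"])
    elif require_frequency:
        raise DataFormatError(
            f"{path}: missing required header '# frequency_GHz: <value>'")
    field, intensity = (np.array(c) for c in zip(*rows))
    return Spectrum(field, intensity, meta)


# ---------------------------------------------------------------------------
# sequences and trees
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SeqRecord]:
    """Read FASTA records; duplicate ids are an error."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (OSError, ValueError) as exc:
        raise DataFormatError(f"{path}: {exc}") from exc
    if not records:
        raise DataFormatError(f"{path}: no FASTA records")
    seen: dict[str, int] = {}
    for pos, rec in enumerate(records, 1):
        if rec.id in seen:
            raise DataFormatError(
                f"{path}: duplicate id {rec.id!r} (records {seen[rec.id]} and {pos})")
        seen[rec.id] = pos
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = str(rec.seq)
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_newick(path):
    from Bio.Phylo.NewickIO import NewickError

    try:
        tree = Phylo.read(str(path), "newick")
    except (OSError, ValueError, NewickError) as exc:
        raise DataFormatError(f"{path}: {exc}") from exc
    return tree


def write_newick(tree, path) -> None:
    Phylo.write(tree, str(path), "newick")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_tsv_table(path, required_columns=None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise DataFormatError(f"{path}: {exc}") from exc
    if required_columns:
        missing = set(required_columns) - set(df.columns)
        if missing:
            raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_tsv_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def write_manifest(subcommand: str, seed, inputs, outputs,
                   config: dict | None = None,
                   manifest_path="rnrkit_runs.jsonl") -> dict:
    """Append one run manifest line to a JSONL journal.

    Records the subcommand, seed, a hash of the configuration, input and
    output paths, package version and UTC timestamp.  Append-only by
    construction.
    """
    config_json = json.dumps(config or {}, sort_keys=True, default=str)
    entry = {
        "subcommand": subcommand,
        "seed": seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = Path(manifest_path)
    if path.parent != Path("."):
        os.makedirs(path.parent, exist_ok=True)
    with open(path, "a") as fh:
        fh.write(json.dumps(entry) + "\n")
    return entry
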
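"""Readers and writers for the tabular formats the pipeline consumes.

All tabular I/O is UTF-8 with '.' decimal separators; the delimiter is
auto-detected from the file extension (.csv comma, .tsv/.txt tab).
Third-party export dialects are mapped onto the internal schemas through
small declarative reader profiles (column-name mappings).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "read_fasta",
    "read_table",
    "write_table",
    "READER_PROFILES",
    "write_manifest",
]

logger = logging.getLogger(__name__)

#: Column-name mappings from common export dialects to internal schemas.
READER_PROFILES: dict[str, dict[str, str]] = {
    # Skyline-style peptide quantification report -> XIC schema
    "skyline-xic": {
        "Protein Name": "group_id",
        "Peptide Modified Sequence": "form_id",
        "Isotope Label Type": "site_labels",
        "Total Area": "area",
        "Condition": "sample",
        "BioReplicate": "replicate",
        "Precursor Charge": "charge",
    },
    # FragPipe-style combined_protein table (already median-summarized)
    "fragpipe-protein": {
        "Protein ID": "protein_id",
        "Replicate": "replicate_id",
        "Label Orientation": "orientation",
        "Median Log2 Ratio HL": "median_log2_hl",
        "Combined Total Peptides": "n_peptides",
        "Is Contaminant": "is_contaminant",
        "Is Decoy": "is_decoy",
    },
    # DESeq2 results export
    "deseq2": {
        "gene": "gene_id",
        "log2FoldChange": "log2_fc",
        "padj": "adj_p",
    },
    # long-format plate reader export
    "plate-long": {
        "Time [min]": "time_min",
        "OD600": "od600",
        "Well": "well",
        "Strain": "strain",
        "Condition": "condition",
        "Replicate": "replicate",
    },
}


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, upper-case sequence) pairs.

    Duplicate record ids are rejected; an empty file yields an empty list
    with a warning.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_table(path: str | Path, profile: str | None = None) -> pd.DataFrame:
    """Read a CSV/TSV table, optionally translating an export dialect's
    column names to the internal schema via a reader profile."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=_delimiter(path), encoding="utf-8")
    if profile is not None:
        if profile not in READER_PROFILES:
            raise KeyError(
                f"unknown reader profile {profile!r}; "
                f"available: {sorted(READER_PROFILES)}"
            )
        df = df.rename(columns=READER_PROFILES[profile])
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_delimiter(path), index=False, encoding="utf-8")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    stage: str,
    config: dict,
    outputs: list[str | Path],
    seed: int | None = None,
) -> Path:
    """Write a machine-readable run manifest (config, seed, output hashes).

    The hashes make any silent change to an output file detectable; the
    timestamp is excluded from hashing concerns since the manifest itself
    is not listed in its own outputs.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "config": config,
        "outputs": {
            str(Path(p).name): _sha256(Path(p)) for p in outputs
        },
        "written_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
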
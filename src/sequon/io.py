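"""File I/O: FASTA, sidecar TSV tables, run metadata, YAML config.

All tabular output is TSV (header row, LF, UTF-8) with 1-based
coordinates; every report directory gets a ``run_metadata.json`` sidecar
recording the seed, configuration and package version so a run can be
reproduced byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Union

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .genetic_code import InputError
from .rates import HomologPair
from .scan import SequenceRecord

PathLike = Union[str, Path]


def read_fasta(path: PathLike, kind: str = "nucleotide",
               compartments: Optional[Mapping[str, str]] = None
               ) -> List[SequenceRecord]:
    """Read FASTA into records; ``kind`` selects CDS vs protein parsing.

    The first whitespace-delimited header token is the id; sequences are
    uppercased; duplicate ids and empty files are errors.
    """
    if kind not in ("nucleotide", "protein"):
        raise InputError(f"kind must be 'nucleotide' or 'protein', got {kind!r}")
    records: List[SequenceRecord] = []
    seen: set = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in seen:
            raise InputError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise InputError(f"record {i} ({rec.id!r}) is empty")
        comp = (compartments or {}).get(rec.id, "unlabeled")
        if kind == "nucleotide":
            records.append(SequenceRecord.from_cds(rec.id, seq, comp))
        else:
            records.append(SequenceRecord(id=rec.id, protein=seq,
                                          compartment=comp))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def read_alignment_pairs(path: PathLike,
                         compartments: Optional[Mapping[str, str]] = None
                         ) -> List[HomologPair]:
    """Read gapped protein FASTA as consecutive (reference, partner) pairs."""
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise InputError(f"no FASTA records in {path}")
    if len(raw) % 2:
        raise InputError("alignment FASTA must contain an even record count")
    pairs = []
    for a, b in zip(raw[0::2], raw[1::2]):
        comp = (compartments or {}).get(a.id, "unlabeled")
        pairs.append(HomologPair(
            id_a=a.id, id_b=b.id,
            aligned_a=str(a.seq).upper(), aligned_b=str(b.seq).upper(),
            compartment=comp,
        ))
    return pairs


def write_fasta(records: List[SequenceRecord], path: PathLike,
                what: str = "cds", width: int = 60) -> None:
    """Write CDS or protein FASTA with fixed line wrapping (deterministic)."""
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            seq = rec.cds if what == "cds" else rec.protein
            if seq is None:
                raise InputError(f"{rec.id}: no {what} to write")
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_compartments(path: PathLike) -> Dict[str, str]:
    """Sidecar TSV (id <TAB> compartment) → mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "compartment"],
                     dtype=str, comment="#")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise InputError(f"duplicate id {dup!r} in compartment table")
    return dict(zip(df["id"], df["compartment"]))


def write_compartments(records: List[SequenceRecord], path: PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            fh.write(f"{rec.id}\t{rec.compartment}\n")


def read_codon_usage(path: PathLike) -> Dict[str, float]:
    """TSV (codon <TAB> weight) → usage mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["codon", "weight"],
                     comment="#")
    return {str(c).upper(): float(w) for c, w in zip(df["codon"], df["weight"])}


def read_variant_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "compartment", "site_number", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"variant table missing columns {sorted(missing)}")
    return df


def load_config(path: PathLike) -> Dict:
    """Load a YAML run-configuration file into a flat dictionary."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputError(f"config {path} is not a mapping")
    return cfg


def write_reports(results: Mapping[str, pd.DataFrame], outdir: PathLike,
                  seed: Optional[int] = None,
                  config: Optional[Mapping] = None) -> List[Path]:
    """Write one TSV per result table plus a JSON run-metadata sidecar."""
    if not results:
        raise InputError("no result tables to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, lineterminator="\n",
                  float_format="%.6g")
        written.append(path)
    meta = {
        "version": __version__,
        "seed": seed,
        "config": dict(config or {}),
        "tables": sorted(r.name for r in written),
    }
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written.append(meta_path)
    return written
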
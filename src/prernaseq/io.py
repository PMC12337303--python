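"""Shared file I/O: FASTA/FASTQ via Biopython, headered TSV, flat config.

Every table written by the pipeline carries a comment header with the tool
version and a hash of the resolved configuration, so outputs are diffable
and traceable to the run that produced them.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .simulate import FastqRead


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality-string) from plain or gzipped FASTQ.

    The full header line (id + description) is preserved as the read id so
    ``UMI:`` annotations survive a round trip.
    """
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield rec.description, str(rec.seq), qual


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> int:
    def _records():
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.read_id.split()[0], description=r.read_id)
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.qual]
            yield rec

    with _open_text(path, "wt") as fh:
        return SeqIO.write(_records(), fh, "fastq")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(path: str | Path, entries: Iterable[tuple[str, str]]) -> int:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    with _open_text(path, "wt") as fh:
        return SeqIO.write(records, fh, "fasta")


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:8]


def write_tsv(df: pd.DataFrame, path: str | Path, config: dict | None = None,
              index: bool = False) -> None:
    with open(path, "w") as fh:
        tag = f" config={config_hash(config)}" if config is not None else ""
        fh.write(f"# prernaseq {__version__}{tag}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# prernaseq {__version__} config={config_hash(config)}\n")
        for key in sorted(config):
            fh.write(f"{key}={config[key]}\n")


def read_config(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
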
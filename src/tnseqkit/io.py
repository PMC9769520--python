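"""File format helpers: FASTA, FASTQ, GFF3 gene tables and provenance TSV.

All writers emit deterministic, plain-text output. Tables carry a provenance
header of '#'-prefixed lines (tool version, seed, config hash) and state the
1-based inclusive coordinate convention; readers skip those lines.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel

__version__ = "0.1.0"


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA/FASTQ

def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def read_fastq(path: str | Path):
    """Yield (read_id, sequence) tuples from a FASTQ file (gzip allowed)."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper()


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> int:
    """Write (id, sequence) pairs with a constant quality string; returns count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


# ---------------------------------------------------------------------- GFF3

def write_gff3(path: str | Path, genes: Sequence[GeneModel], seqid: str = "chr") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.start, g.gene_id)):
            attrs = (
                f"ID={g.gene_id};gene_type={g.gene_type};"
                f"essential={'true' if g.essential else 'false'};operon={g.operon}"
            )
            fh.write(
                f"{seqid}\ttnseqkit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            genes.append(
                GeneModel(
                    gene_id=attrs.get("ID", f"{fields[0]}:{fields[3]}-{fields[4]}"),
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6],
                    gene_type=attrs.get("gene_type", "protein"),
                    essential=attrs.get("essential", "false") == "true",
                    operon=int(attrs.get("operon", -1)),
                )
            )
    return genes


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 or from a TSV with named columns."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return read_gff3(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation TSV needs columns {sorted(required)}")
    return [
        GeneModel(
            gene_id=str(r.gene_id),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            gene_type=str(getattr(r, "gene_type", "protein")),
            essential=bool(getattr(r, "essential", False)),
        )
        for r in df.itertuples()
    ]


# ------------------------------------------------------------ tables / JSON

def provenance_header(seed: int | None = None, config_hash: str | None = None) -> str:
    lines = [
        f"# tnseqkit {__version__}",
        "# coordinates: 1-based inclusive",
    ]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config_hash is not None:
        lines.append(f"# config: {config_hash}")
    return "\n".join(lines) + "\n"


def write_table(
    path: str | Path,
    df: pd.DataFrame,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config_hash))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
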
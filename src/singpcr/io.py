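"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ parsing goes through Biopython; tables are tab-separated with a
header row, UTF-8, no quoting, missing values as empty strings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .models import COMPETITOR, TARGET, MixtureDesign, ReferencePair


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA as an ordered mapping record-id -> uppercase sequence."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def write_pair_fasta(pairs: Sequence[ReferencePair], path: str | Path) -> None:
    """Two records per amplicon, ``<id>|target`` and ``<id>|competitor``,
    with ISV offsets, gene and copy class carried in the description."""
    with open(path, "w") as fh:
        for p in pairs:
            meta = "isv={} gene={} copy={}".format(
                ",".join(map(str, p.isv_positions)), p.gene_id or ".", p.copy_class
            )
            fh.write(f">{p.amplicon_id}|{TARGET} {meta}\n{p.target_seq}\n")
            fh.write(f">{p.amplicon_id}|{COMPETITOR} {meta}\n{p.competitor_seq}\n")


def read_pair_fasta(path: str | Path) -> list[ReferencePair]:
    """Inverse of :func:`write_pair_fasta`."""
    by_amp: dict[str, dict[str, str]] = {}
    meta: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"record {rec.id!r} lacks '|species' suffix")
        amp, species = rec.id.rsplit("|", 1)
        by_amp.setdefault(amp, {})[species] = str(rec.seq).upper()
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        meta.setdefault(amp, fields)
    pairs = []
    for amp, seqs in by_amp.items():
        if TARGET not in seqs or COMPETITOR not in seqs:
            raise ValueError(f"amplicon {amp!r} is missing one species record")
        fields = meta.get(amp, {})
        gene = fields.get("gene", "")
        pairs.append(
            ReferencePair.from_sequences(
                amp,
                seqs[TARGET],
                seqs[COMPETITOR],
                gene_id="" if gene == "." else gene,
                copy_class=fields.get("copy", "autosomal"),
            )
        )
    return pairs


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read id, uppercase sequence) from a Phred+33 FASTQ file."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield rec.id, str(rec.seq).upper()
    except ValueError as err:
        raise ValueError(f"malformed FASTQ record in {path}: {err}") from err


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, float_digits: int = 6) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format=f"%.{float_digits}g")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def write_designs(designs: Sequence[MixtureDesign], path: str | Path) -> None:
    payload = []
    for d in designs:
        entry = {"sample_id": d.sample_id, "group": d.group, "rep_set": d.rep_set}
        if d.group == "G":
            entry["human_fraction"] = float(d.human_fraction)
        else:
            entry["expression_profile"] = {k: float(v) for k, v in d.expression_profile.items()}
            entry["spikein_mass_ng"] = float(d.spikein_mass_ng)
        payload.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_designs(path: str | Path) -> list[MixtureDesign]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [MixtureDesign(**entry) for entry in payload]


def write_sample_sheet(rows: Sequence[Mapping], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "file"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet must contain columns {sorted(required)}")
    return df
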
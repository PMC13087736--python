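"""FASTA ingestion and histogram/report serialization."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO

from .spectrum import AbundanceHistogram

PathLike = Union[str, Path]


def read_fasta(path: PathLike, record_id: Optional[str] = None) -> str:
    """Sequence of one FASTA record, upper-cased.

    Multi-record files require an explicit ``record_id`` (records are never
    concatenated).  Non-ACGT characters such as N are retained; downstream
    spectrum construction skips windows containing them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is None:
        if len(records) > 1:
            ids = ", ".join(rec.id for rec in records)
            raise ValueError(
                f"{path} has {len(records)} records ({ids}); pass record_id"
            )
        rec = records[0]
    else:
        matches = [rec for rec in records if rec.id == record_id]
        if not matches:
            raise ValueError(f"record {record_id!r} not found in {path}")
        rec = matches[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise ValueError(f"record {rec.id!r} in {path} is empty")
    return seq


def write_histogram(hist: AbundanceHistogram, path: PathLike) -> None:
    """Serialize an abundance histogram as 2-column TSV.

    The header comment line carries k, L and L0; data lines are
    ``multiplicity<TAB>count`` in increasing multiplicity order.
    """
    lines = [f"#k={hist.k}\tL={hist.L}\tL0={hist.L0}", "multiplicity\tcount"]
    for i in sorted(hist.a):
        lines.append(f"{i}\t{hist.a[i]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_histogram(path: PathLike) -> AbundanceHistogram:
    """Parse a histogram TSV written by :func:`write_histogram`."""
    text = Path(path).read_text().strip().splitlines()
    if not text or not text[0].startswith("#"):
        raise ValueError(f"{path}: missing '#k=... L=... L0=...' header")
    meta = dict(
        part.split("=", 1) for part in text[0].lstrip("#").split("\t") if "=" in part
    )
    a = {}
    for line in text[1:]:
        if line.startswith("multiplicity"):
            continue
        i, c = line.split("\t")
        a[int(i)] = int(c)
    hist = AbundanceHistogram(
        k=int(meta["k"]), a=a, L=int(meta["L"]), L0=int(meta["L0"])
    )
    hist.validate()
    return hist


def to_jsonable(obj):
    """Recursively convert dataclasses / numpy scalars for json.dumps."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return {key: to_jsonable(val) for key, val in asdict(obj).items()}
    if isinstance(obj, dict):
        return {key: to_jsonable(val) for key, val in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(val) for val in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_report(report, path: PathLike) -> None:
    Path(path).write_text(json.dumps(to_jsonable(report), indent=2) + "\n")
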
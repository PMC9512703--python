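"""Format I/O: TSV tables, FASTA, GMT, TIFF, JSON and YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gmt",
    "write_gmt",
    "read_tiff",
    "write_tiff",
    "read_json",
    "write_json",
    "read_config",
    "write_config",
    "read_tsv",
    "write_tsv",
    "bundled_sequence",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in records.items()),
        str(path),
        "fasta",
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
        sets[fields[0]] = {m for m in fields[2:] if m}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + sorted(members)) + "\n")


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_tiff(array: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), array)


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def read_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="")


def bundled_sequence(accession: str = "P09651") -> str:
    """Sequence bundled with the package (currently human HNRNPA1)."""
    path = Path(__file__).parent / "data" / f"{accession}.fasta"
    if not path.exists():
        raise FileNotFoundError(f"no bundled sequence for {accession}")
    return next(iter(read_fasta(path).values()))
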
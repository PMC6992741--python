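"""Readers and writers for the interchange formats.

Tool outputs travel as a long-format TSV (``mirna_id, target_id, tool,
field, value``) so that adding a new upstream tool needs no schema change.
Interaction tables are TSV with ``mirna_id, target_id, label,
energy_kcal_mol``; sequences are FASTA. Undefined metric cells are written
as the literal string ``null``.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .datasets import InteractionRecord, TrainingSet
from .features import SUPPORTED_TOOLS, ToolRecord

__all__ = [
    "read_tool_table",
    "write_tool_table",
    "read_fasta",
    "write_fasta",
    "read_interactions",
    "write_interactions",
    "write_training_set",
    "config_hash",
]

TOOL_TABLE_COLUMNS = ("mirna_id", "target_id", "tool", "field", "value")
INTERACTION_COLUMNS = ("mirna_id", "target_id", "label", "energy_kcal_mol")

#: fields carried as strings in the long-format table
_STRING_FIELDS = {"seed_types", "category", "call"}


def _parse_value(field: str, raw: str, path, lineno: int):
    if field in _STRING_FIELDS:
        return raw
    try:
        if field in ("site_start", "site_end"):
            return int(raw)
        return float(raw)
    except ValueError:
        raise ValueError(
            f"{path}:{lineno}: cannot parse value {raw!r} for field {field!r}"
        ) from None


def read_tool_table(path: Union[str, Path]) -> list:
    """Parse the long-format tool-output TSV into :class:`ToolRecord` lists."""
    path = Path(path)
    grouped: dict = {}
    order: list = []
    with path.open() as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if tuple(header) != TOOL_TABLE_COLUMNS:
                    raise ValueError(
                        f"{path}:{lineno}: expected header {TOOL_TABLE_COLUMNS}, got {tuple(header)}"
                    )
                continue
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            mirna, target, tool, field, raw = parts
            if tool not in SUPPORTED_TOOLS:
                raise ValueError(
                    f"{path}:{lineno}: unknown tool {tool!r}; supported: {', '.join(SUPPORTED_TOOLS)}"
                )
            key = (mirna, target, tool)
            if key not in grouped:
                grouped[key] = {}
                order.append(key)
            grouped[key][field] = _parse_value(field, raw, path, lineno)
    return [
        ToolRecord(mirna_id=m, target_id=t, tool=tool, fields=grouped[(m, t, tool)])
        for (m, t, tool) in order
    ]


def _format_value(field: str, value) -> str:
    if field in _STRING_FIELDS:
        return str(value)
    if field in ("site_start", "site_end"):
        return str(int(value))
    return repr(float(value))


def write_tool_table(
    records: Iterable[ToolRecord],
    path: Union[str, Path],
    header_comment: Optional[str] = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(TOOL_TABLE_COLUMNS) + "\n")
        for rec in records:
            for field in sorted(rec.fields):
                fh.write(
                    "\t".join(
                        (
                            rec.mirna_id,
                            rec.target_id,
                            rec.tool,
                            field,
                            _format_value(field, rec.fields[field]),
                        )
                    )
                    + "\n"
                )


def read_fasta(path: Union[str, Path]) -> dict:
    """FASTA into an ordered id -> RNA-sequence map.

    IDs are the first whitespace-delimited token; sequences are uppercased
    with T mapped to U. Duplicate ids and empty records are errors.
    """
    out: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("T", "U")
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {rec.id!r} in {path}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict, path: Union[str, Path], width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_interactions(path: Union[str, Path]) -> list:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(INTERACTION_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"interaction table missing column(s): {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        energy = getattr(row, "energy_kcal_mol", None)
        records.append(
            InteractionRecord(
                str(row.mirna_id),
                str(row.target_id),
                str(row.label),
                None if energy is None or pd.isna(energy) else float(energy),
            )
        )
    return records


def _interactions_frame(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in records],
            "target_id": [r.target_id for r in records],
            "label": [r.label for r in records],
            "energy_kcal_mol": [r.energy for r in records],
        }
    )


def write_interactions(
    records: Sequence[InteractionRecord],
    path: Union[str, Path],
    header_comment: Optional[str] = None,
) -> None:
    _write_tsv(_interactions_frame(records), path, header_comment)


def write_training_set(
    ts: TrainingSet, path: Union[str, Path], header_comment: Optional[str] = None
) -> None:
    df = _interactions_frame(ts.records)
    df["mode"] = ts.mode
    _write_tsv(df, path, header_comment)


def _write_tsv(
    df: pd.DataFrame, path: Union[str, Path], header_comment: Optional[str] = None
) -> None:
    with Path(path).open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def config_hash(text: str) -> str:
    """Short stable hash naming the configuration in output headers."""
    return hashlib.sha256(text.encode()).hexdigest()[:12]
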
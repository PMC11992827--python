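"""Readers, writers and node-level screening filters for the exchange formats.

Every tabular format is TSV with a header row (UTF-8); protein sequences are
FASTA; configuration and reports are JSON.  Tables are carried in memory as
pandas DataFrames with a fixed, documented column order so that write/read
round-trips are lossless at printed precision.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("ctpdn")


class FormatError(ValueError):
    """A table or sequence file does not match the expected exchange format."""


#: canonical column rosters, one per table kind
TABLE_COLUMNS: dict[str, list[str]] = {
    "compounds": [
        "compound_id", "smiles", "ob", "dl",
        "admet_as", "admet_bbb", "admet_cyp2d6", "admet_hepatotoxicity", "admet_ppb",
    ],
    "docking": ["compound_id", "target_id", "s_i", "s_m", "success"],
    "ppi": ["target_a", "target_b", "combined_score"],
    "pathways": ["pathway_id", "name", "p_value", "q_value", "member_targets", "diseases"],
}

#: columns holding ';'-joined id lists
_LIST_COLUMNS = {"member_targets", "diseases"}


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table is missing column(s): {', '.join(missing)}")


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read one of the typed TSV tables; ``kind`` selects the column roster.

    An empty file yields an empty table (with a warning); a malformed row
    raises :class:`FormatError` carrying the offending line number.
    """
    columns = TABLE_COLUMNS[kind]
    path = Path(path)
    if path.stat().st_size == 0:
        logger.warning("%s: empty file, returning empty %s table", path, kind)
        return pd.DataFrame(columns=columns)
    try:
        df = pd.read_csv(path, sep="\t", dtype={c: str for c in _LIST_COLUMNS})
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed table: {exc}") from exc
    _require_columns(df, columns, kind)
    df = df[columns]
    if kind == "docking":
        df["success"] = df["success"].astype(bool)
        bad = df.index[df["success"] & ~(df["s_m"] > 0)]
        if len(bad):
            # header is line 1, first data row line 2
            raise FormatError(
                f"{path}: non-positive reference score s_m on line(s) "
                f"{', '.join(str(i + 2) for i in bad)}"
            )
    if kind == "ppi":
        bad = df.index[
            (df["target_a"] == df["target_b"])
            | ~((df["combined_score"] > 0) & (df["combined_score"] <= 1))
        ]
        if len(bad):
            raise FormatError(
                f"{path}: invalid PPI row(s) on line(s) "
                f"{', '.join(str(i + 2) for i in bad)} "
                "(self-loop or combined_score outside (0, 1])"
            )
    if kind == "compounds":
        dup = df["compound_id"][df["compound_id"].duplicated()].tolist()
        if dup:
            raise FormatError(f"{path}: duplicate compound ids: {', '.join(sorted(set(dup)))}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a typed table as TSV in the canonical column order."""
    columns = TABLE_COLUMNS[kind]
    _require_columns(df, columns, kind)
    df[columns].to_csv(path, sep="\t", index=False)


def split_ids(joined: str) -> list[str]:
    """Split a ';'-joined id list column value; empty string means empty set."""
    if not isinstance(joined, str) or joined == "":
        return []
    return [x for x in joined.split(";") if x]


def join_ids(ids) -> str:
    return ";".join(ids)


# ---------------------------------------------------------------------------
# node-level screening filters


def filter_compounds(
    table: pd.DataFrame, ob_min: float = 30.0, dl_min: float = 0.18
) -> pd.DataFrame:
    """Keep compounds with oral bioavailability >= ``ob_min`` (percent) and
    drug-likeness >= ``dl_min``; both boundaries inclusive, input order kept."""
    _require_columns(table, ["ob", "dl"], "compounds")
    if not (pd.api.types.is_numeric_dtype(table["ob"]) and pd.api.types.is_numeric_dtype(table["dl"])):
        raise FormatError("compound filter needs numeric 'ob' and 'dl' columns")
    mask = (table["ob"] >= ob_min) & (table["dl"] >= dl_min)
    return table[mask].reset_index(drop=True)


def filter_pathways(table: pd.DataFrame, p_max: float = 1e-8) -> pd.DataFrame:
    """Keep pathways with enrichment p-value strictly below ``p_max`` and a
    nonempty member-target list."""
    _require_columns(table, ["p_value", "member_targets"], "pathways")
    has_members = table["member_targets"].map(lambda v: len(split_ids(v)) > 0)
    out = table[(table["p_value"] < p_max) & has_members].reset_index(drop=True)
    if out.empty and not table.empty:
        logger.warning("pathway filter removed every pathway (p_max=%g)", p_max)
    return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{record id: sequence}`` mapping.

    Duplicate record ids are an error (the ids key every downstream join).
    """
    sequences: dict[str, str] = {}
    duplicates: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            duplicates.append(record.id)
        sequences[record.id] = str(record.seq)
    if duplicates:
        raise FormatError(f"{path}: duplicate FASTA ids: {', '.join(sorted(set(duplicates)))}")
    if not sequences:
        logger.warning("%s: no FASTA records found", path)
    return sequences


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# bundles and reports


def load_inputs(paths: dict[str, str | Path], config=None) -> dict[str, Any]:
    """Load every input named in ``paths`` into a typed-table bundle.

    Recognized keys: compounds, docking, ppi, pathways (TSV tables) and
    sequences (FASTA).  Unknown keys raise a :class:`FormatError`.
    """
    bundle: dict[str, Any] = {}
    for key, path in paths.items():
        if key in TABLE_COLUMNS:
            bundle[key] = read_table(path, key)
        elif key == "sequences":
            bundle[key] = read_fasta(path)
        else:
            raise FormatError(f"unknown input kind {key!r}")
    return bundle


def write_report(results: dict[str, Any], path: str | Path) -> None:
    """Serialize a results mapping to JSON (+inf encoded as the string 'inf')."""

    def _encode(obj):
        if isinstance(obj, float) and obj == float("inf"):
            return "inf"
        if isinstance(obj, dict):
            return {k: _encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_encode(v) for v in obj]
        return obj

    Path(path).write_text(json.dumps(_encode(results), indent=2, default=str) + "\n")
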
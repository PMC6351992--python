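"""Read and write the VSAC-style value-set export CSV dialect.

The Value Set Authority Center's "export value set results" feature emits
one row per code with columns for the code, its description, the code
system and version, the value set's OID and name. The exact header set has
varied across export vintages, so the reader matches header names
case-insensitively and requires only the code column; everything else is
optional provenance.
"""

from __future__ import annotations

import csv
import logging
from typing import Dict, List, Optional

import pandas as pd

from .errors import FormatError
from .valuesets import ExtensionalValueSet

logger = logging.getLogger(__name__)

#: canonical column names, in write order
_COLUMNS = (
    "Code",
    "Description",
    "Code System",
    "Code System Version",
    "OID",
    "Value Set Name",
)

_ALIASES: Dict[str, str] = {
    "code": "Code",
    "description": "Description",
    "descriptor": "Description",
    "code system": "Code System",
    "codesystem": "Code System",
    "code system version": "Code System Version",
    "codesystemversion": "Code System Version",
    "oid": "OID",
    "value set oid": "OID",
    "value set name": "Value Set Name",
    "valuesetname": "Value Set Name",
}


def _canonical(col: str) -> Optional[str]:
    return _ALIASES.get(col.strip().lower())


def read_vsac_export(path: str, provenance: str = "downloaded") -> ExtensionalValueSet:
    """Read an export CSV into an :class:`ExtensionalValueSet`.

    Only a code column is required. Duplicate codes collapse into the set
    with a logged warning; a file with zero data rows yields an empty set
    (with a warning) rather than an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    renames = {c: _canonical(c) for c in df.columns if _canonical(c)}
    df = df.rename(columns=renames)
    if "Code" not in df.columns:
        raise FormatError(f"{path}: no code column found (headers: {list(df.columns)})")

    codes = [c for c in df["Code"].astype(str) if c]
    concept_ids = set(codes)
    if len(concept_ids) < len(codes):
        logger.warning(
            "%s: %d duplicate code row(s) collapsed", path, len(codes) - len(concept_ids)
        )
    if not codes:
        logger.warning("%s: export has zero data rows; returning an empty set", path)

    def _first(col: str) -> str:
        if col in df.columns and len(df):
            return str(df[col].iloc[0])
        return ""

    return ExtensionalValueSet(
        name=_first("Value Set Name"),
        concept_ids=concept_ids,
        provenance=provenance,
        oid=_first("OID"),
        code_system_version=_first("Code System Version"),
    )


def write_vsac_export(
    evs: ExtensionalValueSet,
    path: str,
    labels: Optional[Dict[str, str]] = None,
    code_system: str = "SNOMEDCT",
) -> None:
    """Write a value set in the export dialect.

    One row per concept in deterministic lexicographic code order, RFC 4180
    quoting. ``labels`` optionally supplies per-code descriptions.
    """
    labels = labels or {}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(_COLUMNS)
        for code in sorted(evs.concept_ids):
            writer.writerow(
                [
                    code,
                    labels.get(code, ""),
                    code_system,
                    evs.code_system_version,
                    evs.oid,
                    evs.name,
                ]
            )
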
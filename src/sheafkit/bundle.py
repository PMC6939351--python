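"""Bundle IO: JSON space files, CSV section tables, and manifest round-trips.

A bundle directory holds ``space.json`` ({"points": [...], "opens": [[...]]}),
one RFC-4180 CSV per open set's table (header = sorted point labels), and a
``manifest.json`` mapping open-set keys to CSV paths.  Open-set keys join the
sorted labels with "+" ("C+L"); "EMPTY" is reserved for the empty set.
Loading a saved bundle reproduces an identical presheaf.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .errors import SchemaError
from .fixtures import Bundle
from .presheaf import Presheaf, SectionTable
from .topology import EMPTY_OPEN, FiniteSpace, OpenSet, make_space

logger = logging.getLogger("sheafkit")

__all__ = ["open_key", "parse_open_key", "load_space", "save_space",
           "load_table", "save_table", "load_bundle", "save_bundle"]

MANIFEST_NAME = "manifest.json"
SPACE_NAME = "space.json"


def open_key(U: OpenSet) -> str:
    return "+".join(sorted(U)) if U else "EMPTY"


def parse_open_key(key: str) -> OpenSet:
    return EMPTY_OPEN if key == "EMPTY" else OpenSet(key.split("+"))


def save_space(space: FiniteSpace, path: Union[str, Path]) -> None:
    doc = {
        "points": sorted(space.points),
        "opens": [sorted(U) for U in space.opens_sorted()],
    }
    Path(path).write_text(json.dumps(doc, ensure_ascii=False, indent=1) + "\n",
                          encoding="utf-8")


def load_space(path: Union[str, Path]) -> FiniteSpace:
    """Load and validate a space; ∅ and the full set are added if omitted."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: not valid JSON: {e}") from None
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: / must be an object")
    for key in ("points", "opens"):
        if key not in doc:
            raise SchemaError(f"{path}: /{key} is missing")
    if not isinstance(doc["points"], list) or not all(
        isinstance(p, str) for p in doc["points"]
    ):
        raise SchemaError(f"{path}: /points must be a list of strings")
    if not isinstance(doc["opens"], list) or not all(
        isinstance(o, list) for o in doc["opens"]
    ):
        raise SchemaError(f"{path}: /opens must be a list of lists")
    opens = [OpenSet(o) for o in doc["opens"]]
    full = OpenSet(doc["points"])
    for missing in (EMPTY_OPEN, full):
        if missing not in opens:
            logger.info("adding omitted open {%s} to %s", missing.label, path)
            opens.append(missing)
    return make_space(doc["points"], opens)


def save_table(table: SectionTable, path: Union[str, Path]) -> None:
    table.to_frame().to_csv(path, index=False, encoding="utf-8")


def load_table(path: Union[str, Path], expected_open: OpenSet = None) -> SectionTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    cols = list(df.columns)
    if cols != sorted(cols):
        logger.info("canonicalizing unsorted header %s in %s", cols, path)
    if expected_open is not None and OpenSet(cols) != expected_open:
        raise SchemaError(
            f"{path}: header {sorted(cols)} does not match the open "
            f"{{{expected_open.label}}}"
        )
    return SectionTable.from_frame(df)


def save_bundle(presheaf: Presheaf, dirpath: Union[str, Path],
                provenance: dict = None) -> Path:
    """Write space.json, one CSV per non-empty open, and manifest.json."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    save_space(presheaf.space, d / SPACE_NAME)
    tables = {}
    for U in presheaf.space.opens_sorted():
        if U == EMPTY_OPEN:
            continue  # F(∅) is the terminal table by convention
        key = open_key(U)
        fname = f"{key}.csv"
        save_table(presheaf.table(U), d / fname)
        tables[key] = fname
    manifest = {
        "space": SPACE_NAME,
        "tables": tables,
        "provenance": provenance or {"source": "user"},
    }
    (d / MANIFEST_NAME).write_text(
        json.dumps(manifest, ensure_ascii=False, indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return d / MANIFEST_NAME


def load_bundle(path: Union[str, Path]) -> Bundle:
    """Load a manifest (or its directory) back into a presheaf bundle.

    The loaded tables are attached as-is (restrictions are projections); use
    :func:`sheafkit.presheaf.check_functoriality` to confirm projection
    closure if the bundle did not come from :func:`save_bundle`.
    """
    p = Path(path)
    if p.is_dir():
        p = p / MANIFEST_NAME
    try:
        manifest = json.loads(p.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise SchemaError(f"{p}: not valid JSON: {e}") from None
    if not isinstance(manifest, dict):
        raise SchemaError(f"{p}: / must be an object")
    for key in ("space", "tables"):
        if key not in manifest:
            raise SchemaError(f"{p}: /{key} is missing")
    if not isinstance(manifest["tables"], dict):
        raise SchemaError(f"{p}: /tables must be an object")
    space = load_space(p.parent / manifest["space"])
    tables = {}
    restrictions = {}
    for key, fname in sorted(manifest["tables"].items()):
        U = parse_open_key(key)
        if U not in space.opens:
            from .errors import NotOpenError

            raise NotOpenError(
                f"{p}: /tables/{key}: {{{U.label}}} is not open in the space"
            )
        tables[U] = load_table(p.parent / fname, expected_open=U)
    for U in space.opens:
        if U not in tables:
            tables[U] = (
                SectionTable.terminal() if U == EMPTY_OPEN else SectionTable.empty(U)
            )
    for V in space.opens:
        for U in space.opens:
            if U <= V:
                restrictions[(V, U)] = {s: s.project(U) for s in tables[V].sections}
    presheaf = Presheaf(space, tables, restrictions)
    return Bundle(presheaf=presheaf, provenance=manifest.get("provenance",
                                                             {"source": "user"}))
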
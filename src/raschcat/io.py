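"""Plain-text readers and writers: item banks, response matrices, cutoffs, logs.

All formats are UTF-8 CSV or JSON.  The item-bank format is
``item_id,domain,difficulty[,age_min_months,age_max_months]`` with
difficulties as decimal logits; writing uses ``repr`` precision so a
write-read round trip reproduces every difficulty exactly as text.
Validation failures name the offending row number (1-based, counting the
header as row 1).
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .engine import CatResult
from .rasch import Item, ItemBank
from .strata import AgeCutoffTable

__all__ = [
    "read_item_bank",
    "write_item_bank",
    "read_response_matrix",
    "write_response_matrix",
    "read_truths",
    "write_truths",
    "read_age_cutoffs",
    "write_session_log",
    "fixture_bank",
    "default_age_cutoffs",
]

_BANK_REQUIRED = ("item_id", "domain", "difficulty")
_BANK_OPTIONAL = ("age_min_months", "age_max_months")


def read_item_bank(path: str | Path) -> ItemBank:
    """Load a calibrated item bank from CSV, validating as it reads."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = tuple(reader.fieldnames or ())
        missing = [c for c in _BANK_REQUIRED if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        unknown = [c for c in header if c not in _BANK_REQUIRED + _BANK_OPTIONAL]
        if unknown:
            raise ValueError(f"{path}: unknown column(s) {unknown}")
        items: list[Item] = []
        seen: set[str] = set()
        for rownum, row in enumerate(reader, start=2):
            item_id = (row["item_id"] or "").strip()
            domain = (row["domain"] or "").strip()
            if not item_id or not domain:
                raise ValueError(f"{path}: row {rownum}: empty item_id or domain")
            if item_id in seen:
                raise ValueError(f"{path}: row {rownum}: duplicate item_id {item_id!r}")
            seen.add(item_id)
            try:
                difficulty = float(row["difficulty"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {rownum}: unparseable difficulty {row['difficulty']!r}"
                ) from None
            ages = {}
            for col in _BANK_OPTIONAL:
                raw = (row.get(col) or "").strip()
                if raw:
                    try:
                        ages[col] = float(raw)
                    except ValueError:
                        raise ValueError(
                            f"{path}: row {rownum}: unparseable {col} {raw!r}"
                        ) from None
            items.append(Item(item_id, domain, difficulty, **ages))
    if not items:
        raise ValueError(f"{path}: bank file contains no items")
    return ItemBank(items)


def write_item_bank(bank: ItemBank, path: str | Path) -> None:
    """Write a bank to CSV with full-precision decimal difficulties."""
    path = Path(path)
    has_ages = any(
        it.age_min_months is not None or it.age_max_months is not None for it in bank
    )
    cols = list(_BANK_REQUIRED) + (list(_BANK_OPTIONAL) if has_ages else [])
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for it in bank:
            row = [it.item_id, it.domain, repr(it.difficulty)]
            if has_ages:
                row += [
                    "" if it.age_min_months is None else repr(it.age_min_months),
                    "" if it.age_max_months is None else repr(it.age_max_months),
                ]
            writer.writerow(row)


def read_response_matrix(path: str | Path) -> pd.DataFrame:
    """Read a persons × items 0/1 matrix (empty cells = missing -> NaN)."""
    df = pd.read_csv(path, index_col="person_id")
    vals = df.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-binary response {vals[r, c]!r} for person "
            f"{df.index[r]!r}, item {df.columns[c]!r}"
        )
    return df


def write_response_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    # integers where observed, blank where missing
    out = out.astype("Int64")
    out.to_csv(path, index_label="person_id")


def read_truths(path: str | Path) -> pd.DataFrame:
    """Read a per-person true-measure table: person_id plus one column per domain."""
    return pd.read_csv(path, index_col="person_id")


def write_truths(truths: pd.DataFrame, path: str | Path) -> None:
    truths.to_csv(path, index_label="person_id")


def read_age_cutoffs(path: str | Path) -> AgeCutoffTable:
    """Read an age/domain cutoff table: ``age_months,domain,cutoff_logit``."""
    path = Path(path)
    rows = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = ("age_months", "domain", "cutoff_logit")
        missing = [c for c in required if c not in (reader.fieldnames or ())]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
        for rownum, row in enumerate(reader, start=2):
            try:
                rows.append(
                    (float(row["age_months"]), row["domain"].strip(), float(row["cutoff_logit"]))
                )
            except (TypeError, ValueError):
                raise ValueError(f"{path}: row {rownum}: unparseable values") from None
    return AgeCutoffTable(rows)


def write_session_log(result: CatResult, path: str | Path) -> None:
    """Write one adaptive session as JSON: per-step records plus a final block."""
    final = {
        d: {
            "theta": result.profile.theta_by_domain[d],
            "sem": (result.profile.sem_by_domain or {}).get(d),
            "n_items": result.n_items_by_domain[d],
            "stop_reason": result.stop_reason_by_domain[d],
        }
        for d in result.profile.domains
    }
    payload = {"steps": result.transcript, "final": final}
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def fixture_bank() -> ItemBank:
    """The packaged synthetic 75-item, five-domain bank.

    A synthetic stand-in emulating the published calibrated pool: domain
    sizes 11/13/19/18/14 with difficulties uniform over −7.35..8.03 logits
    (frozen seed).  See ``data/music_bank_synthetic.csv``.
    """
    with resources.as_file(
        resources.files("raschcat") / "data" / "music_bank_synthetic.csv"
    ) as p:
        return read_item_bank(p)


def default_age_cutoffs() -> AgeCutoffTable:
    """The packaged cutoff table (the published 24-month row only)."""
    with resources.as_file(
        resources.files("raschcat") / "data" / "age_cutoffs.csv"
    ) as p:
        return read_age_cutoffs(p)
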
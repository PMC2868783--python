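"""Tabular I/O and machine-readable reports.

Datasets are tiny (titrations of at most a few dozen points), so CSV is
the only interchange format: comma-delimited, "." decimal separator,
UTF-8, header required.  Reports are JSON with stable keys and a version
stamp.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from .errors import ValidationError

__all__ = ["TitrationDataset", "read_titration_csv", "write_report"]

log = logging.getLogger("bilispec")

#: Recognized observable kinds and their CSV value-column names.
OBSERVABLE_COLUMNS = {"nbar": "nbar", "delta_eps": "delta_eps", "theta": "theta"}


@dataclass(frozen=True)
class TitrationDataset:
    """Ordered (pH, observable) pairs with metadata.

    ``observable_kind`` is one of ``nbar`` (vesicle uptake), ``delta_eps``
    (cyclodextrin CD) or ``theta`` (bile-salt CD, 10^3 units).  Rows are
    sorted by pH.  ``conc_uM`` optionally carries a per-row total UCB
    concentration; ``metadata`` keeps totals, units and provenance tags.
    """

    observable_kind: str
    ph: tuple[float, ...]
    values: tuple[float, ...]
    conc_um: tuple[float, ...] | None = None
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.observable_kind not in OBSERVABLE_COLUMNS:
            raise ValidationError(
                f"unknown observable kind {self.observable_kind!r}"
            )
        if len(self.ph) != len(self.values):
            raise ValidationError("pH and value columns differ in length")
        if any(not _finite(v) for v in (*self.ph, *self.values)):
            raise ValidationError("pH and observable values must be finite")
        if len(self.ph) > 1 and any(
            b <= a for a, b in zip(self.ph, self.ph[1:])
        ):
            raise ValidationError("pH values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.ph)

    def rows(self):
        return list(zip(self.ph, self.values))


def _finite(v: float) -> bool:
    import math

    return math.isfinite(v)


def read_titration_csv(path, observable_kind: str | None = None) -> TitrationDataset:
    """Load and validate a titration table.

    The file must have a ``pH`` column and exactly one recognized
    observable column (``nbar``, ``delta_eps`` or ``theta``) unless
    ``observable_kind`` picks one explicitly.  Rows are sorted by pH;
    unknown columns are preserved in ``metadata['extra_columns']``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file is empty or has no header")
    if "pH" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'pH'")
    if observable_kind is None:
        present = [k for k in OBSERVABLE_COLUMNS if k in df.columns]
        if len(present) != 1:
            raise ValidationError(
                f"{path}: expected exactly one observable column "
                f"({', '.join(OBSERVABLE_COLUMNS)}), found {present or 'none'}"
            )
        observable_kind = present[0]
    col = OBSERVABLE_COLUMNS.get(observable_kind)
    if col is None:
        raise ValidationError(f"unknown observable kind {observable_kind!r}")
    if col not in df.columns:
        raise ValidationError(f"{path}: missing required column '{col}'")
    for name in ("pH", col):
        bad = pd.to_numeric(df[name], errors="coerce").isna() & df[name].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValidationError(
                f"{path}: non-numeric value in column '{name}' at line {line}"
            )
        df[name] = pd.to_numeric(df[name])
    df = df.sort_values("pH", kind="stable").reset_index(drop=True)
    extra = [c for c in df.columns if c not in ("pH", col, "conc_uM")]
    conc = tuple(float(v) for v in df["conc_uM"]) if "conc_uM" in df else None
    return TitrationDataset(
        observable_kind=observable_kind,
        ph=tuple(float(v) for v in df["pH"]),
        values=tuple(float(v) for v in df[col]),
        conc_um=conc,
        metadata={
            "source": str(path),
            "extra_columns": {c: df[c].tolist() for c in extra},
        },
    )


def write_report(results: Mapping[str, Any], path) -> None:
    """Write a JSON report with stable key order and a version stamp."""
    from . import __version__

    payload = {"bilispec_version": __version__}
    payload.update(_jsonable(results))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    text = json.dumps(payload, indent=2, sort_keys=True)
    path.write_text(text + "\n", encoding="utf-8")
    for key, value in payload.items():
        log.info("%s = %s", key, value)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj
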
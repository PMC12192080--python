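"""Reading and writing cohort tables and clock-model documents.

Cohorts travel as comma-separated UTF-8 with a header row: the mandatory
columns ``sample_id``, ``age`` and the six panel sites, then optional
clinical columns (``group``, ``amh``, ``bmi``, ``art_used``,
``art_pregnancy``).  Clock models travel as JSON with numbers at full
precision, so write followed by read is bit-exact.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .cohort import Cohort, ClockModel, FitMetrics, GROUPS, MethylationProfile
from .errors import IntegrityError, SchemaError, ValidationError
from .sites import BUILTIN_SITES, SITE_KEYS

__all__ = ["read_cohort", "write_cohort", "read_clock", "write_clock"]

MANDATORY_COLUMNS = ("sample_id", "age") + SITE_KEYS
CLINICAL_COLUMNS = ("group", "amh", "bmi", "art_used", "art_pregnancy")
_BOOL = {"true": True, "false": False}


def _parse_bool(raw: str, column: str, sample: str) -> bool:
    try:
        return _BOOL[raw.strip().lower()]
    except KeyError:
        raise ValidationError(
            f"sample {sample}: column {column} must be true/false, got {raw!r}"
        ) from None


def read_cohort(path: str | Path, require_clinical: bool = False) -> Cohort:
    """Read a cohort CSV, validating schema and value ranges.

    Parameters
    ----------
    path:
        CSV file with the dialect described in the module docstring.
    require_clinical:
        When true, the ``group``, ``amh`` and ``bmi`` columns must be
        present (ART flags stay optional, as they are implied by group
        membership).

    Raises
    ------
    SchemaError
        A mandatory (or required clinical) column is absent.
    ValidationError
        A value violates its domain (methylation outside [0, 100],
        fractional age, malformed boolean), naming sample and column.
    IntegrityError
        Duplicate ``sample_id``.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for column in MANDATORY_COLUMNS:
        if column not in frame.columns:
            raise SchemaError(f"{path.name}: missing mandatory column {column!r}")
    if require_clinical:
        for column in ("group", "amh", "bmi"):
            if column not in frame.columns:
                raise SchemaError(
                    f"{path.name}: clinical column {column!r} required but absent"
                )
    profiles: list[MethylationProfile] = []
    for _, row in frame.iterrows():
        sample = row["sample_id"].strip()
        raw_age = row["age"].strip()
        try:
            age_f = float(raw_age)
        except ValueError:
            raise ValidationError(
                f"sample {sample}: age {raw_age!r} is not numeric"
            ) from None
        if not age_f.is_integer():
            raise ValidationError(
                f"sample {sample}: age {raw_age} is not a whole number of years"
            )
        methylation: dict[str, float | None] = {}
        for site in SITE_KEYS:
            raw = row[site].strip()
            if raw == "":
                methylation[site] = None
                continue
            try:
                value = float(raw)
            except ValueError:
                raise ValidationError(
                    f"sample {sample}: methylation {raw!r} at {site} is not numeric"
                ) from None
            if not 0.0 <= value <= 100.0:
                raise ValidationError(
                    f"sample {sample}: methylation {value} at {site} outside [0, 100]"
                )
            methylation[site] = value

        def _opt_float(column: str) -> float | None:
            if column not in frame.columns:
                return None
            raw = row[column].strip()
            if raw == "":
                return None
            try:
                return float(raw)
            except ValueError:
                raise ValidationError(
                    f"sample {sample}: column {column} value {raw!r} is not numeric"
                ) from None

        def _opt_bool(column: str) -> bool | None:
            if column not in frame.columns:
                return None
            raw = row[column].strip()
            if raw == "":
                return None
            return _parse_bool(raw, column, sample)

        group = None
        if "group" in frame.columns:
            raw = row["group"].strip()
            group = raw if raw else None
            if group is not None and group not in GROUPS:
                raise ValidationError(
                    f"sample {sample}: group {group!r} not one of {GROUPS}"
                )
        profiles.append(
            MethylationProfile(
                sample_id=sample,
                age=int(age_f),
                methylation=methylation,
                group=group,
                amh=_opt_float("amh"),
                bmi=_opt_float("bmi"),
                art_used=_opt_bool("art_used"),
                art_pregnancy=_opt_bool("art_pregnancy"),
            )
        )
    return Cohort(profiles, label=path.stem)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to CSV with a deterministic column order.

    Clinical columns are emitted only when at least one profile carries the
    field, so purely methylation cohorts stay minimal.  Two writes of the
    same cohort produce byte-identical files.
    """
    path = Path(path)
    columns = list(MANDATORY_COLUMNS)
    for column in CLINICAL_COLUMNS:
        if any(getattr(p, column) is not None for p in cohort):
            columns.append(column)
    lines = [",".join(columns)]
    for p in cohort:
        row = []
        for column in columns:
            if column == "sample_id":
                row.append(p.sample_id)
            elif column == "age":
                row.append(str(p.age))
            elif column in BUILTIN_SITES:
                row.append(_fmt(p.methylation.get(column)))
            else:
                row.append(_fmt(getattr(p, column)))
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_clock(model: ClockModel, path: str | Path) -> Path:
    """Serialize a clock model to JSON at full float precision."""
    path = Path(path)
    doc: dict = {
        "name": model.name,
        "intercept": model.intercept,
        "coefficients": dict(model.coefficients),
    }
    if model.coef_se is not None:
        doc["coef_se"] = dict(model.coef_se)
    if model.metrics is not None:
        doc["metrics"] = model.metrics.to_dict()
    path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    return path


def read_clock(path: str | Path) -> ClockModel:
    """Read a clock-model JSON document, validating keys and numbers."""
    path = Path(path)
    doc = json.loads(path.read_text(encoding="utf-8"))
    for field in ("name", "intercept", "coefficients"):
        if field not in doc:
            raise SchemaError(f"{path.name}: missing field {field!r}")
    coefficients = doc["coefficients"]
    if not isinstance(coefficients, dict) or not coefficients:
        raise SchemaError(f"{path.name}: coefficients must be a non-empty object")
    for key, value in coefficients.items():
        if key not in BUILTIN_SITES:
            raise SchemaError(f"{path.name}: unknown site key {key!r}")
        if not isinstance(value, (int, float)) or isinstance(value, bool) or not math.isfinite(value):
            raise ValidationError(
                f"{path.name}: coefficient for {key} is not a finite number"
            )
    intercept = doc["intercept"]
    if not isinstance(intercept, (int, float)) or isinstance(intercept, bool):
        raise ValidationError(f"{path.name}: intercept is not numeric")
    metrics = None
    if doc.get("metrics") is not None:
        metrics = FitMetrics.from_dict(doc["metrics"])
    return ClockModel(
        name=doc["name"],
        intercept=float(intercept),
        coefficients={k: float(v) for k, v in coefficients.items()},
        coef_se=(
            {k: float(v) for k, v in doc["coef_se"].items()}
            if doc.get("coef_se") is not None
            else None
        ),
        metrics=metrics,
    )
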
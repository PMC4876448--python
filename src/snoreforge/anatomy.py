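"""Subject anatomy records and derived airway geometry.

The upper airway is treated as a single collapsible tube running from the
velum to the glottis.  Three bedside measurements parameterize it:

* ``nc`` — neck circumference at the cricothyroid level (cm),
* ``ua_xsa`` — mean upper-airway cross-sectional area (cm²),
* ``ua_length`` — velum-to-glottis length (cm).

From these the tube radius, the neck radius, and the tissue-wall thickness
are derived by treating both the airway lumen and the neck as circles:

    T_r = sqrt(UA-XSA / pi),   N_r = NC / (2*pi),   h = N_r - T_r.

Measurements are accepted in the clinical units above (cm, cm²); all derived
geometry is stored in SI (m, m²) for use by the acoustic model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

__all__ = [
    "SubjectAnatomy",
    "AirwayGeometry",
    "ValidationError",
    "GeometryError",
    "SchemaError",
    "derive_geometry",
    "read_cohort",
    "write_cohort",
]

#: canonical cohort-file column order
COHORT_COLUMNS = [
    "subject_id",
    "nc_cm",
    "ua_xsa_cm2",
    "ua_length_cm",
    "nc_after_cm",
    "ua_xsa_after_cm2",
    "ahi",
    "pitch_hz",
]

_MANDATORY = ["nc_cm", "ua_xsa_cm2", "ua_length_cm"]


class ValidationError(ValueError):
    """A measurement violates its physical range."""


class GeometryError(ValueError):
    """Derived geometry is unphysical (airway wider than neck)."""


class SchemaError(ValueError):
    """A cohort file is missing mandatory columns."""


@dataclass
class SubjectAnatomy:
    """Raw per-subject measurements, optionally paired before/after sleep.

    ``ahi`` is the apnea–hypopnea index (events/hour) and ``pitch_hz`` the
    subject's snore fundamental frequency; both are optional metadata that
    downstream stages may use (the pitch parameterizes the source model).
    """

    subject_id: str
    nc: float  # neck circumference, cm
    ua_xsa: float  # airway cross-sectional area, cm^2
    ua_length: float  # velum-to-glottis length, cm
    nc_after: float | None = None
    ua_xsa_after: float | None = None
    ahi: float | None = None
    pitch_hz: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("nc", "ua_xsa", "ua_length"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"subject {self.subject_id!r}: {name} must be positive, got {v!r}"
                )
        for name in ("nc_after", "ua_xsa_after"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"subject {self.subject_id!r}: {name} must be positive, got {v!r}"
                )
        if self.ahi is not None and self.ahi < 0:
            raise ValidationError(
                f"subject {self.subject_id!r}: ahi must be >= 0, got {self.ahi!r}"
            )

    @property
    def has_after_sleep(self) -> bool:
        return self.nc_after is not None and self.ua_xsa_after is not None


@dataclass(frozen=True)
class AirwayGeometry:
    """Derived airway geometry in SI units.

    ``tube_radius_m`` (T_r) and ``neck_radius_m`` (N_r) are the lumen and
    neck radii; ``wall_thickness_m`` (h = N_r − T_r) is the tissue layer the
    wall branch of the circuit models.  ``area_m2``, ``length_m`` and
    ``circumference_m`` (S = 2π·T_r) feed the per-element formulas.
    """

    tube_radius_m: float
    neck_radius_m: float
    wall_thickness_m: float
    area_m2: float
    length_m: float
    circumference_m: float


def derive_geometry(
    subject: SubjectAnatomy, use_after_sleep: bool = False
) -> AirwayGeometry:
    """Derive the SI airway geometry for one subject.

    Parameters
    ----------
    subject
        Validated anatomy record.
    use_after_sleep
        If True, parameterize the tube from the after-sleep measurements
        (``nc_after``, ``ua_xsa_after``); length is assumed unchanged.

    Raises
    ------
    ValidationError
        If after-sleep fields are requested but absent.
    GeometryError
        If the derived neck radius does not exceed the tube radius.
    """
    if use_after_sleep:
        if not subject.has_after_sleep:
            raise ValidationError(
                f"subject {subject.subject_id!r}: after-sleep measurements absent"
            )
        nc_cm, xsa_cm2 = subject.nc_after, subject.ua_xsa_after
    else:
        nc_cm, xsa_cm2 = subject.nc, subject.ua_xsa

    t_r_cm = math.sqrt(xsa_cm2 / math.pi)
    n_r_cm = nc_cm / (2.0 * math.pi)
    h_cm = n_r_cm - t_r_cm
    if h_cm <= 0:
        raise GeometryError(
            f"subject {subject.subject_id!r}: airway wider than neck "
            f"(T_r = {t_r_cm:.3f} cm >= N_r = {n_r_cm:.3f} cm)"
        )
    t_r = t_r_cm * 1e-2
    return AirwayGeometry(
        tube_radius_m=t_r,
        neck_radius_m=n_r_cm * 1e-2,
        wall_thickness_m=h_cm * 1e-2,
        area_m2=xsa_cm2 * 1e-4,
        length_m=subject.ua_length * 1e-2,
        circumference_m=2.0 * math.pi * t_r,
    )


def _opt(value: Any) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)


def _record_from_mapping(row: dict[str, Any], index: Any) -> SubjectAnatomy:
    known = set(COHORT_COLUMNS)
    meta = {k: v for k, v in row.items() if k not in known}
    try:
        return SubjectAnatomy(
            subject_id=str(row.get("subject_id", index)),
            nc=float(row["nc_cm"]),
            ua_xsa=float(row["ua_xsa_cm2"]),
            ua_length=float(row["ua_length_cm"]),
            nc_after=_opt(row.get("nc_after_cm")),
            ua_xsa_after=_opt(row.get("ua_xsa_after_cm2")),
            ahi=_opt(row.get("ahi")),
            pitch_hz=_opt(row.get("pitch_hz")),
            metadata=meta,
        )
    except ValidationError as exc:
        raise ValidationError(f"row {index}: {exc}") from exc


def read_cohort(path: str | Path) -> list[SubjectAnatomy]:
    """Read a cohort file (CSV with header, or JSON list of objects).

    Unknown columns are preserved on each record's ``metadata``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise SchemaError(f"{path}: JSON cohort must be a list of objects")
    else:
        rows = pd.read_csv(path).to_dict(orient="records")
    if rows:
        missing = [c for c in _MANDATORY if c not in rows[0]]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return [_record_from_mapping(row, i) for i, row in enumerate(rows)]


def write_cohort(subjects: list[SubjectAnatomy], path: str | Path) -> None:
    """Write records as CSV or JSON (by extension); round-trips read_cohort."""
    path = Path(path)
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "nc_cm": s.nc,
                "ua_xsa_cm2": s.ua_xsa,
                "ua_length_cm": s.ua_length,
                "nc_after_cm": s.nc_after,
                "ua_xsa_after_cm2": s.ua_xsa_after,
                "ahi": s.ahi,
                "pitch_hz": s.pitch_hz,
                **s.metadata,
            }
        )
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows).to_csv(path, index=False)
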
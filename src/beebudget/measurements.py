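"""Geometric body-size estimation from linear caliper measurements.

Traditional bee biophysics approximates the three tagmata as ideal
solids — the head as a cylinder, the mesosoma as a sphere, and the
metasoma as a cylinder joined to a cone — and derives surface area and
volume from six caliper measurements:

1. head width at the widest point (``m1``)
2. head thickness at the thickest point (``m2``)
3. mesosoma width at the widest point (``m3``)
4. metasoma width at the widest point (``m4``)
5. tergite 1–3 span (``m5``)
6. tergite 4–6 span (4–7 for males) (``m6``)

All lengths are millimetres; areas are mm² and volumes mm³.

The mapping of head measurements onto the cylinder is a convention: by
default the head thickness (the smaller, more circular cross-section)
is the cylinder diameter and the head width is the axis length, and the
head cylinder is closed (both end caps counted).  The metasoma solid
counts the cylinder lateral surface, one anterior end cap, and the cone
lateral surface; the internal cylinder–cone junction disc is never part
of the external surface.  Both conventions are configurable via
:class:`EstimationConvention`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

import pandas as pd

__all__ = [
    "Caste",
    "Tagma",
    "LinearMeasurements",
    "SolidEstimate",
    "SizeRecord",
    "EstimationConvention",
    "MeasurementError",
    "estimate_head",
    "estimate_mesosoma",
    "estimate_metasoma",
    "estimate_specimen",
    "estimate_table",
    "read_measurements",
    "size_records_to_frame",
]

#: Upper plausibility bound (mm) used to catch unit mistakes; bees are
#: well under 40 mm, so anything at 100 mm or more was probably entered
#: in micrometres or as a raw pixel count.
MAX_LENGTH_MM = 100.0


class MeasurementError(ValueError):
    """Raised when a linear measurement fails validation."""


class Caste(str, Enum):
    WORKER = "worker"
    QUEEN = "queen"
    DRONE = "drone"


class Tagma(str, Enum):
    HEAD = "head"
    MESOSOMA = "mesosoma"
    METASOMA = "metasoma"


def _check_length(name: str, value: float, *, allow_zero: bool = False) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise MeasurementError(f"{name} must be finite, got {value!r}")
    if allow_zero:
        if value < 0:
            raise MeasurementError(f"{name} must be >= 0 mm, got {value}")
    elif value <= 0:
        raise MeasurementError(f"{name} must be > 0 mm, got {value}")
    if value >= MAX_LENGTH_MM:
        raise MeasurementError(
            f"{name} = {value} mm is implausibly large (>= {MAX_LENGTH_MM} mm); "
            "check units"
        )
    return value


@dataclass(frozen=True)
class LinearMeasurements:
    """The six caliper measurements for one specimen (mm).

    The caste fixes which tergite the posterior metasoma span ends on
    (tergite 6 for females, 7 for males) but enters no formula.
    """

    specimen_id: str
    head_width_mm: float
    head_thickness_mm: float
    mesosoma_width_mm: float
    metasoma_width_mm: float
    metasoma_anterior_length_mm: float
    metasoma_posterior_length_mm: float
    caste: Caste = Caste.WORKER

    def __post_init__(self) -> None:
        object.__setattr__(self, "caste", Caste(self.caste))
        for name in (
            "head_width_mm",
            "head_thickness_mm",
            "mesosoma_width_mm",
            "metasoma_width_mm",
            "metasoma_anterior_length_mm",
            "metasoma_posterior_length_mm",
        ):
            object.__setattr__(self, name, _check_length(name, getattr(self, name)))

    def scaled(self, k: float) -> "LinearMeasurements":
        """All six measurements multiplied by ``k`` (isometric rescale)."""
        return replace(
            self,
            head_width_mm=self.head_width_mm * k,
            head_thickness_mm=self.head_thickness_mm * k,
            mesosoma_width_mm=self.mesosoma_width_mm * k,
            metasoma_width_mm=self.metasoma_width_mm * k,
            metasoma_anterior_length_mm=self.metasoma_anterior_length_mm * k,
            metasoma_posterior_length_mm=self.metasoma_posterior_length_mm * k,
        )


@dataclass(frozen=True)
class EstimationConvention:
    """Configurable choices the solid-approximation leaves open.

    head_diameter
        Which head measurement is the cylinder diameter: ``"thickness"``
        (default; the axis is then the head width) or ``"width"``.
    head_capped
        Count both end caps of the head cylinder (default True).
    metasoma_anterior_cap
        Count the anterior end cap of the metasoma cylinder (default
        True).  The cylinder–cone junction disc is internal and is never
        counted regardless of this flag.
    """

    head_diameter: str = "thickness"
    head_capped: bool = True
    metasoma_anterior_cap: bool = True

    def __post_init__(self) -> None:
        if self.head_diameter not in ("thickness", "width"):
            raise ValueError(
                "head_diameter must be 'thickness' or 'width', "
                f"got {self.head_diameter!r}"
            )


DEFAULT_CONVENTION = EstimationConvention()


@dataclass(frozen=True)
class SolidEstimate:
    """Surface area and volume of one tagma under its solid assumption."""

    tagma: Tagma
    surface_area_mm2: float
    volume_mm3: float
    solid_kind: str

    def __post_init__(self) -> None:
        if self.surface_area_mm2 <= 0 or self.volume_mm3 <= 0:
            raise MeasurementError(
                f"{self.tagma.value}: surface area and volume must be positive"
            )


@dataclass(frozen=True)
class SizeRecord:
    """Per-tagma estimates plus whole-body sums for one specimen."""

    specimen_id: str
    method: str
    head: SolidEstimate
    mesosoma: SolidEstimate
    metasoma: SolidEstimate
    summed_surface_area_mm2: float = field(init=False)
    summed_volume_mm3: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "summed_surface_area_mm2",
            self.head.surface_area_mm2
            + self.mesosoma.surface_area_mm2
            + self.metasoma.surface_area_mm2,
        )
        object.__setattr__(
            self,
            "summed_volume_mm3",
            self.head.volume_mm3 + self.mesosoma.volume_mm3 + self.metasoma.volume_mm3,
        )

    def tagma(self, tagma: Tagma | str) -> SolidEstimate:
        return {
            Tagma.HEAD: self.head,
            Tagma.MESOSOMA: self.mesosoma,
            Tagma.METASOMA: self.metasoma,
        }[Tagma(tagma)]


def estimate_head(
    head_width_mm: float,
    head_thickness_mm: float,
    convention: EstimationConvention = DEFAULT_CONVENTION,
) -> SolidEstimate:
    """Head as a cylinder.

    Under the default convention the diameter is the head thickness and
    the axis length is the head width; the cylinder is closed, so
    SA = pi*d*L + 2*pi*(d/2)^2 and V = pi*(d/2)^2*L.
    """
    w = _check_length("head_width_mm", head_width_mm)
    t = _check_length("head_thickness_mm", head_thickness_mm)
    if convention.head_diameter == "thickness":
        d, length = t, w
    else:
        d, length = w, t
    r = d / 2.0
    sa = math.pi * d * length
    if convention.head_capped:
        sa += 2.0 * math.pi * r * r
    v = math.pi * r * r * length
    return SolidEstimate(Tagma.HEAD, sa, v, "cylinder")


def estimate_mesosoma(mesosoma_width_mm: float) -> SolidEstimate:
    """Mesosoma as a sphere of diameter ``m3``: SA = pi*d^2, V = pi*d^3/6."""
    d = _check_length("mesosoma_width_mm", mesosoma_width_mm)
    return SolidEstimate(
        Tagma.MESOSOMA, math.pi * d * d, math.pi * d ** 3 / 6.0, "sphere"
    )


def estimate_metasoma(
    metasoma_width_mm: float,
    anterior_length_mm: float,
    posterior_length_mm: float,
    convention: EstimationConvention = DEFAULT_CONVENTION,
) -> SolidEstimate:
    """Metasoma as a cylinder (tergites 1–3) joined to a cone (4–6/7).

    SA = cylinder lateral + anterior end cap + cone lateral, with the
    junction disc excluded; V = pi*r^2*m5 + pi*r^2*m6/3.  A zero cone
    height degenerates continuously to a closed cylinder (the cone
    lateral surface becomes the posterior cap).
    """
    d = _check_length("metasoma_width_mm", metasoma_width_mm)
    length = _check_length("metasoma_anterior_length_mm", anterior_length_mm)
    h = _check_length(
        "metasoma_posterior_length_mm", posterior_length_mm, allow_zero=True
    )
    r = d / 2.0
    slant = math.hypot(r, h)
    sa = math.pi * d * length + math.pi * r * slant
    if convention.metasoma_anterior_cap:
        sa += math.pi * r * r
    v = math.pi * r * r * length + math.pi * r * r * h / 3.0
    return SolidEstimate(Tagma.METASOMA, sa, v, "cylinder_plus_cone")


def estimate_specimen(
    m: LinearMeasurements,
    convention: EstimationConvention = DEFAULT_CONVENTION,
) -> SizeRecord:
    """Per-tagma solid estimates plus exact sums for one specimen."""
    return SizeRecord(
        specimen_id=m.specimen_id,
        method="geometric",
        head=estimate_head(m.head_width_mm, m.head_thickness_mm, convention),
        mesosoma=estimate_mesosoma(m.mesosoma_width_mm),
        metasoma=estimate_metasoma(
            m.metasoma_width_mm,
            m.metasoma_anterior_length_mm,
            m.metasoma_posterior_length_mm,
            convention,
        ),
    )


# ---------------------------------------------------------------------------
# tabular interface

_COLUMN_ALIASES = {
    "head_width_mm": ("head_width_mm", "m1"),
    "head_thickness_mm": ("head_thickness_mm", "m2"),
    "mesosoma_width_mm": ("mesosoma_width_mm", "m3"),
    "metasoma_width_mm": ("metasoma_width_mm", "m4"),
    "metasoma_anterior_length_mm": ("metasoma_anterior_length_mm", "m5"),
    "metasoma_posterior_length_mm": ("metasoma_posterior_length_mm", "m6"),
}


def read_measurements(path_or_buf) -> list[LinearMeasurements]:
    """Read a comma-separated caliper table (one row per specimen).

    Columns may use either the descriptive names or the short ``m1``..
    ``m6`` aliases; a ``caste`` column is optional (default worker).
    """
    df = pd.read_csv(path_or_buf)
    cols = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in df.columns:
                cols[canonical] = alias
                break
        else:
            raise MeasurementError(
                f"missing measurement column {canonical!r} (aliases: {aliases})"
            )
    out = []
    for _, row in df.iterrows():
        out.append(
            LinearMeasurements(
                specimen_id=str(row.get("specimen_id", len(out))),
                caste=Caste(row["caste"]) if "caste" in df.columns else Caste.WORKER,
                **{canon: float(row[col]) for canon, col in cols.items()},
            )
        )
    return out


def size_records_to_frame(records: Iterable[SizeRecord]) -> pd.DataFrame:
    """Long-format SizeRecord table: one row per (specimen, scope, quantity pair)."""
    rows = []
    for rec in records:
        for tagma in Tagma:
            est = rec.tagma(tagma)
            rows.append(
                {
                    "specimen_id": rec.specimen_id,
                    "method": rec.method,
                    "scope": tagma.value,
                    "surface_area_mm2": est.surface_area_mm2,
                    "volume_mm3": est.volume_mm3,
                }
            )
        rows.append(
            {
                "specimen_id": rec.specimen_id,
                "method": rec.method,
                "scope": "tagmata_sum",
                "surface_area_mm2": rec.summed_surface_area_mm2,
                "volume_mm3": rec.summed_volume_mm3,
            }
        )
    return pd.DataFrame(rows)


def estimate_table(
    measurements: Iterable[LinearMeasurements],
    convention: EstimationConvention = DEFAULT_CONVENTION,
) -> pd.DataFrame:
    """Estimate every specimen and return the long-format size table."""
    return size_records_to_frame(
        estimate_specimen(m, convention) for m in measurements
    )
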
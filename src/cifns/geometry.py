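"""Electrode-array and cochlear geometry.

The cochlea is modelled as a planar logarithmic spiral in the "cochlear
view" plane (the axial 2-D reorientation used for CT distance reading).
Electrode contacts are placed along the spiral by their arc depth from the
round window, and the electrode--facial-nerve distance (EFND) of each
contact is the Euclidean planar distance to a fixed facial-nerve locus.

Contacts are numbered 1 (apical tip) through 12 (basal), ascending
apical-to-basal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

N_CONTACTS = 12

__all__ = [
    "N_CONTACTS",
    "ElectrodeArraySpec",
    "CochlearSpiralModel",
    "FacialNerveLocus",
    "EfndProfile",
    "ApicalPositionEstimate",
    "load_array_catalogue",
    "get_array",
    "contact_positions",
    "point_on_spiral",
    "efnd_profile",
    "apical_position_estimate",
    "default_spiral",
    "default_facial_nerve",
]


@dataclass(frozen=True)
class ElectrodeArraySpec:
    """One MED-EL style electrode array: total and active length, 12 contacts.

    ``spacing_mm`` is the centre-to-centre inter-contact spacing; it must be
    consistent with ``active_length_mm / (n_contacts - 1)`` to within 5 µm.
    """

    name: str
    array_length_mm: float
    active_length_mm: float
    spacing_mm: float
    n_contacts: int = N_CONTACTS

    def __post_init__(self) -> None:
        if self.n_contacts != N_CONTACTS:
            raise ValueError(f"arrays have {N_CONTACTS} contacts, got {self.n_contacts}")
        if not self.active_length_mm < self.array_length_mm:
            raise ValueError("active length must be smaller than total array length")
        implied = self.active_length_mm / (self.n_contacts - 1)
        if abs(self.spacing_mm - implied) > 0.005:
            raise ValueError(
                f"spacing {self.spacing_mm} mm inconsistent with active length "
                f"({implied:.4f} mm implied)"
            )

    @property
    def tip_offset_mm(self) -> float:
        """Default distance from array tip to contact 1 (half the inactive length)."""
        return (self.array_length_mm - self.active_length_mm) / 2.0


def _catalogue_path() -> Path:
    return Path(str(resources.files("cifns").joinpath("data/electrode_arrays.json")))


def load_array_catalogue(path: str | Path | None = None) -> dict[str, ElectrodeArraySpec]:
    """Load the shipped electrode-array catalogue (name -> spec)."""
    raw = json.loads(Path(path or _catalogue_path()).read_text())
    return {
        row["name"]: ElectrodeArraySpec(
            name=row["name"],
            array_length_mm=row["array_length_mm"],
            active_length_mm=row["active_length_mm"],
            spacing_mm=row["spacing_mm"],
            n_contacts=row["n_contacts"],
        )
        for row in raw["arrays"]
    }


def get_array(name: str) -> ElectrodeArraySpec:
    """Look up a single array type (Standard, FLEXsoft, FLEX28, FLEX24)."""
    catalogue = load_array_catalogue()
    try:
        return catalogue[name]
    except KeyError:
        raise KeyError(f"unknown electrode array {name!r}; known: {sorted(catalogue)}") from None


class SpiralPoint(NamedTuple):
    x_mm: float
    y_mm: float
    angle_deg: float


@dataclass(frozen=True)
class CochlearSpiralModel:
    """Planar logarithmic spiral r(theta) = a * exp(-c * theta).

    Parametrized by its asymptotic total arc length ``K = (a/c) sqrt(1+c^2)``
    and the radial decay rate ``c`` per radian, which makes the arc-length ->
    angle map closed form::

        s(theta) = K (1 - exp(-c theta)),   theta(s) = -ln(1 - s/K) / c

    The insertion angle is 0 deg at the round window and strictly increasing
    with arc depth.  The default calibration places ~200 deg within the
    first ~14.8 mm (basal turn) and >= 540 deg at a 25.6 mm arc depth
    (full long-array insertion reaching the mid turn).
    """

    arc_length_asymptote_mm: float = 30.0
    decay_per_radian: float = 0.195
    duct_length_mm: float = 29.5
    kind: str = "logarithmic"

    def __post_init__(self) -> None:
        if self.kind not in ("logarithmic", "archimedean"):
            raise ValueError(f"unknown spiral kind {self.kind!r}")
        if not 0 < self.duct_length_mm < self.arc_length_asymptote_mm:
            raise ValueError("duct length must lie below the asymptotic arc length")
        if self.decay_per_radian <= 0:
            raise ValueError("decay rate must be positive")

    @property
    def basal_radius_mm(self) -> float:
        c = self.decay_per_radian
        return self.arc_length_asymptote_mm * c / math.sqrt(1.0 + c * c)

    def _check_depth(self, arc_depth_mm: float) -> None:
        if not 0.0 <= arc_depth_mm <= self.duct_length_mm:
            raise ValueError(
                f"arc depth {arc_depth_mm} mm outside [0, {self.duct_length_mm}] mm duct"
            )

    def angle_at_depth(self, arc_depth_mm: float) -> float:
        """Insertion angle in degrees at a given arc depth from the round window."""
        self._check_depth(arc_depth_mm)
        K, c = self.arc_length_asymptote_mm, self.decay_per_radian
        theta = -math.log(1.0 - arc_depth_mm / K) / c
        return math.degrees(theta)

    def point_at_depth(self, arc_depth_mm: float) -> SpiralPoint:
        self._check_depth(arc_depth_mm)
        c = self.decay_per_radian
        theta = math.radians(self.angle_at_depth(arc_depth_mm))
        r = self.basal_radius_mm * math.exp(-c * theta)
        return SpiralPoint(r * math.cos(theta), r * math.sin(theta), math.degrees(theta))


@dataclass(frozen=True)
class FacialNerveLocus:
    """Centre of the facial-nerve canal cross section in the cochlear-view plane."""

    x_mm: float
    y_mm: float

    @classmethod
    def from_spiral_anchor(
        cls, model: CochlearSpiralModel, arc_depth_mm: float, radial_offset_mm: float
    ) -> "FacialNerveLocus":
        """Place the locus ``radial_offset_mm`` outward of the spiral point at
        ``arc_depth_mm`` (on the ray from the spiral centre through that point)."""
        p = model.point_at_depth(arc_depth_mm)
        r = math.hypot(p.x_mm, p.y_mm)
        scale = (r + radial_offset_mm) / r
        return cls(p.x_mm * scale, p.y_mm * scale)

    def as_array(self) -> np.ndarray:
        return np.array([self.x_mm, self.y_mm])


# Default calibration: facial-nerve canal adjacent to the upper basal turn,
# anchored at 16.10 mm arc depth, 1.00 mm outside the lateral wall.  Chosen
# so that full insertion of long arrays has its EFND minimum at contact 6
# and FLEX24 at contact 4, with a second approach of the tip in the mid turn.
FACIAL_NERVE_ARC_ANCHOR_MM = 16.10
FACIAL_NERVE_RADIAL_OFFSET_MM = 1.00


def default_spiral() -> CochlearSpiralModel:
    return CochlearSpiralModel()


def default_facial_nerve(model: CochlearSpiralModel | None = None) -> FacialNerveLocus:
    model = model or default_spiral()
    return FacialNerveLocus.from_spiral_anchor(
        model, FACIAL_NERVE_ARC_ANCHOR_MM, FACIAL_NERVE_RADIAL_OFFSET_MM
    )


@dataclass
class EfndProfile:
    """Per-contact electrode--facial-nerve distances in mm.

    ``distances`` maps contact number (1..12, apical to basal) to the planar
    distance; contacts not yet inserted are absent.
    """

    label: str
    distances: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for contact, d in self.distances.items():
            if not 1 <= contact <= N_CONTACTS:
                raise ValueError(f"contact {contact} outside 1..{N_CONTACTS}")
            if d <= 0:
                raise ValueError(f"EFND must be positive, got {d} for contact {contact}")

    @property
    def contacts(self) -> list[int]:
        return sorted(self.distances)

    def argmin_contact(self) -> int:
        """Contact with the shortest EFND (lowest contact number on ties)."""
        return min(self.contacts, key=lambda c: (self.distances[c], c))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"contact": self.contacts, "efnd_mm": [self.distances[c] for c in self.contacts]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "EfndProfile":
        df = pd.read_csv(path)
        missing = {"contact", "efnd_mm"} - set(df.columns)
        if missing:
            raise ValueError(f"EFND CSV missing columns: {sorted(missing)}")
        return cls(
            label=label or Path(path).stem,
            distances={int(c): float(d) for c, d in zip(df["contact"], df["efnd_mm"])},
        )


def contact_positions(
    spec: ElectrodeArraySpec, n_inserted: int, tip_offset_mm: float | None = None
) -> dict[int, float]:
    """Arc depths from the round window for contacts 1..n_inserted.

    With ``n_inserted`` contacts inside the cochlea, contact 1 (the tip
    contact) is deepest at ``tip_offset + (n_inserted - 1) * spacing`` and
    consecutive contacts sit exactly one spacing apart, contact
    ``n_inserted`` at ``tip_offset``.
    """
    if not 1 <= n_inserted <= spec.n_contacts:
        raise ValueError(f"n_inserted must be in 1..{spec.n_contacts}, got {n_inserted}")
    tip_offset = spec.tip_offset_mm if tip_offset_mm is None else tip_offset_mm
    return {
        k: tip_offset + (n_inserted - k) * spec.spacing_mm for k in range(1, n_inserted + 1)
    }


def point_on_spiral(model: CochlearSpiralModel, arc_depth_mm: float) -> SpiralPoint:
    """Planar point and insertion angle (degrees) at an arc depth on the spiral."""
    return model.point_at_depth(arc_depth_mm)


def efnd_profile(
    spec: ElectrodeArraySpec,
    model: CochlearSpiralModel,
    fn: FacialNerveLocus,
    n_inserted: int = N_CONTACTS,
    tip_offset_mm: float | None = None,
    label: str | None = None,
) -> EfndProfile:
    """EFND of every inserted contact: planar distance from the contact's
    spiral point to the facial-nerve locus."""
    depths = contact_positions(spec, n_inserted, tip_offset_mm)
    fn_xy = fn.as_array()
    distances = {}
    for contact, depth in depths.items():
        p = model.point_at_depth(depth)
        distances[contact] = float(np.hypot(p.x_mm - fn_xy[0], p.y_mm - fn_xy[1]))
    return EfndProfile(label=label or f"{spec.name}_n{n_inserted}", distances=distances)


class ApicalPositionEstimate(NamedTuple):
    """Estimated final contact index of the stimulating tip, P = 12 - N_inserted."""

    position: int
    in_contact_range: bool


def apical_position_estimate(n_inserted: int) -> ApicalPositionEstimate:
    """Estimate which contact slot the tip occupies after full insertion.

    P = 12 - N_inserted.  P = 0 (tip beyond contact slot 1, i.e. full
    insertion) is returned but flagged as outside the 1..12 contact range.
    """
    if not 1 <= n_inserted <= N_CONTACTS:
        raise ValueError(f"n_inserted must be in 1..{N_CONTACTS}, got {n_inserted}")
    p = N_CONTACTS - n_inserted
    return ApicalPositionEstimate(position=p, in_contact_range=1 <= p <= N_CONTACTS)
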
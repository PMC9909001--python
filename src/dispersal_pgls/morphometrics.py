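"""Wing aspect ratio as a flight-efficiency proxy.

The aspect ratio AR = B^2 / A_tot (wingspan squared over total lifting
area) is the wing characteristic that dominates long-distance flight
efficiency.  Total area counts both wings plus the body strip between them:

    A_tot = 2 * A_w + C_r * (B - 2 * E)

where A_w is the area of one spread wing, C_r the root chord (wing width at
its proximal border), and E the wing extent (root chord to farthest feather
tip).  All linear measures in meters, areas in m^2; AR is dimensionless, so
any internally consistent unit system per specimen gives the same value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WingMeasurement",
    "AspectRatioEstimate",
    "total_wing_area",
    "aspect_ratio",
    "species_mean_AR",
    "species_table",
    "read_wings_csv",
]

# plausible avian aspect-ratio range; values outside trigger a warning only
_AR_TYPICAL = (3.0, 20.0)


@dataclass(frozen=True)
class WingMeasurement:
    specimen_id: str
    species: str
    B: float    # wingspan (m)
    A_w: float  # single-wing area (m^2)
    C_r: float  # root chord (m)
    E: float    # wing extent (m)

    def __post_init__(self) -> None:
        for name in ("B", "A_w", "C_r", "E"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{self.specimen_id}: {name} must be positive, got {v}")
        if self.E > self.B / 2:
            raise ValueError(
                f"{self.specimen_id}: wing extent E={self.E} exceeds half wingspan"
            )
        if self.C_r > self.B:
            raise ValueError(f"{self.specimen_id}: root chord exceeds wingspan")


@dataclass(frozen=True)
class AspectRatioEstimate:
    species: str
    mean_AR: float
    n_specimens: int


def total_wing_area(m: WingMeasurement) -> float:
    """Total lifting area: both wings plus the body strip between the roots."""
    body_strip = m.B - 2.0 * m.E
    if body_strip < 0:
        raise ValueError(f"{m.specimen_id}: B - 2E < 0, inconsistent measurement")
    return 2.0 * m.A_w + m.C_r * body_strip


def aspect_ratio(B: float, A_tot: float) -> float:
    """AR = B^2 / A_tot."""
    if B <= 0 or A_tot <= 0:
        raise ValueError(f"wingspan and area must be positive (B={B}, A_tot={A_tot})")
    return B * B / A_tot


def specimen_aspect_ratio(m: WingMeasurement) -> float:
    return aspect_ratio(m.B, total_wing_area(m))


def species_mean_AR(measurements: Sequence[WingMeasurement]) -> AspectRatioEstimate:
    """Arithmetic mean of per-specimen aspect ratios for one species.

    Per-specimen ARs are averaged (rather than computing the AR of mean
    measurements) so that unpaired wingspan/area sources only need internal
    consistency within each specimen; see ``ar_of_means`` for the
    alternative convention.
    """
    if not measurements:
        raise ValueError("need at least one specimen")
    species = measurements[0].species
    if any(m.species != species for m in measurements):
        raise ValueError("species_mean_AR expects a single species")
    ars = [specimen_aspect_ratio(m) for m in measurements]
    mean_ar = float(np.mean(ars))
    if not _AR_TYPICAL[0] <= mean_ar <= _AR_TYPICAL[1]:
        warnings.warn(
            f"{species}: mean aspect ratio {mean_ar:.2f} outside the typical "
            f"avian range {_AR_TYPICAL}",
            stacklevel=2,
        )
    return AspectRatioEstimate(species=species, mean_AR=mean_ar, n_specimens=len(ars))


def ar_of_means(measurements: Sequence[WingMeasurement]) -> float:
    """Alternative convention: aspect ratio of the mean measurements."""
    B = float(np.mean([m.B for m in measurements]))
    A_tot = float(np.mean([total_wing_area(m) for m in measurements]))
    return aspect_ratio(B, A_tot)


def species_table(measurements: Iterable[WingMeasurement]) -> pd.DataFrame:
    """Species-mean aspect ratios as a DataFrame sorted by taxon key."""
    by_species: dict[str, list[WingMeasurement]] = {}
    for m in measurements:
        by_species.setdefault(m.species, []).append(m)
    rows = []
    for sp in sorted(by_species):
        est = species_mean_AR(by_species[sp])
        rows.append(
            {"species": sp, "mean_AR": est.mean_AR, "n_specimens": est.n_specimens}
        )
    return pd.DataFrame(rows)


def read_wings_csv(path) -> list[WingMeasurement]:
    """Read a wing-measurement CSV (specimen_id, species, B, A_w, C_r, E)."""
    df = pd.read_csv(path, dtype={"specimen_id": str, "species": str})
    return [
        WingMeasurement(
            specimen_id=r.specimen_id,
            species=r.species,
            B=float(r.B),
            A_w=float(r.A_w),
            C_r=float(r.C_r),
            E=float(r.E),
        )
        for r in df.itertuples(index=False)
    ]
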
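"""Stereological estimators: Abercrombie correction, Cavalieri volume,
packing density and total neuron number.

Counting labeled profiles in sections overestimates the number of cells,
because a cell whose body spans a cut face appears in more than one
section. Abercrombie's correction rescales a profile count n to
N = n · T / (T + h), where T is section thickness and h the mean
particle height along the cutting axis. The Cavalieri principle
estimates a structure's volume from a systematic series of sections as
V = T · k · Σ A_i (k = every k-th section kept, A_i the profile areas).
Density and total number combine the two:

    density = Σ corrected counts / volume of the counted sections
    total   = density × Cavalieri volume of the whole structure

The two estimators stay independent: density uses only the sampled
sections' volume, the total uses the full Cavalieri volume.

h is not derivable from charted material and must be supplied; the
default of 10 μm is a convention at the scale of a medium-sized
interneuron soma radius and should be overridden when a measured value
exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Default mean particle height h (μm). A convention, not a measurement.
DEFAULT_MEAN_HEIGHT_UM = 10.0

UM3_PER_MM3 = 1e9


@dataclass(frozen=True)
class ProfileCount:
    """A raw profile count in one section, with the quantities the
    Abercrombie correction needs."""

    n_profiles: int
    thickness_um: float = 50.0
    mean_height_um: float = DEFAULT_MEAN_HEIGHT_UM

    def __post_init__(self) -> None:
        if self.n_profiles < 0:
            raise ValueError("n_profiles must be >= 0")
        if self.thickness_um <= 0:
            raise ValueError("thickness_um must be > 0")
        if self.mean_height_um < 0:
            raise ValueError("mean_height_um must be >= 0")


@dataclass(frozen=True)
class VolumeEstimate:
    section_areas_um2: tuple[float, ...]
    thickness_um: float
    sampling_interval: int
    volume_um3: float

    @property
    def volume_mm3(self) -> float:
        return self.volume_um3 / UM3_PER_MM3


def abercrombie_factor(thickness_um: float, mean_height_um: float) -> float:
    """T / (T + h), the fraction of profiles whose count survives correction."""
    if thickness_um <= 0:
        raise ValueError("thickness_um must be > 0")
    if mean_height_um < 0:
        raise ValueError("mean_height_um must be >= 0")
    return thickness_um / (thickness_um + mean_height_um)


def abercrombie_correct(count: ProfileCount) -> float:
    """Corrected cell count N = n · T / (T + h).

    Equal to the raw count when h = 0 and strictly smaller otherwise.
    """
    return count.n_profiles * abercrombie_factor(
        count.thickness_um, count.mean_height_um
    )


def cavalieri_volume(
    areas_um2: Sequence[float],
    thickness_um: float = 50.0,
    sampling_interval: int = 5,
) -> VolumeEstimate:
    """Cavalieri volume of a structure from a systematic section series.

    ``volume = thickness × interval × Σ areas``; at the defaults
    (T = 50 μm, every 5th section) the period between sampled planes is
    250 μm.
    """
    areas = np.asarray(areas_um2, dtype=float)
    if areas.size == 0:
        raise ValueError("need at least one section area")
    if np.any(areas < 0):
        raise ValueError("section areas must be >= 0")
    if thickness_um <= 0:
        raise ValueError("thickness_um must be > 0")
    if sampling_interval < 1:
        raise ValueError("sampling_interval must be >= 1")
    volume = float(thickness_um * sampling_interval * areas.sum())
    return VolumeEstimate(
        section_areas_um2=tuple(float(a) for a in areas),
        thickness_um=thickness_um,
        sampling_interval=sampling_interval,
        volume_um3=volume,
    )


def packing_density(
    corrected_counts: Sequence[float], sampled_volume_um3: float
) -> float:
    """Neurons per mm³ within the counted sections.

    ``sampled_volume_um3`` is the tissue volume of the counted sections
    only (Σ section areas × thickness), not the Cavalieri total.
    """
    if sampled_volume_um3 <= 0:
        raise ValueError("sampled_volume_um3 must be > 0")
    total = float(np.sum(np.asarray(corrected_counts, dtype=float)))
    return total / sampled_volume_um3 * UM3_PER_MM3


def total_number(density_per_mm3: float, total_volume_mm3: float) -> float:
    """Total labeled neurons: packing density × Cavalieri volume."""
    if density_per_mm3 <= 0 or total_volume_mm3 <= 0:
        raise ValueError("density and volume must be > 0")
    return density_per_mm3 * total_volume_mm3
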
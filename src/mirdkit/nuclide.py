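"""Physical decay data for the radionuclide label.

Times are minutes throughout the package; decay constants are 1/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class Nuclide:
    """A radionuclide characterised by its physical half-life.

    Parameters
    ----------
    name
        Nuclide label, e.g. ``"Ga-68"``.
    physical_half_life
        Physical half-life in minutes; must be positive.
    """

    name: str
    physical_half_life: float  # minutes

    def __post_init__(self) -> None:
        if not self.physical_half_life > 0:
            raise ValueError(
                f"physical_half_life must be > 0, got {self.physical_half_life}"
            )

    @property
    def decay_constant(self) -> float:
        """Physical decay constant λ_p = ln2 / T_p, in 1/min."""
        return math.log(2.0) / self.physical_half_life

    @property
    def mean_life_hours(self) -> float:
        """Mean life T_p/ln2 expressed in hours.

        This is the time-integrated activity of unit injected activity with
        no biological removal, i.e. the upper bound on the sum of all
        residence times (1.635 h for Ga-68).
        """
        return self.physical_half_life / math.log(2.0) / 60.0


#: Gallium-68, the positron-emitting label (T_p = 68 min).
GA68 = Nuclide("Ga-68", 68.0)
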
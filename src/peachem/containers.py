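"""Shared in-memory containers for spectra and composition tables.

Spectra live in a :class:`SpectraSet` (wavelength grid + absorbance matrix +
sample ids); composition/sensory tables are plain :class:`pandas.DataFrame`
objects indexed by ``sample_id`` with one column per variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Variable order used everywhere: five chemical components first, then the
#: six sensory attributes.
VARIABLES = (
    "starch",
    "crude_protein",
    "moisture",
    "crude_fiber",
    "crude_fat",
    "length",
    "width",
    "height",
    "hundred_seed_weight",
    "seed_shape",
    "color",
)

#: The five chemical components modeled by PLSR (g/100 g or %).
CHEMICAL_COMPONENTS = VARIABLES[:5]

#: Ordinal sensory scores reported on a 1-4 scale.
ORDINAL_VARIABLES = ("seed_shape", "color")

#: Instrument grid: 908-1676 nm sampled every 6 nm (129 channels).
WAVELENGTH_START = 908.0
WAVELENGTH_STEP = 6.0
N_CHANNELS = 129


def default_grid() -> np.ndarray:
    """The instrument wavelength grid in nm."""
    return WAVELENGTH_START + WAVELENGTH_STEP * np.arange(N_CHANNELS)


@dataclass
class SpectraSet:
    """Absorbance spectra on a common wavelength grid.

    Attributes
    ----------
    wavelengths:
        Strictly increasing wavelength vector in nm, length ``p``.
    absorbance:
        ``(n_samples, p)`` absorbance matrix.
    sample_ids:
        Unique sample identifiers, length ``n_samples``.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:04d}" for i in range(self.absorbance.shape[0])]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    def validate(self) -> None:
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} channels but the "
                f"grid has {self.wavelengths.size}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains NaN or Inf")
        if len(self.sample_ids) != self.absorbance.shape[0]:
            raise ValueError("sample_ids length does not match absorbance rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def subset(self, ids: list[str]) -> "SpectraSet":
        """Row subset in the given id order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return SpectraSet(self.wavelengths.copy(), self.absorbance[idx], list(ids))

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            self.wavelengths.copy(), self.absorbance.copy(), list(self.sample_ids)
        )


def align_composition(spectra: SpectraSet, comp: pd.DataFrame) -> pd.DataFrame:
    """Reindex a composition table to a spectra set's id order."""
    missing = [s for s in spectra.sample_ids if s not in comp.index]
    if missing:
        raise KeyError(f"composition table is missing ids: {missing[:5]}")
    return comp.loc[spectra.sample_ids]
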
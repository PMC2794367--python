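"""Standard populations for direct age-standardisation.

Ships the Segi (1960) world standard in 5-year bands — the "world standard
population" of the study era — and the WHO (2000) world standard as an
alternative.  Weights are proportions over the declared bands and sum to 1;
restricting to a sub-range of bands (e.g. ages 15+) renormalises.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

AGE_BANDS = (
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74",
    "75-79", "80-84", "85+",
)

# Segi world standard, per 100,000
_SEGI = (12000, 10000, 9000, 9000, 8000, 8000, 6000, 6000, 6000,
         6000, 5000, 4000, 4000, 3000, 2000, 1000, 500, 500)

# WHO world standard 2000-2025, percent (85+ pooled)
_WHO2000 = (8.86, 8.69, 8.60, 8.47, 8.22, 7.93, 7.61, 7.15, 6.59,
            6.04, 5.37, 4.55, 3.72, 2.96, 2.21, 1.52, 0.91, 0.635)


class StandardPopulation:
    """Age-band -> weight table; weights >= 0 and sum to 1."""

    def __init__(self, weights: pd.Series | dict):
        w = pd.Series(weights, dtype=float)
        if (w < 0).any():
            raise InvalidArgumentError("standard population weights must be >= 0")
        total = w.sum()
        if total <= 0:
            raise InvalidArgumentError("standard population weights sum to zero")
        w = w / total
        assert abs(w.sum() - 1.0) < 1e-9
        self.weights = w

    @property
    def bands(self) -> list[str]:
        return list(self.weights.index)

    def restrict(self, bands) -> "StandardPopulation":
        """Keep only the given bands, renormalising weights to sum to 1."""
        missing = [b for b in bands if b not in self.weights.index]
        if missing:
            raise InvalidArgumentError(f"bands not in standard: {missing}")
        return StandardPopulation(self.weights.loc[list(bands)])

    def __len__(self) -> int:
        return len(self.weights)

    def __repr__(self) -> str:  # pragma: no cover
        return f"StandardPopulation({len(self)} bands)"


def get_standard(name: str = "segi", min_age_band: str | None = None) -> StandardPopulation:
    """Return a named standard population.

    Parameters
    ----------
    name : 'segi' or 'who2000'
    min_age_band : optional band label; bands below it are dropped and the
        remaining weights renormalised (e.g. '15-19' for analyses of the
        population aged 15 and over).
    """
    name = name.lower()
    if name == "segi":
        raw = _SEGI
    elif name == "who2000":
        raw = _WHO2000
    else:
        raise InvalidArgumentError(f"unknown standard {name!r}; use 'segi' or 'who2000'")
    std = StandardPopulation(pd.Series(np.asarray(raw, dtype=float), index=list(AGE_BANDS)))
    if min_age_band is not None:
        if min_age_band not in AGE_BANDS:
            raise InvalidArgumentError(f"unknown age band {min_age_band!r}")
        start = AGE_BANDS.index(min_age_band)
        std = std.restrict(AGE_BANDS[start:])
    return std
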
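"""Poisson observation model for annual territory counts.

Observed counts of occupied breeding territories per habitat and year are
linked to the latent number of breeders NB by

    C_{h,t} ~ Poisson(NB_{h,t}),

which absorbs observation error in the census.  Counts are of pairs; the
sex-specific model variants consume the same counts as counts of the
modelled sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CountData", "count_loglik"]


@dataclass
class CountData:
    """One territory count record (year, habitat, count >= 0)."""

    year: int
    habitat: int
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be non-negative, got {self.count}")


def count_loglik(data: CountData, nb: float) -> float:
    """Log Poisson pmf of the observed count given latent breeders ``nb``.

    The limit nb -> 0 is handled exactly: a zero count has log likelihood 0,
    any positive count has density zero.
    """
    if nb < 0:
        raise ValueError(f"latent breeder number must be non-negative, got {nb}")
    if nb == 0.0:
        return 0.0 if data.count == 0 else -np.inf
    return float(stats.poisson.logpmf(data.count, nb))
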
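"""Stratified sampling designs for sensitivity analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = ["LHSDesign", "latin_hypercube_design"]


@dataclass(frozen=True)
class LHSDesign:
    """A Latin hypercube sample over named parameter intervals."""

    intervals: dict[str, tuple[float, float]]
    n_samples: int
    samples: pd.DataFrame

    def __post_init__(self):
        for name, (lo, hi) in self.intervals.items():
            col = self.samples[name]
            if not ((col >= lo) & (col <= hi)).all():
                raise ValueError(f"sample outside interval for {name!r}")


def latin_hypercube_design(intervals: dict[str, tuple[float, float]],
                           n_samples: int,
                           rng: np.random.Generator | int) -> LHSDesign:
    """Draw a Latin hypercube design: one sample per equal-width stratum
    in each dimension, scaled to the given (low, high) intervals."""
    if n_samples <= 0:
        raise ValueError("need at least one sample")
    names = list(intervals)
    lows = [intervals[k][0] for k in names]
    highs = [intervals[k][1] for k in names]
    if any(h <= l for l, h in zip(lows, highs)):
        raise ValueError("empty interval")
    sampler = qmc.LatinHypercube(d=len(names), rng=np.random.default_rng(rng)
                                 if isinstance(rng, int) else rng)
    unit = sampler.random(n=n_samples)
    scaled = qmc.scale(unit, lows, highs)
    return LHSDesign(dict(intervals), n_samples,
                     pd.DataFrame(scaled, columns=names))
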
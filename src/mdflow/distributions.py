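"""Gaussian mixture targets.

Synthetic stand-ins for experimentally measured pair-distance distributions
(the shape of DEER spectroscopy data): a weighted mixture of Gaussian
components, with sampling, CDF evaluation and a Kolmogorov-Smirnov distance
against an empirical sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import InvariantViolationError


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    center: float
    width: float


class GaussianMixture:
    """A normalized mixture of Gaussians over pair distances.

    *components* is a sequence of (weight, center, width) triples; weights
    must be positive and sum to one, widths positive.
    """

    def __init__(self, components: Sequence[Tuple[float, float, float]]):
        comps = [MixtureComponent(*c) for c in components]
        if not comps:
            raise InvariantViolationError("mixture needs at least one component")
        for idx, c in enumerate(comps):
            if c.weight <= 0:
                raise InvariantViolationError(f"components[{idx}].weight must be > 0")
            if c.width <= 0:
                raise InvariantViolationError(f"components[{idx}].width must be > 0")
        total = sum(c.weight for c in comps)
        if abs(total - 1.0) > 1e-9:
            raise InvariantViolationError(f"weights sum to {total}, expected 1")
        self.components = comps

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        weights = np.array([c.weight for c in self.components])
        idx = rng.choice(len(self.components), size=n, p=weights)
        centers = np.array([c.center for c in self.components])[idx]
        widths = np.array([c.width for c in self.components])[idx]
        return rng.normal(centers, widths)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        out = np.zeros_like(x, dtype=float)
        for c in self.components:
            out = out + c.weight * stats.norm.cdf(x, loc=c.center, scale=c.width)
        return out

    def ks_distance(self, samples: Sequence[float]) -> float:
        """Kolmogorov-Smirnov statistic of an empirical sample against the
        mixture CDF."""
        return float(stats.kstest(np.asarray(samples, float), self.cdf).statistic)

    def to_json(self) -> Dict[str, Any]:
        return {"components": [[c.weight, c.center, c.width] for c in self.components]}

    @staticmethod
    def from_json(doc: Dict[str, Any]) -> "GaussianMixture":
        return GaussianMixture([tuple(c) for c in doc["components"]])


def ks_critical_value(n: int, alpha: float = 0.05) -> float:
    """Asymptotic one-sample KS critical value: c(alpha) / sqrt(n), with
    c(0.05) = sqrt(-ln(alpha/2)/2) ≈ 1.358."""
    c = np.sqrt(-0.5 * np.log(alpha / 2.0))
    return float(c / np.sqrt(n))
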
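"""Synthetic microtissue size populations.

Microtissue equivalent diameters are modelled as lognormal: aggregate sizes
are strictly positive and mildly right-skewed, and a lognormal is the
standard minimal choice for such data. Two named populations are provided:

* the *inoculum* — the day-2 starting population, nearly monomodal with an
  arithmetic mean diameter of 120 um (we default to a 10% coefficient of
  variation to honour "homogeneous in size");
* the *steady state* — after early fusion stops, projected areas fall in
  [0.01, 0.04] mm^2, i.e. circle-equivalent diameters of roughly
  113-226 um; sampled as a truncated lognormal by rejection.

``fit_size_spec`` calibrates a spec to measured projected areas (one area
in mm^2 per line of a plain-text table) by log-moment matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .exceptions import DataError, InvalidParameterError

__all__ = [
    "SizeDistributionSpec",
    "inoculum_spec",
    "steady_state_spec",
    "sample_inoculum",
    "sample_steady_state",
    "projected_area",
    "equivalent_diameter",
    "fused_diameter",
    "fit_size_spec",
    "read_areas",
]


@dataclass(frozen=True)
class SizeDistributionSpec:
    """Lognormal description of microtissue equivalent diameters.

    Parameters
    ----------
    median_diameter:
        Median (= geometric mean) equivalent diameter, m.
    cv:
        Coefficient of variation of the lognormal, dimensionless;
        log-scale sigma = sqrt(ln(1 + cv^2)).
    area_bounds:
        Optional (low, high) truncation bounds on projected area, m^2.
    """

    median_diameter: float
    cv: float = 0.10
    area_bounds: Optional[tuple] = None
    family: str = "lognormal"

    def __post_init__(self):
        if not (math.isfinite(self.median_diameter) and self.median_diameter > 0):
            raise InvalidParameterError("median diameter must be > 0")
        if not (math.isfinite(self.cv) and self.cv >= 0):
            raise InvalidParameterError("cv must be >= 0")
        if self.family != "lognormal":
            raise InvalidParameterError(f"unsupported family {self.family!r}")
        if self.area_bounds is not None:
            lo, hi = self.area_bounds
            if not (0 <= lo < hi):
                raise InvalidParameterError("area bounds must satisfy 0 <= lo < hi")

    @property
    def sigma_log(self) -> float:
        return math.sqrt(math.log1p(self.cv ** 2))

    @property
    def mu_log(self) -> float:
        return math.log(self.median_diameter)

    @property
    def mean_diameter(self) -> float:
        """Arithmetic mean = median * exp(sigma^2 / 2)."""
        return self.median_diameter * math.exp(0.5 * self.sigma_log ** 2)

    @classmethod
    def from_mean(cls, mean_diameter: float, cv: float = 0.10,
                  area_bounds: Optional[tuple] = None) -> "SizeDistributionSpec":
        sigma2 = math.log1p(cv ** 2)
        return cls(median_diameter=mean_diameter * math.exp(-0.5 * sigma2),
                   cv=cv, area_bounds=area_bounds)


def inoculum_spec() -> SizeDistributionSpec:
    """Day-2 starting population: mean diameter 120 um, CV 10%."""
    return SizeDistributionSpec.from_mean(120.0e-6, cv=0.10)


def steady_state_spec() -> SizeDistributionSpec:
    """Post-fusion population truncated to projected areas 0.01-0.04 mm^2."""
    return SizeDistributionSpec(median_diameter=160.0e-6, cv=0.25,
                                area_bounds=(0.01e-6, 0.04e-6))


def sample_inoculum(n: int, seed: int,
                    spec: Optional[SizeDistributionSpec] = None) -> np.ndarray:
    """Draw ``n`` inoculum equivalent diameters (m), reproducibly."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    spec = spec or inoculum_spec()
    rng = np.random.default_rng(seed)
    if spec.cv == 0.0:
        return np.full(n, spec.median_diameter)
    return rng.lognormal(spec.mu_log, spec.sigma_log, size=n)


def sample_steady_state(n: int, seed: int,
                        spec: Optional[SizeDistributionSpec] = None,
                        max_batches: int = 1000) -> np.ndarray:
    """Draw ``n`` steady-state diameters (m) with projected areas in bounds.

    Rejection sampling from the lognormal; raises if the acceptance rate
    falls below 1e-4 (bounds incompatible with the lognormal body).
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    spec = spec or steady_state_spec()
    if spec.area_bounds is None:
        raise InvalidParameterError("steady-state spec needs area bounds")
    lo, hi = spec.area_bounds
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    drawn = accepted = 0
    batch = max(4 * n, 1000)
    for _ in range(max_batches):
        d = rng.lognormal(spec.mu_log, spec.sigma_log, size=batch)
        a = projected_area(d)
        d = d[(a >= lo) & (a <= hi)]
        drawn += batch
        accepted += d.size
        out = np.concatenate([out, d])
        if out.size >= n:
            return out[:n]
        if drawn >= 1e4 and accepted / drawn < 1e-4:
            break
    raise InvalidParameterError(
        f"truncation bounds accept too little probability mass "
        f"({accepted}/{drawn} draws)")


def projected_area(d):
    """Circle-equivalent projected area A = pi d^2 / 4 (m^2)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise InvalidParameterError("diameter must be >= 0")
    return math.pi * d ** 2 / 4.0


def equivalent_diameter(area):
    """Inverse of :func:`projected_area`: d = 2 sqrt(A / pi)."""
    area = np.asarray(area, dtype=float)
    return 2.0 * np.sqrt(area / math.pi)


def fused_diameter(d: float, k: int) -> float:
    """Volume-conserving diameter of ``k`` fused microtissues: d * k^(1/3)."""
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    return d * k ** (1.0 / 3.0)


def fit_size_spec(areas: Sequence[float]) -> SizeDistributionSpec:
    """Fit a lognormal diameter spec to measured projected areas (m^2).

    Areas are converted to circle-equivalent diameters and the lognormal is
    fitted by log-moment matching (median = exp(mean log d), cv from the
    log variance). At least 3 positive areas are required.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size < 3:
        raise DataError("need at least 3 areas to fit a size distribution")
    if np.any(areas <= 0) or not np.all(np.isfinite(areas)):
        raise DataError("areas must be positive and finite")
    logd = np.log(equivalent_diameter(areas))
    mu = float(np.mean(logd))
    sigma = float(np.std(logd, ddof=1))
    cv = math.sqrt(math.expm1(sigma ** 2))
    return SizeDistributionSpec(median_diameter=math.exp(mu), cv=cv)


def read_areas(path, unit: float = 1.0e-6) -> np.ndarray:
    """Read projected areas from plain text (one value per line, mm^2).

    ``#`` starts a comment. ``unit`` converts to m^2 (default mm^2 -> m^2).
    """
    values = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            values.append(float(line) * unit)
    if not values:
        raise DataError(f"no areas found in {path}")
    return np.asarray(values)
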
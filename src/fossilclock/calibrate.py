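"""Calibration-density construction for node dating and FBD age specs.

Three node-dating density families are built from a fossil table:

* ``NDn`` ("narrow"): log-normal offset at the fossil's epoch minimum age,
  95th percentile at the epoch maximum age.
* ``NDb`` ("broad"): log-normal offset at the fossil's published minimum age
  a; the 95th percentile sits ``margin(a)`` Ma above the offset, where the
  margin is 5 Ma for the youngest age class and grows 10% per 5-Ma class
  (margin(a) = 5 * 1.1**(a/5), evaluated continuously off the grid). The
  log-scale s.d. is scaled linearly from 1.0 (youngest fossil) to 0.6
  (oldest fossil).
* ``NDu`` ("uniform"): uniform between the 2.5% and 97.5% quantiles of the
  corresponding NDb density.

For FBD tip dating, fossils get either a fixed tip age (the minimum age) or
a uniform sampling range [a, a + margin(a)], optionally capped by a root-age
ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .fossils import EpochInterval, FossilRecord

__all__ = [
    "Z95",
    "CalibrationDensity",
    "FBDAgeSpec",
    "InfeasibleDensityError",
    "solve_lognormal_location",
    "ndb_q95_margin",
    "ndb_sigma",
    "build_ndn_density",
    "build_ndb_density",
    "build_ndu_density",
    "build_fbd_age_spec",
]

#: standard normal 95th percentile
Z95 = 1.6448536269514722


class InfeasibleDensityError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationDensity:
    """A parametric prior on a calibration node's age (Ma).

    ``log_normal``: age = offset + LogNormal(location, sigma); ``q95`` is the
    95th percentile of the node age. ``uniform``: age ~ U(lower, upper).
    ``target`` names the clade constraint and node role this density applies
    to (resolved against a tree at run time).
    """

    family: str                      # log_normal | uniform
    target: str = ""
    node_role: str = "stem"
    offset: float | None = None      # Ma (log_normal)
    sigma: float | None = None       # log-scale sd
    location: float | None = None    # log-scale mean
    q95: float | None = None         # Ma
    lower: float | None = None       # Ma (uniform)
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.family == "log_normal":
            if self.sigma is None or self.sigma <= 0:
                raise InfeasibleDensityError(f"sigma must be > 0, got {self.sigma}")
            if self.q95 is not None and self.offset is not None and self.q95 <= self.offset:
                raise InfeasibleDensityError(
                    f"q95 {self.q95} must exceed offset {self.offset}")
        elif self.family == "uniform":
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise InfeasibleDensityError(
                    f"uniform needs lower < upper, got [{self.lower}, {self.upper}]")
        else:
            raise InfeasibleDensityError(f"unknown family {self.family!r}")

    # -- distribution interface -------------------------------------------
    def _dist(self):
        if self.family == "log_normal":
            return stats.lognorm(s=self.sigma, scale=math.exp(self.location),
                                 loc=self.offset)
        return stats.uniform(loc=self.lower, scale=self.upper - self.lower)

    def logpdf(self, age: float) -> float:
        # closed form (the chain evaluates this every generation)
        if self.family == "log_normal":
            x = age - self.offset
            if x <= 0:
                return -math.inf
            z = (math.log(x) - self.location) / self.sigma
            return (-math.log(x) - math.log(self.sigma)
                    - 0.5 * math.log(2.0 * math.pi) - 0.5 * z * z)
        if self.lower <= age <= self.upper:
            return -math.log(self.upper - self.lower)
        return -math.inf

    def pdf(self, age: float) -> float:
        return float(self._dist().pdf(age))

    def cdf(self, age: float) -> float:
        return float(self._dist().cdf(age))

    def ppf(self, p: float) -> float:
        return float(self._dist().ppf(p))

    def sample(self, rng, size=None):
        return self._dist().rvs(size=size, random_state=rng)

    @property
    def floor(self) -> float:
        """Hard lower bound on the calibrated node age."""
        return self.offset if self.family == "log_normal" else self.lower

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass(frozen=True)
class FBDAgeSpec:
    """Fossil tip-age configuration for FBD: fixed age or uniform range."""

    fossil: str
    mode: str                    # fixed_tip | uniform_range
    age: float | None = None     # Ma (fixed_tip)
    lower: float | None = None   # Ma (uniform_range)
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "fixed_tip":
            if self.age is None or self.age <= 0:
                raise InfeasibleDensityError(
                    f"fossil {self.fossil!r}: fixed tip age must be positive")
        elif self.mode == "uniform_range":
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise InfeasibleDensityError(
                    f"fossil {self.fossil!r}: need lower < upper, got "
                    f"[{self.lower}, {self.upper}]")
        else:
            raise InfeasibleDensityError(f"unknown FBD age mode {self.mode!r}")

    def initial_age(self) -> float:
        return self.age if self.mode == "fixed_tip" else self.lower

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


# ---------------------------------------------------------------------------
# construction rules
# ---------------------------------------------------------------------------

def solve_lognormal_location(offset: float, sigma: float, q95: float) -> float:
    """Log-scale mean m such that quantile(0.95) of offset+LogNormal(m, sigma)
    equals ``q95``: m = ln(q95 - offset) - z95 * sigma."""
    if sigma <= 0:
        raise InfeasibleDensityError(f"sigma must be > 0, got {sigma}")
    if q95 <= offset:
        raise InfeasibleDensityError(
            f"95th percentile ({q95} Ma) must exceed the offset ({offset} Ma)")
    return math.log(q95 - offset) - Z95 * sigma


def ndb_q95_margin(a: float) -> float:
    """Margin (Ma) of the broad density's 95th percentile above its offset.

    5 Ma at age class 0, increased by 10% per 5-Ma age class:
    margin(a) = 5 * 1.1**(a/5), evaluated continuously for off-grid ages
    (smooth, monotone, and exact on the grid; margin(90) = 27.80 ~ 28 Ma).
    """
    if a < 0:
        raise ValueError(f"fossil age must be non-negative, got {a}")
    return 5.0 * 1.1 ** (a / 5.0)


def ndb_sigma(a: float, a_min: float, a_max: float) -> float:
    """Log-scale s.d. scaled linearly from 1.0 (youngest) to 0.6 (oldest)."""
    import warnings
    if not a_min < a_max:
        raise ValueError(f"need a_min < a_max, got [{a_min}, {a_max}]")
    if a < a_min or a > a_max:
        warnings.warn(f"fossil age {a} outside [{a_min}, {a_max}]; clamping")
        a = min(max(a, a_min), a_max)
    return 1.0 - 0.4 * (a - a_min) / (a_max - a_min)


def build_ndn_density(fossil: FossilRecord, epoch: EpochInterval,
                      sigma: float = 1.0) -> CalibrationDensity:
    """Narrow density: offset = epoch minimum age, q95 = epoch maximum age."""
    if epoch.max_age <= epoch.min_age:
        raise InfeasibleDensityError(
            f"epoch {epoch.name!r}: max {epoch.max_age} <= min {epoch.min_age}")
    m = solve_lognormal_location(epoch.min_age, sigma, epoch.max_age)
    return CalibrationDensity(family="log_normal", target=fossil.clade,
                              node_role="stem", offset=epoch.min_age,
                              sigma=sigma, location=m, q95=epoch.max_age)


def build_ndb_density(fossil: FossilRecord, a_min: float, a_max: float) -> CalibrationDensity:
    """Broad density: offset at the fossil's published minimum age; margin and
    sigma from the age-class rules (a_min/a_max span the active fossil set)."""
    a = fossil.min_age
    sigma = ndb_sigma(a, a_min, a_max)
    q95 = a + ndb_q95_margin(a)
    m = solve_lognormal_location(a, sigma, q95)
    return CalibrationDensity(family="log_normal", target=fossil.clade,
                              node_role="stem", offset=a, sigma=sigma,
                              location=m, q95=q95)


def build_ndu_density(ndb: CalibrationDensity) -> CalibrationDensity:
    """Uniform on the source NDb density's [2.5%, 97.5%] quantile interval."""
    if ndb.family != "log_normal":
        raise InfeasibleDensityError("NDu is derived from a log-normal NDb density")
    return CalibrationDensity(family="uniform", target=ndb.target,
                              node_role=ndb.node_role,
                              lower=ndb.ppf(0.025), upper=ndb.ppf(0.975))


def build_fbd_age_spec(fossil: FossilRecord, mode: str,
                       cap: float | None = None) -> FBDAgeSpec:
    """FBD fossil age configuration.

    ``fixed_tip``: the tip age is the fossil's minimum age. ``uniform_range``:
    the MCMC samples the age uniformly in [a, a + margin(a)], truncated at
    ``cap`` (a root-age ceiling) when given.
    """
    a = fossil.min_age
    if mode == "fixed_tip":
        return FBDAgeSpec(fossil=fossil.name, mode="fixed_tip", age=a)
    if mode != "uniform_range":
        raise InfeasibleDensityError(f"unknown FBD age mode {mode!r}")
    if cap is not None and cap < a:
        raise InfeasibleDensityError(
            f"fossil {fossil.name!r}: cap {cap} Ma below minimum age {a} Ma")
    upper = a + ndb_q95_margin(a)
    if cap is not None:
        upper = min(upper, cap)
    return FBDAgeSpec(fossil=fossil.name, mode="uniform_range", lower=a, upper=upper)
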
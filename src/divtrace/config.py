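"""Configuration objects for virtual spinal-cord cohorts and viral tracing.

A :class:`CordConfig` describes, region by region, the premotor population a
dual-injection rabies tracing experiment samples from: how many premotor
neurons there are, which fraction genuinely contacts both injected motor
pools (the true divergence rate ``d``), how the cells are spread over the
four grey-matter quadrants, and the log-normal soma-size and marker
composition of the population.  A :class:`VirusParams` describes the two
glycoprotein-deleted rabies viruses: the per-jump trans-synaptic transfer
efficiency ``e`` and an optional interference factor ``rho`` that reduces
the probability of a second infection once a first virus has entered the
cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError

REGIONS = ("cervical", "thoracic", "lumbar", "sacral")
QUADRANTS = ("DI", "DC", "VI", "VC")  # dorsal/ventral x ipsi/contra


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Convert an arithmetic mean/SD (in µm²) to log-normal (mu, sigma).

    Inverse of the standard moment relations ``mean = exp(mu + sigma²/2)``
    and ``var = mean² (exp(sigma²) - 1)``.
    """
    if mean <= 0 or sd < 0:
        raise ConfigError(f"soma moments must satisfy mean > 0, sd >= 0 "
                          f"(got mean={mean}, sd={sd})")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class RegionSpec:
    """Premotor-population description for one spinal-cord region.

    Parameters
    ----------
    n_premotor : int
        Premotor neurons per animal in this region.
    divergent_fraction : float
        Ground-truth fraction ``d`` of premotor neurons contacting both
        injected motor pools.
    quadrant_probs : mapping
        Probability of a cell lying in each quadrant DI/DC/VI/VC
        (dorso-ventral x ipsi-contralateral, relative to the hindlimb
        injection side); must sum to 1.
    segments : sequence of str
        Ordered segment labels (e.g. L1..L6).
    n_sections : int
        Transverse sections cut per animal in this region.
    soma_logmean, soma_logsd : float
        Log-normal parameters of the soma cross-sectional area (µm²).
    inhibitory_fraction, cholinergic_fraction : float
        Marker (GlyT2+/ChAT+) probabilities per cell.
    """

    n_premotor: int
    divergent_fraction: float
    quadrant_probs: Mapping[str, float]
    segments: Sequence[str]
    n_sections: int
    soma_logmean: float
    soma_logsd: float
    inhibitory_fraction: float = 0.0
    cholinergic_fraction: float = 0.0
    ab_split: float = 0.5  # P(A_only | single-pool); no generative ratio known

    def __post_init__(self):
        if self.n_premotor < 0:
            raise ConfigError(f"n_premotor must be >= 0, got {self.n_premotor}")
        if self.n_sections < 1:
            raise ConfigError(f"n_sections must be >= 1, got {self.n_sections}")
        _check_fraction("divergent_fraction", self.divergent_fraction)
        _check_fraction("inhibitory_fraction", self.inhibitory_fraction)
        _check_fraction("cholinergic_fraction", self.cholinergic_fraction)
        _check_fraction("ab_split", self.ab_split)
        if set(self.quadrant_probs) != set(QUADRANTS):
            raise ConfigError(
                f"quadrant_probs must have exactly the keys {QUADRANTS}, "
                f"got {sorted(self.quadrant_probs)}")
        probs = [float(self.quadrant_probs[q]) for q in QUADRANTS]
        if any(p < 0 for p in probs):
            raise ConfigError(f"quadrant_probs must be non-negative, got {probs}")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError(
                f"quadrant_probs must sum to 1 within 1e-9, got sum={sum(probs)!r}")
        if not self.segments:
            raise ConfigError("segments must be a non-empty sequence")
        if self.soma_logsd < 0:
            raise ConfigError(f"soma_logsd must be >= 0, got {self.soma_logsd}")


@dataclass
class VirusParams:
    """Two-virus labelling parameters.

    ``efficiency`` is the probability that a virus crosses any given
    premotor→motoneuron synapse ("jump efficiency" e); ``interference``
    (rho) multiplies the second virus's efficiency by (1 - rho) in a
    neuron the first virus has already entered.
    """

    efficiency: float = 0.25
    interference: float = 0.0
    colour_a: str = "eGFP"
    colour_b: str = "mCherry"

    def __post_init__(self):
        if not (0.0 < self.efficiency <= 1.0):
            raise ConfigError(
                f"efficiency must lie in (0, 1], got {self.efficiency}")
        if not (0.0 <= self.interference < 1.0):
            raise ConfigError(
                f"interference must lie in [0, 1), got {self.interference}")
        if self.colour_a == self.colour_b:
            raise ConfigError("colour_a and colour_b must differ")

    @property
    def colours(self) -> tuple[str, str]:
        return (self.colour_a, self.colour_b)


@dataclass
class CordConfig:
    """Full virtual-cord specification: per-region specs plus cohort size."""

    regions: Mapping[str, RegionSpec]
    n_animals: int = 1
    seed: int = 0
    include_motoneurons: bool = False
    n_motoneurons: int = 20  # per injected pool when include_motoneurons

    def __post_init__(self):
        if self.n_animals < 1:
            raise ConfigError(f"n_animals must be >= 1, got {self.n_animals}")
        unknown = set(self.regions) - set(REGIONS)
        if unknown:
            raise ConfigError(
                f"unknown region name(s) {sorted(unknown)}; expected subset of {REGIONS}")
        for name, spec in self.regions.items():
            if not isinstance(spec, RegionSpec):
                raise ConfigError(f"regions[{name!r}] must be a RegionSpec")

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for name, spec in d["regions"].items():
            spec["segments"] = list(spec["segments"])
            spec["quadrant_probs"] = {q: float(spec["quadrant_probs"][q])
                                      for q in QUADRANTS}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: Mapping) -> "CordConfig":
        data = dict(data)
        raw_regions = data.pop("regions", None)
        if not raw_regions:
            raise ConfigError("config must contain a non-empty 'regions' block")
        regions = {}
        for name, block in raw_regions.items():
            block = dict(block)
            if "soma_mean" in block or "soma_sd" in block:
                try:
                    mu, sigma = lognormal_from_moments(
                        block.pop("soma_mean"), block.pop("soma_sd"))
                except KeyError as exc:
                    raise ConfigError(
                        f"regions[{name!r}]: soma_mean and soma_sd must be "
                        f"given together") from exc
                block["soma_logmean"], block["soma_logsd"] = mu, sigma
            try:
                regions[name] = RegionSpec(**block)
            except TypeError as exc:
                raise ConfigError(f"regions[{name!r}]: {exc}") from exc
        try:
            return cls(regions=regions, **data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "CordConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)


_SEGMENTS = {
    "cervical": [f"C{i}" for i in range(1, 9)] + ["T1"],
    "thoracic": [f"T{i}" for i in range(2, 12)],
    "lumbar": [f"L{i}" for i in range(1, 7)],
    "sacral": [f"S{i}" for i in range(1, 5)],
}

# Printed per-quadrant labelled-cell counts pooled over injection schemes
# determine the default spatial weights; soma moments are the printed
# mean ± SD cross-sectional areas (µm²).
_DEFAULTS = {
    "lumbar": dict(n_premotor=7000, divergent_fraction=0.18,
                   quadrant_probs={"DI": 0.55, "DC": 0.035,
                                   "VI": 0.27, "VC": 0.145},
                   n_sections=90, soma=(320.0, 114.0),
                   inhibitory_fraction=0.30, cholinergic_fraction=0.02),
    "thoracic": dict(n_premotor=500, divergent_fraction=0.85,
                     quadrant_probs={"DI": 0.455, "DC": 0.02,
                                     "VI": 0.215, "VC": 0.31},
                     n_sections=60, soma=(359.0, 144.0),
                     inhibitory_fraction=0.34, cholinergic_fraction=0.02),
    "cervical": dict(n_premotor=100, divergent_fraction=0.9,
                     quadrant_probs={"DI": 0.03, "DC": 0.01,
                                     "VI": 0.22, "VC": 0.74},
                     n_sections=60, soma=(774.0, 231.0),
                     inhibitory_fraction=0.05, cholinergic_fraction=0.0),
    "sacral": dict(n_premotor=15, divergent_fraction=0.25,
                   quadrant_probs={"DI": 0.05, "DC": 0.05,
                                   "VI": 0.10, "VC": 0.80},
                   n_sections=20, soma=(710.0, 310.0),
                   inhibitory_fraction=0.30, cholinergic_fraction=0.02),
}


def default_cord_config(n_animals: int = 4, seed: int = 0,
                        regions: Sequence[str] = REGIONS) -> CordConfig:
    """A virtual cord matching the study conditions of a dual hindlimb
    injection: per-region population sizes, quadrant weights and soma-size
    moments taken from the experiment's printed counts, with ground-truth
    divergent fractions set to the corrected (true) rates the tracing model
    implies."""
    specs = {}
    for name in regions:
        d = dict(_DEFAULTS[name])
        mean, sd = d.pop("soma")
        mu, sigma = lognormal_from_moments(mean, sd)
        specs[name] = RegionSpec(segments=_SEGMENTS[name],
                                 soma_logmean=mu, soma_logsd=sigma, **d)
    return CordConfig(regions=specs, n_animals=n_animals, seed=seed)
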
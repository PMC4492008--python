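"""Run configuration and named presets.

``RunConfig`` gathers every numeric knob of the method.  The *default* preset
uses a backbone of 1000 sequences; the *fast* preset is identical except for a
100-sequence backbone, trading accuracy for speed on very large inputs.  The
decomposition stops once subsets contain at most ten sequences, and only
sequences within 25 % of the typical (median) length are eligible for the
backbone unless the restriction is disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ConfigError

DECOMPOSITION_MODES = ("hierarchical", "none", "disjoint")


@dataclass
class RunConfig:
    backbone_size: int = 1000
    subset_max: int = 10
    length_tolerance: float = 0.25
    decomposition_mode: str = "hierarchical"
    restrict_backbone_full_length: bool = True
    pseudocount: float = 1.0
    seed: int = 0
    fragment_mean: float = 500.0
    fragment_sd: float = 60.0
    fragment_fraction: float = 0.25
    #: optional user-declared typical locus length, overriding the median
    typical_length: float | None = field(default=None)

    def __post_init__(self):
        if self.backbone_size < 1 or self.subset_max < 1:
            raise ConfigError("backbone_size and subset_max must be positive")
        if self.backbone_size < self.subset_max:
            raise ConfigError("backbone_size must be >= subset_max")
        if not 0.0 < self.length_tolerance < 1.0:
            raise ConfigError("length_tolerance must lie in (0, 1)")
        if self.decomposition_mode not in DECOMPOSITION_MODES:
            raise ConfigError(
                f"unknown decomposition mode {self.decomposition_mode!r}; "
                f"expected one of {DECOMPOSITION_MODES}"
            )
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be positive")
        if not 0.0 <= self.fragment_fraction <= 1.0:
            raise ConfigError("fragment_fraction must lie in [0, 1]")
        if self.fragment_mean <= 0 or self.fragment_sd < 0:
            raise ConfigError("fragment_mean must be > 0 and fragment_sd >= 0")

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


_PRESETS = {
    "default": {},
    "fast": {"backbone_size": 100},
}


def preset(name: str, **overrides) -> RunConfig:
    """Named configuration: ``default`` (backbone 1000) or ``fast`` (100)."""
    try:
        base = _PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; expected one of {sorted(_PRESETS)}"
        ) from None
    return RunConfig(**{**base, **overrides})
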
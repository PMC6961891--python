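"""Analysis configuration with the method's standard default settings."""

from __future__ import annotations

import dataclasses

from .errors import ConfigurationError
from .ricker import MIN_SEGMENT_POINTS


@dataclasses.dataclass(frozen=True)
class DsdConfig:
    """Tunable settings of a break-point analysis.

    Defaults are the method's standard settings: AICc model selection, segments
    of at least four sequential data points, a two-unit equivalence band,
    pruning of combinations below 0.001 Akaike weight, and the 0.8 / 0.2
    break-weight decision thresholds.
    """

    criterion: str = "AICc"
    min_segment: int = MIN_SEGMENT_POINTS
    equivalence_delta: float = 2.0
    prune_threshold: float = 0.001
    supported_threshold: float = 0.8
    erroneous_threshold: float = 0.2
    max_breaks: int | None = None
    seed: int | None = None
    #: renormalize retained weights after pruning (the alternative reports
    #: the pre-pruning weights unchanged)
    renormalize: bool = True

    def __post_init__(self) -> None:
        if self.criterion not in ("AICc", "AIC"):
            raise ConfigurationError(
                f"criterion must be 'AICc' or 'AIC', got {self.criterion!r}"
            )
        if self.criterion == "AICc" and self.min_segment < 4:
            raise ConfigurationError(
                "AICc requires segments of at least 4 data points; "
                "raise min_segment or switch to criterion='AIC'"
            )
        if self.min_segment < 3:
            raise ConfigurationError("min_segment must be at least 3")
        if self.equivalence_delta <= 0:
            raise ConfigurationError("equivalence_delta must be positive")
        if not 0 <= self.prune_threshold < 1:
            raise ConfigurationError("prune_threshold must be in [0, 1)")
        if not 0 <= self.erroneous_threshold <= self.supported_threshold <= 1:
            raise ConfigurationError(
                "need 0 <= erroneous_threshold <= supported_threshold <= 1"
            )
        if self.max_breaks is not None and self.max_breaks < 0:
            raise ConfigurationError("max_breaks must be non-negative")
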
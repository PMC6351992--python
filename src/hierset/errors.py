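"""Exception hierarchy for hierset."""

from __future__ import annotations


class HiersetError(Exception):
    """Base class for all hierset errors."""


class FormatError(HiersetError):
    """An input file does not conform to its expected dialect."""


class ValidationError(HiersetError):
    """Loaded content violates a structural invariant (cycle, dangling edge...)."""


class ConceptNotFoundError(HiersetError, KeyError):
    """A concept id was queried that is not present in the graph."""

    def __init__(self, concept_id: str):
        super().__init__(f"concept id not in graph: {concept_id!r}")
        self.concept_id = concept_id


class RuleParseError(HiersetError):
    """An ECL-lite rule expression could not be parsed."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UndefinedRatioError(HiersetError):
    """A ratio or percent is undefined because its denominator is empty/zero."""
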
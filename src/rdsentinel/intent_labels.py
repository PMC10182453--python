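"""Session intent label conventions: RD=0, NEWS=1, OTHER=2 everywhere."""

from __future__ import annotations

__all__ = ["RD", "NEWS", "OTHER", "INTENT_NAMES", "as_intent_index", "as_intent_name"]

RD, NEWS, OTHER = 0, 1, 2
INTENT_NAMES = ("RD", "NEWS", "OTHER")
_BY_NAME = {name: i for i, name in enumerate(INTENT_NAMES)}


def as_intent_index(label) -> int:
    """Coerce an intent label ("RD"/"NEWS"/"OTHER" or 0/1/2) to its index."""
    if isinstance(label, str):
        try:
            return _BY_NAME[label.upper()]
        except KeyError:
            raise ValueError(f"unknown intent label {label!r}") from None
    idx = int(label)
    if idx not in (0, 1, 2):
        raise ValueError(f"intent index must be 0, 1 or 2, got {label!r}")
    return idx


def as_intent_name(label) -> str:
    return INTENT_NAMES[as_intent_index(label)]
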
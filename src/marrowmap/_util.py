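"""Small shared helpers."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Undefined:
    """Marker for a quantity that is undefined on this input.

    Carries a human-readable reason (e.g. "no cells satisfy the
    condition").  Truthiness is False so callers can write
    ``if result: ...``.
    """

    reason: str

    def __bool__(self) -> bool:
        return False

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Undefined({self.reason!r})"


def check_seed(seed: int) -> int:
    if not isinstance(seed, (int,)) or isinstance(seed, bool):
        raise TypeError(f"seed must be an integer, got {seed!r}")
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return int(seed)
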
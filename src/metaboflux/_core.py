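"""Shared small utilities: flagged undefined values."""
from __future__ import annotations

import math


class Undefined(float):
    """A NaN that remembers why it is undefined.

    Quantities such as spare respiratory capacity with nonpositive basal
    respiration, or a surrogate ratio with a zero denominator, are reported
    as an ``Undefined`` value rather than a bare NaN: it behaves like
    ``float('nan')`` in arithmetic but carries a ``flag`` string naming the
    degeneracy, so downstream tables can surface the reason instead of
    silently propagating NaN.
    """

    flag: str

    def __new__(cls, flag: str) -> "Undefined":
        obj = super().__new__(cls, math.nan)
        obj.flag = flag
        return obj

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Undefined({self.flag!r})"


def is_undefined(x: object) -> bool:
    """True if ``x`` is a flagged undefined value."""
    return isinstance(x, Undefined)


def flag_of(x: object) -> str | None:
    """Return the flag string of an Undefined value, else None."""
    return x.flag if isinstance(x, Undefined) else None
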
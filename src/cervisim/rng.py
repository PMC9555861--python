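"""Counter-based random numbers for reproducible, common-random-number runs.

Every uniform draw is a pure function of ``(key, stream, counter)`` where the
key identifies a woman within a scenario *family* (cohort x frequency x
modality x variant, master seed mixed in) and the stream separates purposes:

* stream 0 — natural-history events, counter = month index (one draw per
  month, so the disease shock sequence is identical across delay arms);
* stream 1 — occult-lesion assignment, counter = month index;
* stream 2 — screening/management cascade, counter = running draw count;
* stream 3 — vaccination assignment, counter = 0.

Because draws are stateless, arms of the same scenario family share the
disease shocks exactly (common random numbers), which is what lets the
delay-vs-no-delay differences isolate the delay effect.

The generator is the splitmix64 finalizer applied twice; it is implemented
identically here (masked Python ints) and in the numba kernel (uint64
arithmetic), and the two are tested to be bit-identical.
"""

from __future__ import annotations

_MASK = (1 << 64) - 1
GOLDEN = 0x9E3779B97F4A7C15
_C2 = 0xC2B2AE3D27D4EB4F


def mix64(z: int) -> int:
    """splitmix64 finalizer (Steele, Lea & Flood)."""
    z &= _MASK
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
    return z ^ (z >> 31)


def woman_key(master_seed: int, family_id: int, woman_index: int) -> int:
    """Per-woman key; excludes the delay arm so arms share shocks."""
    k = mix64((master_seed & _MASK) ^ (GOLDEN * (family_id + 1) & _MASK))
    return mix64(k ^ (GOLDEN * (woman_index + 1) & _MASK))


def u01(key: int, stream: int, counter: int) -> float:
    """Uniform(0,1) as a pure function of (key, stream, counter)."""
    z = mix64((key & _MASK) ^ (GOLDEN * (stream + 1) & _MASK))
    z = mix64(z ^ (_C2 * (counter + 1) & _MASK))
    return (z >> 11) * 2.0**-53


def string_id(s: str) -> int:
    """Stable 64-bit FNV-1a hash of a scenario-family label."""
    h = 0xCBF29CE484222325
    for b in s.encode():
        h = ((h ^ b) * 0x100000001B3) & _MASK
    return h


class DrawStream:
    """Sequential view over stream 2 (cascade draws) for one woman."""

    __slots__ = ("key", "counter")

    def __init__(self, key: int, counter: int = 0):
        self.key = key
        self.counter = counter

    def next(self) -> float:
        u = u01(self.key, 2, self.counter)
        self.counter += 1
        return u
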
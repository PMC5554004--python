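"""Shared numerical helpers: phase wrapping and reproducible seed splitting."""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi

# Multipliers for the arithmetic seed-splitting rule.  Chosen as large primes so
# nearby master seeds give unrelated child streams; children stay below 2**31.
_SEED_MULT = 1_000_003
_SEED_STEP = 7_919


def wrap_phase(x):
    """Wrap angles into the half-open interval (-pi, pi].

    The convention matches the range of the four-quadrant arctangent used to
    extract instantaneous phase, with the boundary assigned to +pi.
    """
    w = np.mod(np.asarray(x, dtype=float), TWO_PI)
    w = np.where(w > np.pi, w - TWO_PI, w)
    return w


def split_seed(master_seed: int, index: int) -> int:
    """Derive a child seed from a master seed by a fixed arithmetic rule.

    ``child = (master * 1000003 + 7919 * index + 1) mod 2**31`` — documented so
    any single participant of a cohort can be regenerated in isolation.
    """
    return (int(master_seed) * _SEED_MULT + _SEED_STEP * int(index) + 1) % (2**31)


def rng_from(seed) -> np.random.Generator:
    return np.random.default_rng(int(seed))
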
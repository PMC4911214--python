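"""Shared numerical helpers and seeded substream derivation."""

from __future__ import annotations

import hashlib
import math

import numpy as np

LN2 = math.log(2.0)


def substream(seed: int, name: str) -> np.random.Generator:
    """Derive an independent, named random substream from a root seed.

    Each generator in the simulation pulls from its own substream, so adding
    or reordering generators never perturbs the draws of the others.
    """
    digest = hashlib.blake2b(name.encode(), digest_size=8).digest()
    key = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def int_exp2(g: float, t: float) -> float:
    """Integral of 2**(g*s) over s in [0, t], stable near g = 0."""
    if t < 0:
        raise ValueError("integration time must be non-negative")
    x = g * LN2
    if abs(x * t) < 1e-12:
        return t
    return math.expm1(x * t) / x


def lognormal_sigma(cv: float) -> float:
    """Log-space sigma of a multiplicative log-normal with the given CV."""
    return math.sqrt(math.log1p(cv * cv))


def multiplicative_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise factors with coefficient of
    variation `cv`; exactly ones when cv == 0."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv == 0:
        return np.ones(size)
    sigma = lognormal_sigma(cv)
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)
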
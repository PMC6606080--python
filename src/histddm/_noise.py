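"""Seeded noise banks for the grid simulators.

A bank holds all parameter-independent random draws of one simulation
chunk: the raw starting-point uniforms, the per-trace drift-variability
normals, the Euler increment normals (one or two accumulators) and the
timeout tie-break uniforms.  Banks are keyed by (kind, seed, chunk offset,
shape) and LRU-cached: within a fitting session every objective evaluation
reuses the same bank (common random numbers), which makes the likelihood
surface deterministic and removes the RNG cost from the inner loop.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

_MAX_CACHE_ELEMENTS = 60_000_000
_cache: OrderedDict[tuple, dict] = OrderedDict()
_cache_elements = 0


def _entry_elements(bank: dict) -> int:
    return int(sum(a.size for a in bank.values()))


def noise_bank(kind: str, seed: int, lo: int, n: int, n_steps: int) -> dict:
    """Raw draws for traces [lo, lo+n) of a simulation with this seed."""
    global _cache_elements
    key = (kind, int(seed), int(lo), int(n), int(n_steps))
    hit = _cache.get(key)
    if hit is not None:
        _cache.move_to_end(key)
        return hit
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**63), lo]))
    bank = {
        "u": rng.uniform(-1.0, 1.0, n),
        "v": rng.standard_normal(n),
        "noise": rng.standard_normal((n, n_steps)),
        "tie": rng.random(n),
    }
    if kind == "dual":
        bank["noise_b"] = rng.standard_normal((n, n_steps))
    sz = _entry_elements(bank)
    while _cache and _cache_elements + sz > _MAX_CACHE_ELEMENTS:
        _, old = _cache.popitem(last=False)
        _cache_elements -= _entry_elements(old)
    _cache[key] = bank
    _cache_elements += sz
    return bank


def clear_cache() -> None:
    global _cache_elements
    _cache.clear()
    _cache_elements = 0
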
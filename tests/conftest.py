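"""Shared fixtures and independent naive oracles for descriptor checks.

The oracle functions here recompute every descriptor with plain Python
loops and explicit arithmetic, independently of the package's vectorised
implementations, so agreement between the two routes is a meaningful check.
"""

from __future__ import annotations

import numpy as np
import pytest

# The classic worked example: a 22-residue sequence whose reduced-alphabet
# encoding, composition, transitions and distributions are known by hand.
EXAMPLE_SEQUENCE = "VCCPPVCVVCPPVCVPVPPCCV"
EXAMPLE_CODES = "0112201001220102022110"


@pytest.fixture
def example_codes() -> np.ndarray:
    return np.array([int(c) for c in EXAMPLE_CODES], dtype=np.int8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


# --------------------------------------------------------------------------
# Naive oracles (pure Python, loop-based)

def naive_composition(codes) -> list[float]:
    codes = list(int(c) for c in codes)
    return [100.0 * sum(1 for c in codes if c == g) / len(codes) for g in range(7)]


def naive_transition(codes) -> list[float]:
    codes = list(int(c) for c in codes)
    pairs = [(g, h) for g in range(7) for h in range(g + 1, 7)]
    out = []
    for g, h in pairs:
        count = 0
        for i in range(len(codes) - 1):
            if {codes[i], codes[i + 1]} == {g, h}:
                count += 1
        out.append(100.0 * count / (len(codes) - 1) if len(codes) > 1 else 0.0)
    return out


def naive_distribution(codes) -> list[float]:
    import math

    codes = list(int(c) for c in codes)
    L = len(codes)
    out = []
    for g in range(7):
        positions = [i + 1 for i, c in enumerate(codes) if c == g]
        n = len(positions)
        if n == 0:
            out.extend([0.0] * 5)
            continue
        ordinals = [1] + [max(1, math.floor(q * n + 0.5)) for q in (0.25, 0.5, 0.75, 1.0)]
        out.extend(100.0 * positions[r - 1] / L for r in ordinals)
    return out


def naive_triad_counts(codes) -> list[int]:
    codes = list(int(c) for c in codes)
    counts = [0] * 343
    for i in range(len(codes) - 2):
        idx = codes[i] + 7 * codes[i + 1] + 49 * codes[i + 2]
        counts[idx] += 1
    return counts


def naive_triad_normalized(codes) -> list[float]:
    f = naive_triad_counts(codes)
    fmax = max(f)
    if fmax == 0:
        return [0.0] * 343
    fmin = min(f)
    return [(x - fmin) / fmax for x in f]


def naive_region_bounds(L: int) -> dict[str, tuple[int, int]]:
    b = [0, L // 4, 2 * L // 4, 3 * L // 4, L]
    return {
        "A": (b[0], b[1]), "B": (b[1], b[2]), "C": (b[2], b[3]), "D": (b[3], b[4]),
        "E": (b[0], b[2]), "F": (b[2], b[4]), "G": (b[1], b[3]),
        "H": (b[0], b[3]), "I": (b[1], b[4]), "J": (L // 8, 7 * L // 8),
    }
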
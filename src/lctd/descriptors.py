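"""Composition/transition/distribution and conjoint-triad sequence descriptors.

Three per-protein feature encodings are provided, all computed on the
reduced 7-class alphabet (see :mod:`lctd.encoding`):

``CT``
    Conjoint triads over the whole sequence: frequencies of every ordered
    triple of consecutive residue classes (7^3 = 343 types), normalised per
    sequence.  Captures short-range (3-mer) context, ignores where in the
    sequence it occurs.

``LD``
    Local descriptor: composition (C, 7), transition (T, 21) and
    distribution (D, 35) statistics on each of the 10 regions A-J,
    concatenated to 10 x 63 = 630 values.  Captures positional/discontinuous
    structure, but only pairwise adjacency.

``LCTD``
    Local conjoint triad descriptor: per region, C + T + D + the 343 triad
    values (406), concatenated over the 10 regions to 4060 values.  Combines
    the 3-mer context of CT with the regional decomposition of LD.

A protein pair is encoded by concatenating the two per-protein vectors in
the order given by the pair, so pair dimensions are 686 / 1260 / 8120.

Scale conventions: C, T and D are percentages on a 0-100 scale; normalised
triad values lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import (
    N_GROUPS,
    REGION_ORDER,
    EncodedSequence,
    split_regions,
)

__all__ = [
    "N_TRIADS",
    "TRANSITION_PAIRS",
    "PROTEIN_DIMS",
    "PAIR_DIMS",
    "DescriptorBlock",
    "triad_index",
    "composition",
    "transition",
    "distribution",
    "triad_frequencies",
    "normalize_triads",
    "conjoint_triad",
    "ct_protein_vector",
    "ld_protein_vector",
    "lctd_protein_vector",
    "protein_vector",
    "pair_vector",
    "feature_names",
]

#: Number of ordered residue-class triples.
N_TRIADS = N_GROUPS**3

#: Unordered class pairs {g, h}, g < h, in lexicographic order; fixes the
#: layout of the 21 transition values.
TRANSITION_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (g, h) for g in range(N_GROUPS) for h in range(g + 1, N_GROUPS)
)

#: Distribution anchor quantiles after the mandatory first occurrence.
_D_QUANTILES = (0.25, 0.5, 0.75, 1.0)

#: Per-protein feature dimensions by method name.
PROTEIN_DIMS = {"ct": N_TRIADS, "ld": 630, "lctd": 4060}
#: Per-pair feature dimensions by method name.
PAIR_DIMS = {m: 2 * d for m, d in PROTEIN_DIMS.items()}

# (g, h) -> flat transition slot, symmetric.
_PAIR_SLOT = np.full((N_GROUPS, N_GROUPS), -1, dtype=np.int64)
for _k, (_g, _h) in enumerate(TRANSITION_PAIRS):
    _PAIR_SLOT[_g, _h] = _k
    _PAIR_SLOT[_h, _g] = _k


def triad_index(c1: int, c2: int, c3: int) -> int:
    """Flat index of the ordered class triple (c1, c2, c3).

    The first symbol is the least-significant digit: ``i = c1 + 7 c2 + 49 c3``,
    so triple (1,0,0) -> 1, (0,1,0) -> 7, (3,1,0) -> 10.
    """
    return c1 + N_GROUPS * c2 + N_GROUPS**2 * c3


def _as_codes(enc: EncodedSequence | np.ndarray) -> np.ndarray:
    if isinstance(enc, EncodedSequence):
        return enc.codes
    return np.asarray(enc, dtype=np.int8)


def composition(enc: EncodedSequence | np.ndarray) -> np.ndarray:
    """Percentage of region residues in each of the 7 classes (sums to 100)."""
    codes = _as_codes(enc)
    if codes.size == 0:
        raise ValueError("composition of an empty region is undefined")
    counts = np.bincount(codes, minlength=N_GROUPS)
    return 100.0 * counts / codes.size


def transition(enc: EncodedSequence | np.ndarray) -> np.ndarray:
    """Percentage of adjacent positions switching between each class pair.

    For each unordered pair {g, h} the numerator counts adjacent positions
    whose classes change between g and h in either direction; the denominator
    is region length - 1.  A length-1 region has no adjacent positions and
    yields the zero vector.
    """
    codes = _as_codes(enc)
    if codes.size == 0:
        raise ValueError("transition of an empty region is undefined")
    out = np.zeros(len(TRANSITION_PAIRS))
    if codes.size == 1:
        return out
    a, b = codes[:-1], codes[1:]
    change = a != b
    slots = _PAIR_SLOT[a[change], b[change]]
    np.add.at(out, slots, 1.0)
    return 100.0 * out / (codes.size - 1)


def _anchor_ordinals(n: int) -> np.ndarray:
    """Occurrence ordinals (1-based) probed by the distribution descriptor.

    For a class with n occurrences: the first occurrence, then the
    round-half-up of 25%, 50%, 75% and 100% of n, clamped to at least 1.
    """
    qs = np.floor(np.asarray(_D_QUANTILES) * n + 0.5).astype(np.int64)
    return np.concatenate(([1], np.maximum(qs, 1)))


def distribution(enc: EncodedSequence | np.ndarray) -> np.ndarray:
    """Positional spread of each class within the region (35 percentages).

    For each class g (class-major order), 5 values: the 1-based position of
    the first, 25%-th, 50%-th, 75%-th and last occurrence of g, each divided
    by the region length and scaled to percent.  Absent classes contribute 5
    zeros.
    """
    codes = _as_codes(enc)
    if codes.size == 0:
        raise ValueError("distribution of an empty region is undefined")
    out = np.zeros(N_GROUPS * 5)
    for g in range(N_GROUPS):
        positions = np.flatnonzero(codes == g) + 1  # 1-based
        n = positions.size
        if n == 0:
            continue
        ordinals = _anchor_ordinals(n)
        out[g * 5 : g * 5 + 5] = 100.0 * positions[ordinals - 1] / codes.size
    return out


def triad_frequencies(enc: EncodedSequence | np.ndarray) -> np.ndarray:
    """Raw counts of every ordered class triple over consecutive windows.

    Counts all length-3 windows inside the given (sub)sequence only; windows
    never span region boundaries.  Regions shorter than 3 give all zeros.
    """
    codes = _as_codes(enc).astype(np.int64)
    if codes.size < 3:
        return np.zeros(N_TRIADS, dtype=np.int64)
    idx = codes[:-2] + N_GROUPS * codes[1:-1] + N_GROUPS**2 * codes[2:]
    return np.bincount(idx, minlength=N_TRIADS)


def normalize_triads(freqs: np.ndarray, min_max: bool = False) -> np.ndarray:
    """Length-normalise a triad count vector to [0, 1].

    The default follows the original conjoint-triad recipe literally:
    ``d_i = (f_i - min_j f_j) / max_j f_j``.  ``min_max=True`` switches to
    standard min-max scaling (divide by ``max - min``) as a documented
    variant.  An all-zero count vector maps to all zeros.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    fmax = freqs.max(initial=0.0)
    if fmax <= 0:
        return np.zeros_like(freqs)
    fmin = freqs.min()
    denom = (fmax - fmin) if min_max else fmax
    if denom <= 0:  # constant non-zero vector under min-max
        return np.zeros_like(freqs)
    return (freqs - fmin) / denom


def conjoint_triad(
    enc: EncodedSequence | np.ndarray, min_max: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Raw and normalised triad vectors (each length 343) for a region."""
    f = triad_frequencies(enc)
    return f, normalize_triads(f, min_max=min_max)


@dataclass(frozen=True)
class DescriptorBlock:
    """One region's descriptor values: C(7), T(21), D(35), CT(343)."""

    C: np.ndarray
    T: np.ndarray
    D: np.ndarray
    CT: np.ndarray

    def ld_values(self) -> np.ndarray:
        return np.concatenate([self.C, self.T, self.D])

    def lctd_values(self) -> np.ndarray:
        return np.concatenate([self.C, self.T, self.D, self.CT])


def _region_block(codes: np.ndarray, min_max: bool = False) -> DescriptorBlock:
    _, d = conjoint_triad(codes, min_max=min_max)
    return DescriptorBlock(
        C=composition(codes),
        T=transition(codes),
        D=distribution(codes),
        CT=d,
    )


def ct_protein_vector(enc: EncodedSequence, min_max: bool = False) -> np.ndarray:
    """Whole-sequence conjoint-triad vector (343 normalised values)."""
    _, d = conjoint_triad(enc, min_max=min_max)
    return d


def _region_blocks(
    enc: EncodedSequence, min_max: bool = False
) -> list[DescriptorBlock]:
    regions = split_regions(enc.length)
    return [
        _region_block(enc.codes[start:end], min_max=min_max)
        for start, end in (regions[label] for label in REGION_ORDER)
    ]


def ld_protein_vector(enc: EncodedSequence) -> np.ndarray:
    """Local descriptor: C+T+D per region A-J, concatenated (630 values)."""
    return np.concatenate([blk.ld_values() for blk in _region_blocks(enc)])


def lctd_protein_vector(enc: EncodedSequence, min_max: bool = False) -> np.ndarray:
    """Local conjoint triad descriptor: C+T+D+CT per region A-J (4060 values)."""
    return np.concatenate(
        [blk.lctd_values() for blk in _region_blocks(enc, min_max=min_max)]
    )


def protein_vector(enc: EncodedSequence, method: str) -> np.ndarray:
    """Dispatch to the per-protein encoder for ``method`` in {ct, ld, lctd}."""
    method = method.lower()
    if method == "ct":
        return ct_protein_vector(enc)
    if method == "ld":
        return ld_protein_vector(enc)
    if method == "lctd":
        return lctd_protein_vector(enc)
    raise ValueError(f"unknown descriptor method {method!r}")


def pair_vector(
    enc_a: EncodedSequence, enc_b: EncodedSequence, method: str
) -> np.ndarray:
    """Feature vector of a protein pair: A's vector followed by B's.

    The orientation is exactly as given; swapping the arguments swaps the two
    halves of the result.
    """
    try:
        va = protein_vector(enc_a, method)
    except Exception as err:
        raise type(err)(f"protein {enc_a.id!r}: {err}") from err
    try:
        vb = protein_vector(enc_b, method)
    except Exception as err:
        raise type(err)(f"protein {enc_b.id!r}: {err}") from err
    return np.concatenate([va, vb])


def _block_names(prefix: str, with_ct: bool) -> list[str]:
    names = [f"{prefix}.C{g}" for g in range(N_GROUPS)]
    names += [f"{prefix}.T{g}{h}" for g, h in TRANSITION_PAIRS]
    names += [
        f"{prefix}.D{g}.{anchor}"
        for g in range(N_GROUPS)
        for anchor in ("first", "q25", "q50", "q75", "q100")
    ]
    if with_ct:
        names += [f"{prefix}.CT{i:03d}" for i in range(N_TRIADS)]
    return names


def feature_names(method: str, scope: str = "protein") -> list[str]:
    """Human-readable column names matching the frozen feature layout."""
    method = method.lower()
    if method == "ct":
        names = [f"CT{i:03d}" for i in range(N_TRIADS)]
    elif method in ("ld", "lctd"):
        names = []
        for label in REGION_ORDER:
            names += _block_names(label, with_ct=(method == "lctd"))
    else:
        raise ValueError(f"unknown descriptor method {method!r}")
    if scope == "protein":
        return names
    if scope == "pair":
        return [f"A.{n}" for n in names] + [f"B.{n}" for n in names]
    raise ValueError(f"unknown scope {scope!r}")
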
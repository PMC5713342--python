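"""Synthetic proteomes and labelled interaction datasets.

The generator emulates the construction of a sequence-based PPI benchmark:

* a proteome of random sequences (>= 50 residues) over the 20 standard
  amino acids, each protein tagged with a subcellular localization label;
* positive pairs that carry a learnable sequence signal: a compatible pair
  of short interface motifs (fixed patterns at the reduced-alphabet level)
  implanted into the two partners of an interacting pair;
* negative pairs sampled only between proteins with *differing*
  localization, never duplicating a positive pair.

The interaction signal is implanted at the 7-class reduced-alphabet level
(each motif position is filled with a residue drawn from the prescribed
class), so all descriptor families can in principle detect it.  ``motif
strength`` is the probability that a positive pair actually receives the
motif pair; at strength 0 the dataset carries no signal at all and any
classifier should score at chance level.

Proteins carrying both compatible motifs would, by construction, interact;
such combinations are therefore excluded from the negative set, mirroring
the benchmark convention that likely interactions must not be labelled
negative.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .encoding import GROUP_MEMBERS, N_GROUPS, ProteinRecord

__all__ = ["SyntheticConfig", "InteractionPair", "generate_proteome", "generate_pairs", "generate_dataset"]

_AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class InteractionPair:
    """A labelled protein pair: label 1 = interacting, 0 = non-interacting."""

    id_a: str
    id_b: str
    label: int


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a balanced 2,000-pair dataset (1,000 positives, 1,000
    negatives) drawn from a 40,000-protein proteome with uniform lengths in
    [50, 100], four localization compartments, and a strong interaction
    signal: a 6-residue motif pair implanted into 90% of positive pairs.
    The proteome is deliberately much larger than the pair list so that
    motif carriers stay rare among the proteins entering negative pairs, and
    the short sequences keep the per-feature signal recoverable from a
    2,000-pair training set.
    """

    n_proteins: int = 40000
    min_length: int = 50
    max_length: int = 100
    length_distribution: str = "uniform"  # or "lognormal"
    n_localizations: int = 4
    n_positive: int = 1000
    n_negative: int = 1000
    motif_length: int = 6
    motif_strength: float = 0.9
    background: tuple[float, ...] | None = None  # per-letter probs, default uniform
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_length < 50:
            raise ValueError("minimum protein length must be >= 50")
        if self.max_length < self.min_length:
            raise ValueError("max_length < min_length")
        if not (0.0 <= self.motif_strength <= 1.0):
            raise ValueError("motif_strength must lie in [0, 1]")
        if self.motif_length < 1 or self.motif_length > self.min_length:
            raise ValueError("motif_length must lie in [1, min_length]")
        if self.n_localizations < 2:
            raise ValueError("need at least 2 localization compartments")
        if self.length_distribution not in ("uniform", "lognormal"):
            raise ValueError(f"unknown length distribution {self.length_distribution!r}")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=np.float64)
            if bg.size != 20 or (bg < 0).any() or not np.isclose(bg.sum(), 1.0):
                raise ValueError("background must be 20 non-negative probs summing to 1")
        if self.n_proteins < 2 * self.n_positive:
            raise ValueError(
                "positive pairs use disjoint proteins: need n_proteins >= "
                f"2 * n_positive = {2 * self.n_positive}"
            )

    def as_dict(self) -> dict:
        return asdict(self)


def _sample_length(rng: np.random.Generator, cfg: SyntheticConfig) -> int:
    if cfg.length_distribution == "uniform":
        return int(rng.integers(cfg.min_length, cfg.max_length + 1))
    # log-normal shaped to sit mostly inside [min, max], then clipped
    mu = np.log((cfg.min_length + cfg.max_length) / 2.0)
    val = int(np.round(rng.lognormal(mean=mu, sigma=0.35)))
    return int(np.clip(val, cfg.min_length, cfg.max_length))


def generate_proteome(cfg: SyntheticConfig) -> list[ProteinRecord]:
    """Random proteome with localization labels, reproducible from the seed.

    Residues are drawn i.i.d. from the background distribution (uniform over
    the 20 letters unless configured); localizations are assigned uniformly
    over ``loc0 .. loc{n-1}``.
    """
    rng = np.random.default_rng(cfg.seed)
    bg = (
        np.asarray(cfg.background, dtype=np.float64)
        if cfg.background is not None
        else np.full(20, 1.0 / 20.0)
    )
    width = len(str(cfg.n_proteins))
    records = []
    letters = np.array(_AMINO_ACIDS)
    for i in range(cfg.n_proteins):
        length = _sample_length(rng, cfg)
        seq = "".join(rng.choice(letters, size=length, p=bg))
        loc = f"loc{int(rng.integers(cfg.n_localizations))}"
        records.append(
            ProteinRecord(id=f"P{i:0{width}d}", sequence=seq, localization=loc)
        )
    return records


def _random_motif(rng: np.random.Generator, length: int) -> np.ndarray:
    """A fixed residue-class pattern of the given length."""
    return rng.integers(0, N_GROUPS, size=length)


def _implant(
    rng: np.random.Generator, sequence: str, motif_classes: np.ndarray
) -> str:
    """Overwrite a random window of the sequence with residues realising
    the motif's class pattern (length preserved)."""
    L, m = len(sequence), motif_classes.size
    start = int(rng.integers(0, L - m + 1))
    residues = "".join(
        GROUP_MEMBERS[c][int(rng.integers(len(GROUP_MEMBERS[c])))]
        for c in motif_classes
    )
    return sequence[:start] + residues + sequence[start + m :]


def generate_pairs(
    proteome: list[ProteinRecord], cfg: SyntheticConfig
) -> tuple[list[ProteinRecord], list[InteractionPair]]:
    """Build labelled positive and negative pairs over a proteome.

    Positives are disjoint protein pairs (each protein belongs to at most
    one interacting pair); with probability ``motif_strength`` the pair
    receives the compatible motif pair, implanted into partner A and partner
    B respectively.  Negatives are sampled uniformly from cross-localization
    protein pairs, excluding pairs already positive and combinations of
    compatible motif carriers.

    Returns the (possibly motif-modified) proteome and the pair list,
    positives first.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = len(proteome)
    if cfg.n_positive * 2 > n:
        raise ValueError("not enough proteins for disjoint positive pairs")

    motif_a = _random_motif(rng, cfg.motif_length)
    motif_b = _random_motif(rng, cfg.motif_length)

    order = rng.permutation(n)
    records = list(proteome)
    pairs: list[InteractionPair] = []
    carriers_a: set[int] = set()
    carriers_b: set[int] = set()
    positive_keys: set[tuple[int, int]] = set()
    for k in range(cfg.n_positive):
        ia, ib = int(order[2 * k]), int(order[2 * k + 1])
        if rng.random() < cfg.motif_strength:
            ra, rb = records[ia], records[ib]
            records[ia] = ProteinRecord(
                id=ra.id,
                sequence=_implant(rng, ra.sequence, motif_a),
                localization=ra.localization,
            )
            records[ib] = ProteinRecord(
                id=rb.id,
                sequence=_implant(rng, rb.sequence, motif_b),
                localization=rb.localization,
            )
            carriers_a.add(ia)
            carriers_b.add(ib)
        positive_keys.add((min(ia, ib), max(ia, ib)))
        pairs.append(InteractionPair(records[ia].id, records[ib].id, 1))

    # Negative sampling: uniform over cross-localization pairs, rejecting
    # positives and compatible-carrier combinations.
    negatives: set[tuple[int, int]] = set()
    neg_pairs: list[InteractionPair] = []
    max_attempts = 200 * max(cfg.n_negative, 1)
    attempts = 0
    while len(neg_pairs) < cfg.n_negative:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "could not sample enough negative pairs under the "
                "cross-localization constraint; increase n_proteins or "
                "n_localizations"
            )
        ia, ib = (int(x) for x in rng.integers(0, n, size=2))
        if ia == ib:
            continue
        if records[ia].localization == records[ib].localization:
            continue
        key = (min(ia, ib), max(ia, ib))
        if key in positive_keys or key in negatives:
            continue
        if (ia in carriers_a and ib in carriers_b) or (
            ib in carriers_a and ia in carriers_b
        ):
            continue  # compatible motif carriers would interact
        negatives.add(key)
        neg_pairs.append(InteractionPair(records[ia].id, records[ib].id, 0))
    return records, pairs + neg_pairs


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[list[ProteinRecord], list[InteractionPair]]:
    """Proteome + labelled pairs in one call (both driven by ``cfg.seed``)."""
    proteome = generate_proteome(cfg)
    return generate_pairs(proteome, cfg)
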
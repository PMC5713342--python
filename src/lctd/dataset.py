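"""Assembling pair feature matrices and reading/writing the text formats.

The on-disk formats are deliberately plain: FASTA for sequences, a
two-column TSV for localization labels, a three-column TSV for pairs
(id_a, id_b, label), and the feature matrix as TSV with a JSON sidecar
describing the column layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import PAIR_DIMS, feature_names, protein_vector
from .encoding import ProteinRecord, encode_sequence
from .synthetic import InteractionPair

__all__ = [
    "encode_pairs",
    "read_pairs",
    "write_pairs",
    "write_localizations",
    "write_feature_matrix",
    "read_feature_matrix",
]


def read_pairs(path: str | Path, sep: str = "\t") -> list[InteractionPair]:
    """Read a (id_a, id_b, label) delimited pair list; '#' lines are comments."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            label = int(parts[2])
            if label not in (0, 1):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {parts[2]!r}")
            pairs.append(InteractionPair(parts[0], parts[1], label))
    return pairs


def write_pairs(pairs: list[InteractionPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#id_a\tid_b\tlabel\n")
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.label}\n")


def write_localizations(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.localization is not None:
                fh.write(f"{rec.id}\t{rec.localization}\n")


def encode_pairs(
    records: list[ProteinRecord],
    pairs: list[InteractionPair],
    method: str = "lctd",
    dtype: str = "float32",
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Feature matrix, labels and id pairs for a labelled pair list.

    Per-protein vectors are computed once per distinct protein and reused
    across pairs.  Raises ``KeyError`` naming any pair member missing from
    ``records``.
    """
    method = method.lower()
    by_id: dict[str, ProteinRecord] = {rec.id: rec for rec in records}
    cache: dict[str, np.ndarray] = {}

    def vec(pid: str) -> np.ndarray:
        if pid not in cache:
            if pid not in by_id:
                raise KeyError(f"pair references unknown protein id {pid!r}")
            cache[pid] = protein_vector(encode_sequence(by_id[pid]), method)
        return cache[pid]

    X = np.empty((len(pairs), PAIR_DIMS[method]), dtype=np.dtype(dtype))
    y = np.empty(len(pairs), dtype=np.int64)
    ids = []
    half = PAIR_DIMS[method] // 2
    for row, pair in enumerate(pairs):
        X[row, :half] = vec(pair.id_a)
        X[row, half:] = vec(pair.id_b)
        y[row] = pair.label
        ids.append((pair.id_a, pair.id_b))
    return X, y, ids


def write_feature_matrix(
    X: np.ndarray,
    y: np.ndarray,
    ids: list[tuple[str, str]],
    method: str,
    path: str | Path,
) -> None:
    """Write one row per pair (id_a, id_b, label, features...) as TSV, plus a
    JSON sidecar (<path>.json) recording the method and column order."""
    path = Path(path)
    cols = feature_names(method, scope="pair")
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "label", np.asarray(y, dtype=int))
    df.insert(0, "id_b", [b for _, b in ids])
    df.insert(0, "id_a", [a for a, _ in ids])
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    sidecar = {
        "method": method.lower(),
        "n_pairs": int(len(ids)),
        "n_features": int(X.shape[1]),
        "columns": ["id_a", "id_b", "label"] + cols,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_feature_matrix(
    path: str | Path,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]], str]:
    """Inverse of :func:`write_feature_matrix`; returns (X, y, ids, method)."""
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    df = pd.read_csv(path, sep="\t")
    ids = list(zip(df["id_a"].astype(str), df["id_b"].astype(str)))
    y = df["label"].to_numpy(dtype=np.int64)
    X = df.drop(columns=["id_a", "id_b", "label"]).to_numpy(dtype=np.float32)
    if X.shape[1] != sidecar["n_features"]:
        raise ValueError(
            f"{path}: sidecar declares {sidecar['n_features']} features, "
            f"file has {X.shape[1]}"
        )
    return X, y, ids, sidecar["method"]
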
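"""Shared plumbing: seed derivation, canonical binary-matrix ordering, TSV I/O."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "derive_seed",
    "left_order",
    "write_tsv",
    "read_tsv",
    "ConfigError",
]

#: floating-point formatting for all emitted tables (10 significant digits)
FLOAT_FORMAT = "%.10g"


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed.

    Every stochastic stage draws its seed from one global integer through
    ``sha256("<stage>|<global_seed>")``: the first four bytes of the digest,
    reduced modulo 2**31.  Distinct stage names therefore consume
    statistically independent streams while the whole run remains
    reproducible from a single integer.
    """
    digest = hashlib.sha256(f"{stage}|{int(global_seed)}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def left_order(Z: np.ndarray) -> np.ndarray:
    """Return ``Z`` with columns in left-ordered canonical form.

    Columns are sorted by their binary-number reading (row 0 is the most
    significant bit), in decreasing order; identical columns keep their
    relative order (stable sort), which realizes the first-active-row
    tie-break.
    """
    Z = np.asarray(Z)
    if Z.ndim != 2:
        raise ValueError("Z must be a 2-D binary matrix")
    if Z.shape[1] <= 1:
        return Z.copy()
    order = sorted(range(Z.shape[1]), key=lambda k: tuple(Z[:, k]), reverse=True)
    return Z[:, order]


def write_tsv(df: pd.DataFrame, path: str | Path, provenance: dict | None = None,
              index: bool = False) -> None:
    """Write a table as TSV with optional ``# key: value`` provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT, index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`, skipping provenance lines."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
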
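"""Numeric encoding of amino-acid sequences via the five Atchley factors.

The packaged 20x5 table (Atchley et al., PNAS 2005) maps each standard
one-letter residue code to five physicochemical factor scores.  The resource
file is integrity-checked against a pinned SHA-256 digest at load time.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["ATCHLEY_SHA256", "load_atchley_table", "encode_atchley"]

ATCHLEY_SHA256 = "2fc93ffd58fbf9d64229541bb4e54d8133d8a35896bf6343e688c16f66102597"

_RESOURCE = "atchley_factors.tsv"


@lru_cache(maxsize=1)
def load_atchley_table() -> pd.DataFrame:
    """Load the 20x5 factor table, verifying the pinned checksum."""
    ref = resources.files("sparsemil.resources").joinpath(_RESOURCE)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != ATCHLEY_SHA256:
        raise RuntimeError(
            f"Atchley resource checksum mismatch: {digest} != {ATCHLEY_SHA256}"
        )
    df = pd.read_csv(ref.open("r"), sep="\t", index_col="residue")
    assert df.shape == (20, 5)
    return df


def encode_atchley(sequence: str) -> np.ndarray:
    """Encode an amino-acid string as an (L, 5) matrix of factor scores.

    Raises ValueError naming the offending position for any character outside
    the 20 standard one-letter codes.
    """
    table = load_atchley_table()
    rows = []
    for pos, residue in enumerate(sequence):
        aa = residue.upper()
        if aa not in table.index:
            raise ValueError(f"invalid residue {residue!r} at position {pos}")
        rows.append(table.loc[aa].to_numpy())
    if not rows:
        raise ValueError("empty sequence")
    return np.asarray(rows, dtype=np.float64)
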
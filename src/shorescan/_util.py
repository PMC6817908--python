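"""Small shared helpers: child seeding, BH adjustment, TSV round-trips."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def child_rng(seed: int, *tags: str) -> np.random.Generator:
    """Derive an independent generator from a global seed and a string path.

    One global integer seed reproduces every stochastic component; each
    component hashes its own tag so adding a new component never perturbs
    the streams of existing ones.
    """
    h = hashlib.sha256(("/".join(map(str, tags)) + f"#{seed}").encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "big"))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs pass through untested."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def read_tsv_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["."])


def write_tsv_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep=".", float_format="%.10g")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
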
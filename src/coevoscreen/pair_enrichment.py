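"""Hypergeometric pair-enrichment statistics for paired count tables.

A pair (a, b) observed k times among N pooled reads, with marginal read
counts c_a and c_b, is tested against the null that a and b pair at random:
the upper-tail probability P(X >= k) with X ~ Hypergeometric(N, c_b, c_a).
Pairs with p below the threshold (0.05 by default, uncorrected, matching
the screen analysis convention) form the enriched set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from coevoscreen.screen_simulator import PairCountTable


@dataclass
class EnrichedPairSet:
    """Statistically filtered pairs with marginals and p-values."""

    rounds: list[str]
    alpha: float
    df: pd.DataFrame  # seq_a seq_b k c_a c_b n p_value
    all_pairs: pd.DataFrame | None = field(default=None, repr=False)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# rounds={','.join(self.rounds)}\n# alpha={self.alpha}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EnrichedPairSet":
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k.strip()] = v.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", dtype={"seq_a": str, "seq_b": str})
        return cls(meta.get("rounds", "").split(","), float(meta.get("alpha", 0.05)), df)


def pair_pvalue(
    k: int | np.ndarray,
    c_a: int | np.ndarray,
    c_b: int | np.ndarray,
    n: int | np.ndarray,
) -> float | np.ndarray:
    """Upper-tail hypergeometric p-value P(X >= k).

    X ~ Hypergeometric(population n, successes c_b, draws c_a); the test is
    symmetric in (c_a, c_b). Computed via the survival function in
    log-stable form; k = 0 gives exactly 1.
    """
    k_arr, ca, cb, n_arr = np.broadcast_arrays(
        np.asarray(k), np.asarray(c_a), np.asarray(c_b), np.asarray(n)
    )
    if np.any((k_arr < 0) | (ca > n_arr) | (cb > n_arr) | (k_arr > np.minimum(ca, cb))):
        raise ValueError("inconsistent counts: need 0 <= k <= min(c_a, c_b) <= n")
    p = stats.hypergeom.sf(k_arr - 1, n_arr, cb, ca)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(k) or p.ndim == 0 else p


def pool_counts(
    tables: Sequence[PairCountTable], rounds: Sequence[str]
) -> pd.DataFrame:
    """Sum pair counts over the named rounds."""
    by_label = {t.round_label: t for t in tables}
    missing = [r for r in rounds if r not in by_label]
    if missing:
        raise KeyError(f"unknown round label(s): {missing}; have {sorted(by_label)}")
    pooled = (
        pd.concat([by_label[r].df for r in rounds], ignore_index=True)
        .groupby(["seq_a", "seq_b"], as_index=False)["count"]
        .sum()
    )
    return pooled


def filter_pairs(
    tables: Sequence[PairCountTable],
    rounds: Sequence[str],
    alpha: float = 0.05,
    correction: Literal["none", "bh"] = "none",
) -> EnrichedPairSet:
    """Pool counts over ``rounds`` and retain pairs enriched at ``p < alpha``.

    Marginals are read counts per unique variable-region sequence on each
    chain. Benjamini-Hochberg correction is available but off by default
    (the screen convention filters at raw p < 0.05).
    """
    pooled = pool_counts(tables, rounds)
    n = int(pooled["count"].sum())
    ca = pooled.groupby("seq_a")["count"].sum()
    cb = pooled.groupby("seq_b")["count"].sum()
    pooled = pooled.rename(columns={"count": "k"})
    pooled["c_a"] = pooled["seq_a"].map(ca).astype(int)
    pooled["c_b"] = pooled["seq_b"].map(cb).astype(int)
    pooled["n"] = n
    pooled["p_value"] = pair_pvalue(
        pooled["k"].to_numpy(), pooled["c_a"].to_numpy(),
        pooled["c_b"].to_numpy(), n,
    )
    if correction == "bh":
        pooled["p_value"] = _benjamini_hochberg(pooled["p_value"].to_numpy())
    kept = pooled[pooled["p_value"] < alpha].reset_index(drop=True)
    return EnrichedPairSet(list(rounds), alpha, kept, all_pairs=pooled)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        adj[order[rank]] = running
    return adj


@dataclass
class PositionFrequencyMatrix:
    """Per-position amino-acid frequencies for one chain (columns sum to 1)."""

    chain: str
    df: pd.DataFrame  # rows = amino acids, columns = 1..L

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t")


def position_frequency_matrix(
    source: PairCountTable | EnrichedPairSet | pd.DataFrame,
    chain: Literal["A", "B"],
    weighting: Literal["count", "unique"] = "count",
) -> PositionFrequencyMatrix:
    """Amino-acid frequency per position of one chain's variable region.

    ``weighting="count"`` weights each sequence by its read count (column
    ``count`` or ``k``); ``"unique"`` weights every distinct sequence
    equally.
    """
    if isinstance(source, PairCountTable):
        df = source.df
    elif isinstance(source, EnrichedPairSet):
        df = source.df
    else:
        df = source
    col = "seq_a" if chain == "A" else "seq_b"
    seqs = df[col].astype(str)
    if seqs.empty:
        raise ValueError("empty input")
    lengths = seqs.str.len().unique()
    if len(lengths) != 1:
        raise ValueError(f"mixed sequence lengths {sorted(lengths)} on chain {chain}")
    length = int(lengths[0])
    if weighting == "count":
        wcol = "count" if "count" in df.columns else "k"
        weights = df[wcol].to_numpy(dtype=float)
    else:
        # aggregate to distinct sequences first
        seqs = pd.Series(sorted(seqs.unique()))
        weights = np.ones(len(seqs))
    chars = np.array([list(s) for s in seqs])
    alphabet = sorted(set(chars.ravel()))
    mat = np.zeros((len(alphabet), length))
    aa_index = {aa: i for i, aa in enumerate(alphabet)}
    for j in range(length):
        for aa, w in zip(chars[:, j], weights):
            mat[aa_index[aa], j] += w
    mat /= mat.sum(axis=0, keepdims=True)
    out = pd.DataFrame(mat, index=alphabet, columns=[str(j + 1) for j in range(length)])
    return PositionFrequencyMatrix(chain, out)
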
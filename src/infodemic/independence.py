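"""Cross-account duplication matrix, overlap strength, and valued density.

Accounts that republish each other's articles verbatim are less editorially
independent.  The duplication matrix counts, for each account pair, how many
title pairs match after canonical normalization; per-account row sums give an
*overlap strength* (the field sometimes calls this "independence strength" —
high overlap means low independence, so independence is the inverse ranking
of this quantity).  Density follows the valued-network convention: the mean
tie value over all ordered node pairs.
"""

from __future__ import annotations

import dataclasses
import re
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus

_PUNCT = re.compile(r"[^\w\s]+", flags=re.UNICODE)
_WS = re.compile(r"\s+")


class NetworkError(ValueError):
    """Raised for malformed pair matrices or matcher parameters."""


@dataclasses.dataclass(frozen=True)
class PairMatrix:
    """A symmetric labeled nonnegative matrix with a zero diagonal.

    Used both for account-pair duplication counts (integer values) and for
    term-term co-occurrence / similarity (integer or real values).
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.labels)
        if values.shape != (n, n):
            raise NetworkError(f"matrix shape {values.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise NetworkError("labels must be unique")
        if not np.allclose(values, values.T):
            raise NetworkError("matrix must be symmetric")
        if np.any(np.diagonal(values) != 0):
            raise NetworkError("diagonal must be zero")
        if np.any(values < 0):
            raise NetworkError("entries must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def normalize_title(title: str) -> str:
    """Canonical form for duplicate matching: casefolded, punctuation stripped,
    whitespace collapsed.  Deterministic and idempotent."""
    text = _PUNCT.sub(" ", str(title).casefold())
    return _WS.sub(" ", text).strip()


def _token_set(title: str) -> frozenset[str]:
    return frozenset(normalize_title(title).split())


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def duplication_matrix(
    corpus: Corpus,
    matcher: str = "exact",
    sim_threshold: float = 0.8,
) -> PairMatrix:
    """Count matched title pairs between every pair of accounts.

    ``exact`` matches canonical titles; entry (i, j) sums, per distinct
    title, the smaller of the two accounts' copy counts (each post matched at
    most once per counterpart account).  ``similarity`` matches token sets
    with Jaccard >= ``sim_threshold`` via greedy one-to-one assignment in
    descending similarity order (quadratic per pair; fine at account scale,
    use ``exact`` for large corpora).
    """
    accounts = corpus.accounts
    if len(accounts) < 2:
        raise NetworkError("need at least 2 accounts")
    if matcher not in ("exact", "similarity"):
        raise NetworkError(f"unknown matcher {matcher!r}")
    if matcher == "similarity" and not (0.0 < sim_threshold <= 1.0):
        raise NetworkError(f"sim_threshold must be in (0, 1], got {sim_threshold}")

    n = len(accounts)
    values = np.zeros((n, n))
    index = {a: i for i, a in enumerate(accounts)}

    if matcher == "exact":
        counters: dict[str, Counter] = {a: Counter() for a in accounts}
        for r in corpus.records:
            counters[r.account_id][normalize_title(r.title)] += 1
        for i in range(n):
            ci = counters[accounts[i]]
            for j in range(i + 1, n):
                cj = counters[accounts[j]]
                small, large = (ci, cj) if len(ci) <= len(cj) else (cj, ci)
                matched = sum(min(k, large[t]) for t, k in small.items() if t in large)
                values[i, j] = values[j, i] = matched
    else:
        tokens: dict[str, list[frozenset[str]]] = {a: [] for a in accounts}
        for r in corpus.records:
            tokens[r.account_id].append(_token_set(r.title))
        for i in range(n):
            for j in range(i + 1, n):
                ti, tj = tokens[accounts[i]], tokens[accounts[j]]
                candidates = [
                    (_jaccard(a, b), ia, ib)
                    for ia, a in enumerate(ti)
                    for ib, b in enumerate(tj)
                    if _jaccard(a, b) >= sim_threshold
                ]
                candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
                used_i: set[int] = set()
                used_j: set[int] = set()
                matched = 0
                for _, ia, ib in candidates:
                    if ia not in used_i and ib not in used_j:
                        used_i.add(ia)
                        used_j.add(ib)
                        matched += 1
                values[i, j] = values[j, i] = matched

    return PairMatrix(labels=accounts, values=values)


def strength_sums(matrix: PairMatrix) -> pd.Series:
    """Per-node total tie strength (row sums), reported in descending order."""
    sums = pd.Series(matrix.values.sum(axis=1), index=list(matrix.labels), name="strength")
    return sums.sort_values(ascending=False, kind="stable")


def valued_density(matrix: PairMatrix, mode: str = "mean") -> float:
    """Network density of a pair matrix.

    ``mean``  — average tie value over the n(n-1) ordered off-diagonal cells
                (valued-network convention; the default).
    ``binary``— proportion of off-diagonal cells with a nonzero tie.
    ``sum``   — total tie value over unordered pairs (upper triangle).
    """
    if matrix.n < 2:
        raise NetworkError("density needs at least 2 nodes")
    off = ~np.eye(matrix.n, dtype=bool)
    if mode == "mean":
        return float(matrix.values[off].mean())
    if mode == "binary":
        return float((matrix.values[off] > 0).mean())
    if mode == "sum":
        return float(np.triu(matrix.values, k=1).sum())
    raise NetworkError(f"unknown density mode {mode!r}")


def to_edge_list(matrix: PairMatrix, include_zero: bool = False) -> pd.DataFrame:
    """Upper-triangle edge list (source, target, weight) for external tools."""
    rows = []
    for i in range(matrix.n):
        for j in range(i + 1, matrix.n):
            w = matrix.values[i, j]
            if include_zero or w > 0:
                rows.append((matrix.labels[i], matrix.labels[j], w))
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


def to_ucinet_dl(matrix: PairMatrix) -> str:
    """Render the matrix in UCINET DL full-matrix format."""
    lines = [f"dl n={matrix.n} format=fullmatrix", "labels:"]
    lines.append(",".join(f'"{lab}"' for lab in matrix.labels))
    lines.append("data:")
    for row in matrix.values:
        lines.append(" ".join(_fmt_number(v) for v in row))
    return "\n".join(lines) + "\n"


def _fmt_number(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:.6f}"
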
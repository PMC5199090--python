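"""Independent brute-force oracles used to check the library.

Everything here is written directly from the definitions, with plain Python
loops over characters and pairs, and shares no code path with the package.
"""

from __future__ import annotations

import itertools
import random


def analyzed_cols(rows: list[str], policy: str) -> list[int]:
    """0-based analysed columns under a gap policy."""
    n_cols = len(rows[0])
    if policy == "complete_deletion":
        return [
            c for c in range(n_cols) if all(r[c] not in "-N" for r in rows)
        ]
    return list(range(n_cols))


def _missing(policy: str) -> set[str]:
    return {"N"} if policy == "include_gaps" else {"-", "N"}


def s_eta(rows: list[str], policy: str) -> tuple[int, int]:
    miss = _missing(policy)
    S = eta = 0
    for c in analyzed_cols(rows, policy):
        states = {r[c] for r in rows} - miss
        if len(states) >= 2:
            S += 1
            eta += len(states) - 1
    return S, eta


def pair_diff(a: str, b: str, policy: str, cols: list[int]) -> int:
    miss = _missing(policy)
    return sum(
        1 for c in cols if a[c] not in miss and b[c] not in miss and a[c] != b[c]
    )


def mean_k(rows: list[str], policy: str) -> float:
    cols = analyzed_cols(rows, policy)
    pairs = list(itertools.combinations(rows, 2))
    return sum(pair_diff(a, b, policy, cols) for a, b in pairs) / len(pairs)


def hap_count(rows: list[str], policy: str) -> int:
    """Distinct strings over the shared identity columns.

    Identity columns: gap/N-free columns (complete or pairwise deletion);
    N-free columns with gaps compared as a fifth state (include_gaps).
    """
    n_cols = len(rows[0])
    if policy == "include_gaps":
        cols = [c for c in range(n_cols) if all(r[c] != "N" for r in rows)]
    else:
        cols = analyzed_cols(rows, "complete_deletion")
    return len({"".join(r[c] for c in cols) for r in rows})


def random_toy(rng: random.Random, max_records: int = 8, max_cols: int = 60):
    """A random small alignment over ACGT-N as a list of row strings."""
    n = rng.randint(2, max_records)
    L = rng.randint(5, max_cols)
    alphabet = "ACGT" * 6 + "-N"  # gaps/N sparse
    base = [rng.choice("ACGT") for _ in range(L)]
    rows = []
    for _ in range(n):
        row = [
            rng.choice(alphabet) if rng.random() < 0.3 else base[c]
            for c in range(L)
        ]
        rows.append("".join(row))
    return rows


def window_stats(rows: list[str], start0: int, length: int, policy: str):
    """(S, mean pairwise diffs, n analysed) within one window, by loops."""
    cols = [c for c in analyzed_cols(rows, policy) if start0 <= c < start0 + length]
    miss = _missing(policy)
    S = 0
    for c in cols:
        if len({r[c] for r in rows} - miss) >= 2:
            S += 1
    pairs = list(itertools.combinations(rows, 2))
    mean_d = sum(pair_diff(a, b, policy, cols) for a, b in pairs) / len(pairs)
    return S, mean_d, len(cols)
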
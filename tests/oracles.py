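"""Independent reference implementations used as test oracles.

The Viterbi oracle enumerates every state path explicitly and recomputes
emission probabilities from the documented formulas, independently of the
dynamic-programming implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def emission_log10(symbol: str, state: str, depth: int, params) -> float:
    """Documented emission model, written out independently."""
    if symbol == "M":
        return 0.0
    if params.allele_dropout:
        q = min(1.0, 0.5 ** depth + params.E_hom)
    else:
        q = params.E_hom
    if params.c_mode == "constant":
        c = params.C
    else:
        c = params.C * (1.0 - math.exp(-depth))
    p_s_n = min(1.0, params.E_het + c)
    if state == "H":
        p = 1.0 - q if symbol == "S" else q
    else:
        p = p_s_n if symbol == "S" else 1.0 - p_s_n
    return math.log10(p) if p > 0 else -math.inf


def brute_force_paths(symbols: str, depths, params):
    """Joint log10 probability of every one of the 2^L state paths.

    Returns (paths, logprobs) with paths as an (2^L, L) array over
    {0: H, 1: N}, sorted by decreasing log probability (ties: fewer
    transitions first, then lexicographically with H before N).
    """
    L = len(symbols)
    n_paths = 2 ** L
    paths = ((np.arange(n_paths)[:, None] >> np.arange(L)[::-1]) & 1) \
        .astype(np.int8)
    e = np.array([[emission_log10(symbols[t], s, depths[t], params)
                   for s in ("H", "N")] for t in range(L)])
    lp = np.log10(0.5) + e[np.arange(L), paths].sum(axis=1)
    if L > 1:
        switches = (paths[:, 1:] != paths[:, :-1]).sum(axis=1)
        lp = lp + switches * np.log10(params.T) \
            + (L - 1 - switches) * np.log10(1.0 - params.T)
    else:
        switches = np.zeros(n_paths, dtype=int)
    order = np.lexsort((np.arange(n_paths), switches, -lp))
    return paths[order], lp[order]


def brute_force_viterbi(symbols: str, depths, params):
    """Best and second-best joint log10 probabilities plus the best path."""
    paths, lp = brute_force_paths(symbols, depths, params)
    best_path = "".join("H" if s == 0 else "N" for s in paths[0])
    second = lp[1] if len(lp) > 1 else -math.inf
    return best_path, float(lp[0]), float(second)
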
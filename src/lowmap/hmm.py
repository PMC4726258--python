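"""Hidden-Markov imputation of the inherited parental homolog.

For each (individual, haplotype block, segregating phase) the observation
string over {S, N, M} is decoded with a two-state Viterbi pass. The hidden
states are H — the individual carries the homolog with the segregating
alleles — and N — it carries the other homolog. The decoder also recovers
the globally second-best state path; the call is accepted only when

* the string has at least ``min_obs_len`` non-missing observations,
* LOD = log10 P(Z*, X) - log10 P(Z2, X) >= ``min_lod``, and
* any residual state switches are resolved by the trimming rules
  (relative segment length and relative SNP density, both thresholded),

otherwise no genotype is generated for that individual/block.

Emission model (four tunable parameters plus the observed depth d):

==========  ==========================  ==========================
observation  state H (carrier)           state N (non-carrier)
==========  ==========================  ==========================
S            1 - q_d                     min(1, E_het + c_d)
N            q_d                         1 - min(1, E_het + c_d)
M            1                           1
==========  ==========================  ==========================

A carrier is heterozygous at a TC site (one homolog carries the
segregating allele, the other the constant allele from the homozygous
parent), so a depth-d pile-up samples only the constant allele with
probability 0.5^d — allele dropout, the dominant noise at 0.5-1x.
Hence ``q_d = min(1, 0.5^d + E_hom)`` (dropout plus a genuine miscall;
``allele_dropout=False`` reduces it to the depth-free ``E_hom``).
On the non-carrier side ``c_d`` models spurious heterozygous evidence
from multi-mapping reads: a constant ``C`` (default mode) or
``C * (1 - exp(-depth))`` when ``c_mode='poisson_depth'`` (the chance
that at least one read of a Poisson-depth pile-up is mis-mapped).
Transitions between H and N occur with per-step probability ``T``; the
initial distribution is uniform, matching the 1:1 expected segregation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .testcross import CHAR_TO_SYM, ObservationMatrix, ObservationString, \
    SYM_M, SYM_N, SYM_S

STATE_H, STATE_N = 0, 1
STATE_CHARS = {STATE_H: "H", STATE_N: "N"}


@dataclass(frozen=True)
class HMMParams:
    """Decoding parameters; defaults are the pipeline's operating point."""

    T: float = 1e-8            # per-step homolog switch probability
    E_het: float = 0.01        # false heterozygous miscall probability
    E_hom: float = 0.01        # false homozygous miscall probability
    C: float = 0.2             # multi-mapping false-het factor
    c_mode: str = "constant"   # 'constant' | 'poisson_depth'
    allele_dropout: bool = True  # depth-aware P(N|H); False -> E_hom only
    min_obs_len: int = 6       # minimum non-missing observations
    min_lod: float = 2.0
    max_len_ratio: float = 0.2
    max_density_ratio: float = 0.2

    def __post_init__(self) -> None:
        for name in ("T", "E_het", "E_hom", "C"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.min_obs_len < 1:
            raise ValueError("min_obs_len must be >= 1")
        for name in ("max_len_ratio", "max_density_ratio"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.c_mode not in ("constant", "poisson_depth"):
            raise ValueError(f"unknown c_mode {self.c_mode!r}")


@dataclass(frozen=True)
class PathResult:
    best_path: str          # over {H, N}, one state per observation
    best_logprob: float     # log10 P(Z*, X)
    second_logprob: float   # log10 P(Z2, X)
    n_transitions: int

    @property
    def lod(self) -> float:
        return self.best_logprob - self.second_logprob


@dataclass(frozen=True)
class BlockCall:
    individual_id: str
    parent_id: str
    block_id: str
    phase_type: int
    genotype: str | None    # 'H' | 'N' | None (no call)
    lod: float | None = None


def emission_logprob(symbol: str, state: str, depth: int,
                     params: HMMParams) -> float:
    """log10 emission probability of one observation symbol in one state."""
    if depth < 0:
        raise ValueError("negative depth")
    if symbol == "M":
        return 0.0
    if params.c_mode == "constant":
        c_d = params.C
    else:
        c_d = params.C * (1.0 - np.exp(-float(depth)))
    p_s_given_n = min(1.0, params.E_het + c_d)
    if params.allele_dropout:
        q_d = min(1.0, 0.5 ** depth + params.E_hom)
    else:
        q_d = params.E_hom
    with np.errstate(divide="ignore"):
        if state == "H":
            p = 1.0 - q_d if symbol == "S" else q_d
        elif state == "N":
            p = p_s_given_n if symbol == "S" else 1.0 - p_s_given_n
        else:
            raise ValueError(f"unknown state {state!r}")
        return float(np.log10(p))


def _emission_matrix(sym: np.ndarray, dep: np.ndarray,
                     params: HMMParams) -> np.ndarray:
    """(n, L) symbol/depth arrays -> (n, L, 2) log10 emissions."""
    if params.c_mode == "constant":
        c_d = np.full(sym.shape, params.C)
    else:
        c_d = params.C * (1.0 - np.exp(-dep.astype(np.float64)))
    p_s_n = np.minimum(1.0, params.E_het + c_d)
    if params.allele_dropout:
        q_d = np.minimum(1.0, 0.5 ** dep.astype(np.float64) + params.E_hom)
    else:
        q_d = np.full(sym.shape, params.E_hom)
    with np.errstate(divide="ignore"):
        l_s_h = np.log10(1.0 - q_d)
        l_n_h = np.log10(q_d)
        l_s_n = np.log10(p_s_n)
        l_n_n = np.log10(1.0 - p_s_n)
    e = np.zeros(sym.shape + (2,), dtype=np.float64)
    is_s = sym == SYM_S
    is_n = sym == SYM_N
    e[..., STATE_H] = np.where(is_s, l_s_h, np.where(is_n, l_n_h, 0.0))
    e[..., STATE_N] = np.where(is_s, l_s_n, np.where(is_n, l_n_n, 0.0))
    return e


def viterbi_decode_matrix(sym: np.ndarray, dep: np.ndarray,
                          params: HMMParams
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                     np.ndarray]:
    """Two-best Viterbi, vectorised across individuals.

    ``sym``/``dep`` are (n, L). Returns ``(paths, best_lp, second_lp,
    n_transitions)`` where ``paths`` is (n, L) over {STATE_H, STATE_N}.
    Keeping the two best partial paths per state at every step yields the
    exact global top-2; exact score ties are broken toward fewer state
    switches, then toward the H state.
    """
    n, L = sym.shape
    if L < 1:
        raise ValueError("empty observation")
    e = _emission_matrix(sym, dep, params)
    with np.errstate(divide="ignore"):
        lt_switch = float(np.log10(params.T))
        lt_stay = float(np.log10(1.0 - params.T))
    NEG = -np.inf
    score = np.full((n, 2, 2), NEG)
    ntr = np.zeros((n, 2, 2), dtype=np.int32)
    for s in (STATE_H, STATE_N):
        score[:, s, 0] = np.log10(0.5) + e[:, 0, s]
    bp_state = np.zeros((n, L, 2, 2), dtype=np.int8)
    bp_rank = np.zeros((n, L, 2, 2), dtype=np.int8)
    ar = np.arange(n)
    # candidate enumeration order fixes residual ties: predecessor H first
    cand = [(p, r) for p in (STATE_H, STATE_N) for r in (0, 1)]
    p_of = np.array([p for p, _ in cand], dtype=np.int8)
    r_of = np.array([r for _, r in cand], dtype=np.int8)
    for t in range(1, L):
        new_score = np.empty_like(score)
        new_ntr = np.empty_like(ntr)
        for s in (STATE_H, STATE_N):
            cs = np.empty((n, 4))
            ct = np.empty((n, 4), dtype=np.int64)
            for k, (p, r) in enumerate(cand):
                trans = lt_stay if p == s else lt_switch
                cs[:, k] = score[:, p, r] + trans + e[:, t, s]
                ct[:, k] = ntr[:, p, r] + (0 if p == s else 1)
            order = np.lexsort((ct, -cs), axis=1)  # score desc, ntrans asc
            for rank in (0, 1):
                sel = order[:, rank]
                new_score[:, s, rank] = cs[ar, sel]
                new_ntr[:, s, rank] = ct[ar, sel]
                bp_state[:, t, s, rank] = p_of[sel]
                bp_rank[:, t, s, rank] = r_of[sel]
        score, ntr = new_score, new_ntr
    # final selection over (state, rank), H first on residual ties
    fs = np.empty((n, 4))
    ft = np.empty((n, 4), dtype=np.int64)
    for k, (s, r) in enumerate(cand):
        fs[:, k] = score[:, s, r]
        ft[:, k] = ntr[:, s, r]
    order = np.lexsort((ft, -fs), axis=1)
    best_sel = order[:, 0]
    second_sel = order[:, 1]
    best_lp = fs[ar, best_sel]
    second_lp = fs[ar, second_sel]
    n_transitions = ft[ar, best_sel].astype(np.int64)
    paths = np.empty((n, L), dtype=np.int8)
    cur_s = p_of[best_sel].copy()  # here p_of doubles as state lookup
    cur_r = r_of[best_sel].copy()
    for t in range(L - 1, -1, -1):
        paths[:, t] = cur_s
        if t > 0:
            ps = bp_state[ar, t, cur_s, cur_r]
            pr = bp_rank[ar, t, cur_s, cur_r]
            cur_s, cur_r = ps, pr
    return paths, best_lp, second_lp, n_transitions


def viterbi_decode(obs: ObservationString, params: HMMParams) -> PathResult:
    """Decode a single observation string; see :func:`viterbi_decode_matrix`."""
    sym = np.array([CHAR_TO_SYM[c] for c in obs.symbols], dtype=np.int8)
    dep = np.asarray(obs.depths, dtype=np.int32)
    paths, best, second, ntr = viterbi_decode_matrix(
        sym[None, :], dep[None, :], params)
    path = "".join(STATE_CHARS[int(s)] for s in paths[0])
    return PathResult(path, float(best[0]), float(second[0]), int(ntr[0]))


# ---------------------------------------------------------------------------
# Transition trimming
# ---------------------------------------------------------------------------

def _segments(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Runs of constant state as (start, end_exclusive, state)."""
    out = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            out.append((start, i, int(states[start])))
            start = i
    return out


def _trim_states(states: np.ndarray, sym: np.ndarray, positions: np.ndarray,
                 params: HMMParams) -> np.ndarray | None:
    """Apply the segment-trimming rules; None when a transition survives.

    Segment length is counted in non-missing observations; SNP density is
    non-missing observations per bp of segment span. At each transition
    the shorter (fewer non-missing sites; sparser on a length tie) of the
    two adjacent segments is absorbed into the other's state when either
    the length ratio or the density ratio falls at or below its threshold.
    Iterates to a fixed point.
    """
    states = states.copy()
    while True:
        segs = _segments(states)
        if len(segs) == 1:
            return states
        merged = False
        for (a0, a1, sa), (b0, b1, sb) in zip(segs, segs[1:]):
            na = int((sym[a0:a1] != SYM_M).sum())
            nb = int((sym[b0:b1] != SYM_M).sum())
            da = na / max(int(positions[a1 - 1] - positions[a0]) + 1, 1)
            db = nb / max(int(positions[b1 - 1] - positions[b0]) + 1, 1)
            hi, lo = max(na, nb), min(na, nb)
            len_ratio = lo / hi if hi > 0 else 1.0
            dhi, dlo = max(da, db), min(da, db)
            density_ratio = min(dlo / dhi, 1.0) if dhi > 0 else 1.0
            if len_ratio <= params.max_len_ratio \
                    or density_ratio <= params.max_density_ratio:
                if na < nb or (na == nb and da <= db):
                    states[a0:a1] = sb
                else:
                    states[b0:b1] = sa
                merged = True
                break
        if not merged:
            return None


def trim_transitions(path_result: PathResult, obs: ObservationString,
                     params: HMMParams) -> PathResult | None:
    """Trim spurious state switches from a decoded path.

    Returns the (possibly all-one-state) path result, or None when a
    transition survives trimming — a haplotype block must yield a single
    genotype, so such blocks are not called.
    """
    if path_result.n_transitions == 0:
        return path_result
    states = np.array([0 if c == "H" else 1 for c in path_result.best_path],
                      dtype=np.int8)
    sym = np.array([CHAR_TO_SYM[c] for c in obs.symbols], dtype=np.int8)
    pos = np.asarray(obs.positions, dtype=np.int64)
    trimmed = _trim_states(states, sym, pos, params)
    if trimmed is None:
        return None
    path = "".join(STATE_CHARS[int(s)] for s in trimmed)
    return replace(path_result, best_path=path,
                   n_transitions=int((trimmed[1:] != trimmed[:-1]).sum()))


# ---------------------------------------------------------------------------
# Block-level imputation
# ---------------------------------------------------------------------------

def impute_block(obs: ObservationString, params: HMMParams = HMMParams()
                 ) -> BlockCall:
    """Impute one individual's inherited homolog on one block/phase."""
    n_obs = sum(1 for c in obs.symbols if c != "M")
    no_call = BlockCall(obs.individual_id, obs.parent_id, obs.block_id,
                        obs.phase_type, None)
    if n_obs < params.min_obs_len:
        return no_call
    pr = viterbi_decode(obs, params)
    if pr.lod < params.min_lod:
        return no_call
    trimmed = trim_transitions(pr, obs, params)
    if trimmed is None or trimmed.n_transitions != 0:
        return no_call
    return BlockCall(obs.individual_id, obs.parent_id, obs.block_id,
                     obs.phase_type, trimmed.best_path[0], pr.lod)


def impute_matrix(om: ObservationMatrix, params: HMMParams = HMMParams()
                  ) -> tuple[list[BlockCall], Counter]:
    """Impute all individuals of one (block, phase) at once.

    Vectorised equivalent of mapping :func:`impute_block` over
    ``om.strings()``; returns the calls plus per-reason no-call counts.
    """
    counts: Counter[str] = Counter()
    n, L = om.symbols.shape
    n_obs = (om.symbols != SYM_M).sum(axis=1)
    eligible = n_obs >= params.min_obs_len
    genotype: list[str | None] = [None] * n
    lods: list[float | None] = [None] * n
    if eligible.any():
        paths, best, second, ntr = viterbi_decode_matrix(
            om.symbols, om.depths, params)
        lod = best - second
        for i in np.nonzero(eligible)[0]:
            if lod[i] < params.min_lod:
                counts["rejected_lod"] += 1
                continue
            if ntr[i] == 0:
                genotype[i] = STATE_CHARS[int(paths[i, 0])]
                lods[i] = float(lod[i])
                counts["accepted"] += 1
                continue
            trimmed = _trim_states(paths[i], om.symbols[i], om.positions,
                                   params)
            if trimmed is None:
                counts["rejected_trimming"] += 1
                continue
            genotype[i] = STATE_CHARS[int(trimmed[0])]
            lods[i] = float(lod[i])
            counts["accepted"] += 1
    counts["rejected_short"] += int((~eligible).sum())
    calls = [BlockCall(ind, om.parent_id, om.block_id, om.phase_type,
                       genotype[i], lods[i])
             for i, ind in enumerate(om.individuals)]
    return calls, counts
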
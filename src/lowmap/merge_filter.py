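"""Merging the two segregating phases and block-level segregation filters.

The two phase types of a block carry complementary information about the
same inheritance: an individual that received homolog 0 shows the
segregating alleles of phase-0 sites (state H on the phase-0 string) and
only constant alleles at phase-1 sites (state N on the phase-1 string).
``to_homolog`` applies that inversion so the two types can be merged into
one inherited-homolog call (h0/h1) per individual and block. Merged blocks
then pass segregation filters: a minimum genotyping ratio and a chi-square
test of the 1:1 expectation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hmm import BlockCall


@dataclass(frozen=True)
class MergeParams:
    max_missing_per_type: float = 0.30
    min_consensus: float = 0.50

    def __post_init__(self) -> None:
        for name in ("max_missing_per_type", "min_consensus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class FilterParams:
    min_call_rate: float = 0.70
    chi2_alpha: float = 0.03  # blocks with p < alpha are removed

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "chi2_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass(frozen=True)
class MergedCall:
    individual_id: str
    parent_id: str
    block_id: str
    homolog: str | None    # 'h0' | 'h1' | None
    lod: float | None = None


def to_homolog(call: BlockCall) -> str | None:
    """Convert a phase-typed H/N call to the inherited homolog.

    Phase type 0: H -> h0, N -> h1; phase type 1 is the inversion.
    """
    if call.genotype is None:
        return None
    if call.genotype not in ("H", "N"):
        raise ValueError(f"unexpected genotype {call.genotype!r}")
    carries_seg = call.genotype == "H"
    if call.phase_type == 0:
        return "h0" if carries_seg else "h1"
    return "h1" if carries_seg else "h0"


def merge_block(calls_type0: Sequence[BlockCall] | None,
                calls_type1: Sequence[BlockCall] | None,
                params: MergeParams = MergeParams()
                ) -> tuple[list[MergedCall], Counter]:
    """Merge the two phase types of one block across all individuals.

    A type is eligible only if its missing ratio is at most
    ``max_missing_per_type``. With both types eligible, consensus merging
    starts only when agreement over the individuals called in both types
    reaches ``min_consensus`` (an empty overlap counts as vacuous
    agreement); conflicting individuals take the call with the higher LOD,
    one-sided individuals take their single call. Below consensus, the
    type with the higher mean LOD passes through alone. With one eligible
    type it passes through; with none the block is all-missing.
    """
    counts: Counter[str] = Counter()
    ref = calls_type0 or calls_type1
    if ref is None:
        raise ValueError("both phase types absent")
    roster = [c.individual_id for c in ref]
    parent, block = ref[0].parent_id, ref[0].block_id

    def eligible(calls: Sequence[BlockCall] | None) -> bool:
        if calls is None or len(calls) == 0:
            return False
        if [c.individual_id for c in calls] != roster:
            raise ValueError(f"block {block}: phase types disagree on roster")
        missing = sum(1 for c in calls if c.genotype is None)
        return missing / len(calls) <= params.max_missing_per_type

    use0, use1 = eligible(calls_type0), eligible(calls_type1)
    if not use0 and not use1:
        counts["blocks_no_eligible_type"] += 1
        return [MergedCall(i, parent, block, None) for i in roster], counts

    def homologs(calls: Sequence[BlockCall]) -> list[tuple[str | None,
                                                           float | None]]:
        return [(to_homolog(c), c.lod) for c in calls]

    if use0 != use1:
        counts["blocks_single_type"] += 1
        hs = homologs(calls_type0 if use0 else calls_type1)
        return [MergedCall(i, parent, block, h, l)
                for i, (h, l) in zip(roster, hs)], counts

    h0s, h1s = homologs(calls_type0), homologs(calls_type1)
    both = [(a, b) for (a, _), (b, _) in zip(h0s, h1s)
            if a is not None and b is not None]
    agree = sum(1 for a, b in both if a == b)
    consensus = agree / len(both) if both else 1.0
    if consensus < params.min_consensus:
        counts["blocks_consensus_failed"] += 1
        mean0 = np.mean([l for h, l in h0s if h is not None] or [0.0])
        mean1 = np.mean([l for h, l in h1s if h is not None] or [0.0])
        hs = h0s if mean0 >= mean1 else h1s
        return [MergedCall(i, parent, block, h, l)
                for i, (h, l) in zip(roster, hs)], counts

    counts["blocks_merged"] += 1
    merged: list[MergedCall] = []
    for ind, (a, la), (b, lb) in zip(roster, h0s, h1s):
        if a is None and b is None:
            merged.append(MergedCall(ind, parent, block, None))
        elif a is None:
            merged.append(MergedCall(ind, parent, block, b, lb))
        elif b is None:
            merged.append(MergedCall(ind, parent, block, a, la))
        elif a == b:
            merged.append(MergedCall(ind, parent, block, a, max(la, lb)))
        else:
            counts["conflicts_resolved_by_lod"] += 1
            h, l = (a, la) if la >= lb else (b, lb)
            merged.append(MergedCall(ind, parent, block, h, l))
    return merged, counts


def chi_square_segregation(merged: Sequence[MergedCall] | Sequence[str | None]
                           ) -> tuple[float, float]:
    """Pearson 1-df goodness of fit of h0:h1 counts against 1:1.

    Raises ValueError on an all-missing block (caller drops it with a
    reason). No continuity correction.
    """
    hs = [m.homolog if isinstance(m, MergedCall) else m for m in merged]
    n0 = sum(1 for h in hs if h == "h0")
    n1 = sum(1 for h in hs if h == "h1")
    n = n0 + n1
    if n == 0:
        raise ValueError("all calls missing; segregation undefined")
    exp = n / 2.0
    chi2 = (n0 - exp) ** 2 / exp + (n1 - exp) ** 2 / exp
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def apply_filters(merged_blocks: Mapping[str, Sequence[MergedCall]],
                  params: FilterParams = FilterParams()
                  ) -> tuple[list[str], pd.DataFrame]:
    """Apply call-rate and segregation-distortion filters per block.

    ``merged_blocks`` maps block_id to its merged call vector. Returns the
    retained block ids and a per-block report with columns block_id,
    call_rate, chi2, p, decision, reason. Both filters are evaluated
    independently on the merged calls.
    """
    retained: list[str] = []
    rows = []
    for block_id, calls in merged_blocks.items():
        n = len(calls)
        called = sum(1 for c in calls if c.homolog is not None)
        rate = called / n if n else 0.0
        try:
            chi2, p = chi_square_segregation(calls)
        except ValueError:
            rows.append((block_id, rate, np.nan, np.nan, "removed",
                         "all_missing"))
            continue
        reasons = []
        if rate < params.min_call_rate:
            reasons.append("call_rate")
        if p < params.chi2_alpha:
            reasons.append("distortion")
        if reasons:
            rows.append((block_id, rate, chi2, p, "removed",
                         "+".join(reasons)))
        else:
            retained.append(block_id)
            rows.append((block_id, rate, chi2, p, "retained", ""))
    report = pd.DataFrame(rows, columns=["block_id", "call_rate", "chi2",
                                         "p", "decision", "reason"])
    return retained, report


def merged_calls_frame(merged_blocks: Mapping[str, Sequence[MergedCall]],
                       individuals: Sequence[str]) -> pd.DataFrame:
    """Block-by-individual table of homolog calls ('h0'/'h1'/'missing')."""
    data = {}
    for block_id, calls in merged_blocks.items():
        if [c.individual_id for c in calls] != list(individuals):
            raise ValueError(f"block {block_id}: roster mismatch")
        data[block_id] = [c.homolog or "missing" for c in calls]
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(individuals))
    df.index.name = "marker_id"
    return df
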
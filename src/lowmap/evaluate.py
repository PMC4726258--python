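"""Truth-based evaluation of pipeline output on simulated crosses."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import PipelineResult
from .simulate import SimulatedCross

_HOMOLOG_CODE = {"h0": 0, "h1": 1}


def merged_call_accuracy(result: PipelineResult, cross: SimulatedCross
                         ) -> dict:
    """Accuracy of accepted merged homolog calls against simulated truth.

    Truth per (individual, block) is the majority inherited homolog over
    the block's sites. Phase labels are directly comparable: phase 0 of a
    simulated block is the allele set of homolog 0.
    """
    n_match = n_accepted = n_total = 0
    for parent, blocks in result.merged.items():
        truth = cross.truth.block_homolog[parent]
        for block_id, calls in blocks.items():
            if block_id not in truth.index:
                continue
            t = truth.loc[block_id]
            for c in calls:
                n_total += 1
                if c.homolog is None:
                    continue
                n_accepted += 1
                if _HOMOLOG_CODE[c.homolog] == int(t[c.individual_id]):
                    n_match += 1
    return {
        "n_calls": n_total,
        "n_accepted": n_accepted,
        "call_rate": n_accepted / n_total if n_total else float("nan"),
        "accuracy": n_match / n_accepted if n_accepted else float("nan"),
    }


def string_acceptance_rate(result: PipelineResult,
                           min_informative: int = 10) -> dict:
    """Accepted-call rate among strings with enough informative sites.

    Counts (individual, block, phase) observation strings carrying at
    least ``min_informative`` non-missing observations and the fraction of
    them for which the HMM produced an accepted genotype.
    """
    from .testcross import SYM_M

    n_eligible = n_accepted = 0
    for om in result.strings.matrices:
        calls = result.block_calls[(om.parent_id, om.block_id,
                                    om.phase_type)]
        informative = (om.symbols != SYM_M).sum(axis=1)
        for i, call in enumerate(calls):
            if informative[i] < min_informative:
                continue
            n_eligible += 1
            if call.genotype is not None:
                n_accepted += 1
    return {"n_eligible": n_eligible, "n_accepted": n_accepted,
            "rate": n_accepted / n_eligible if n_eligible else float("nan")}


def evaluate_anchoring(result: PipelineResult, cross: SimulatedCross,
                       min_markers: int = 3) -> dict:
    """Placement, orientation and order recovery against the true layout.

    Linkage groups are matched to true chromosomes by majority vote of
    their anchored scaffolds; each group's map direction is aligned to the
    chromosome (a genetic map has no intrinsic left end) before comparing
    orientations and computing per-chromosome Kendall tau of scaffold
    order.
    """
    layout = cross.scaffolds.set_index("scaffold_id")
    placed_ok = placed_tot = 0
    orient_ok = orient_tot = 0
    taus: list[float] = []
    for parent, anchored in result.anchorings.items():
        if anchored.empty:
            continue
        a = anchored.copy()
        a["true_chrom"] = [layout.at[s, "chromosome"]
                           for s in a["scaffold_id"]]
        a["true_center"] = [layout.at[s, "offset_bp"]
                            + layout.at[s, "length"] / 2.0
                            for s in a["scaffold_id"]]
        a["true_orient"] = [layout.at[s, "orientation"]
                            for s in a["scaffold_id"]]
        group_to_chrom = {
            g: grp["true_chrom"].mode().iloc[0]
            for g, grp in a.groupby("chromosome")}
        eligible = a[a["n_markers"] >= min_markers]
        placed_tot += len(eligible)
        placed_ok += int(sum(
            group_to_chrom[row.chromosome] == row.true_chrom
            for row in eligible.itertuples()))
        for g, grp in a.groupby("chromosome"):
            on_true = grp[grp["true_chrom"] == group_to_chrom[g]]
            if len(on_true) < 2:
                continue
            r = np.corrcoef(on_true["position_cM"],
                            on_true["true_center"])[0, 1]
            flipped = r < 0
            tau = stats.kendalltau(on_true["position_cM"],
                                   on_true["true_center"]).statistic
            taus.append(abs(float(tau)))
            oriented = on_true[on_true["orientation"].isin(["+", "-"])]
            for row in oriented.itertuples():
                orient_tot += 1
                expected = row.true_orient
                if flipped:
                    expected = "+" if expected == "-" else "-"
                orient_ok += row.orientation == expected
    return {
        "n_scaffolds_eligible": placed_tot,
        "placement_pct": 100.0 * placed_ok / placed_tot if placed_tot
        else float("nan"),
        "n_oriented": orient_tot,
        "orientation_pct": 100.0 * orient_ok / orient_tot if orient_tot
        else float("nan"),
        "mean_kendall_tau": float(np.mean(taus)) if taus else float("nan"),
        "min_kendall_tau": float(np.min(taus)) if taus else float("nan"),
    }
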
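"""End-to-end orchestration: TC extraction -> strings -> HMM -> merge ->
filters -> maps -> anchoring, in memory.

The CLI wraps these steps with file I/O between stages; tests and the
acceptance analyses drive them directly from a :class:`~lowmap.simulate.
SimulatedCross` or from parsed inputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hmm import BlockCall, HMMParams, impute_matrix
from .io_formats import PhasedBlock, VariantRecord
from .mapping import (AnchorParams, LinkageParams, anchor_scaffolds,
                      build_map)
from .merge_filter import (FilterParams, MergeParams, MergedCall,
                           apply_filters, merge_block, merged_calls_frame)
from .simulate import SimulatedCross
from .testcross import (MafWindow, StringBuildResult, TestcrossSite,
                        build_observation_strings_from_site_table,
                        classify_testcross_sites)


@dataclass(frozen=True)
class PipelineParams:
    """All stage parameters in one bundle (defaults = operating point)."""

    maf: MafWindow = MafWindow()
    hmm: HMMParams = HMMParams()
    merge: MergeParams = MergeParams()
    filter: FilterParams = FilterParams()
    linkage: LinkageParams = LinkageParams()
    anchor: AnchorParams = AnchorParams()
    min_hom_depth: int = 8


@dataclass
class PipelineResult:
    individuals: list[str]
    tc_sites: list[TestcrossSite]
    tc_counts: Counter
    strings: StringBuildResult
    block_calls: dict[tuple[str, str, int], list[BlockCall]]
    impute_counts: Counter
    merged: dict[str, dict[str, list[MergedCall]]]   # parent -> block -> calls
    merge_counts: Counter
    retained: dict[str, list[str]]
    filter_reports: dict[str, pd.DataFrame]
    calls_frames: dict[str, pd.DataFrame]            # retained markers only
    maps: dict[str, pd.DataFrame] = field(default_factory=dict)
    map_details: dict[str, dict] = field(default_factory=dict)
    marker_meta: dict[str, pd.DataFrame] = field(default_factory=dict)
    anchorings: dict[str, pd.DataFrame] = field(default_factory=dict)
    ambiguous_scaffolds: dict[str, list[str]] = field(default_factory=dict)


def _block_marker_meta(blocks: Iterable[PhasedBlock]) -> pd.DataFrame:
    """Block markers with their scaffold and physical midpoint (bp)."""
    rows = [(b.block_id, b.scaffold_id,
             float(np.mean([p for p, _, _ in b.sites])))
            for b in blocks]
    return pd.DataFrame(rows, columns=["marker_id", "scaffold_id",
                                       "physical_pos"])


def run_pipeline(
    joint_parent_records: Iterable[VariantRecord],
    parent_ids: Sequence[str],
    blocks_by_parent: Mapping[str, list[PhasedBlock]],
    progeny_site_table: Mapping[tuple[str, int],
                                tuple[np.ndarray, np.ndarray, str, str]],
    individuals: Sequence[str],
    params: PipelineParams = PipelineParams(),
    build_maps: bool = True,
) -> PipelineResult:
    """Run every stage downstream of variant calling and phasing."""
    tc_sites, tc_counts = classify_testcross_sites(
        joint_parent_records, parent_ids, blocks_by_parent,
        min_hom_depth=params.min_hom_depth)
    strings = build_observation_strings_from_site_table(
        tc_sites, progeny_site_table, individuals, params.maf)

    block_calls: dict[tuple[str, str, int], list[BlockCall]] = {}
    impute_counts: Counter[str] = Counter()
    for om in strings.matrices:
        calls, counts = impute_matrix(om, params.hmm)
        block_calls[(om.parent_id, om.block_id, om.phase_type)] = calls
        impute_counts.update(counts)

    merged: dict[str, dict[str, list[MergedCall]]] = {p: {}
                                                      for p in parent_ids}
    merge_counts: Counter[str] = Counter()
    block_ids = sorted({(p, b) for (p, b, _) in block_calls})
    for parent, block in block_ids:
        calls0 = block_calls.get((parent, block, 0))
        calls1 = block_calls.get((parent, block, 1))
        mc, counts = merge_block(calls0, calls1, params.merge)
        merged[parent][block] = mc
        merge_counts.update(counts)

    retained: dict[str, list[str]] = {}
    reports: dict[str, pd.DataFrame] = {}
    frames: dict[str, pd.DataFrame] = {}
    for parent in parent_ids:
        keep, report = apply_filters(merged[parent], params.filter)
        retained[parent] = keep
        reports[parent] = report
        frames[parent] = merged_calls_frame(
            {b: merged[parent][b] for b in keep}, individuals)

    result = PipelineResult(list(individuals), tc_sites, tc_counts, strings,
                            block_calls, impute_counts, merged, merge_counts,
                            retained, reports, frames)
    if not build_maps:
        return result
    for parent in parent_ids:
        frame = frames[parent]
        result.marker_meta[parent] = _block_marker_meta(
            blocks_by_parent[parent])
        if len(frame) < 2:
            continue
        map_df, details = build_map(frame, params.linkage)
        result.maps[parent] = map_df
        result.map_details[parent] = details
        anchored, ambiguous = anchor_scaffolds(
            map_df, result.marker_meta[parent], params.anchor)
        result.anchorings[parent] = anchored
        result.ambiguous_scaffolds[parent] = ambiguous
    return result


def run_from_cross(cross: SimulatedCross,
                   params: PipelineParams = PipelineParams(),
                   build_maps: bool = True) -> PipelineResult:
    """Run the pipeline on a simulated cross (in-memory fast path)."""
    return run_pipeline(cross.joint_parent_records(), list(cross.blocks),
                        cross.blocks, cross.progeny_site_table(),
                        cross.individuals, params, build_maps=build_maps)
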
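"""Testcross-site extraction and per-individual observation strings.

A testcross (TC) SNP is heterozygous in exactly one parent and homozygous
in the other, so the F1 progeny segregate 1:1 for the heterozygous parent's
two homologous chromosomes. Each TC site is attached to the parental
haplotype block that phases it and to the homolog ("phase type") carrying
the segregating allele; per individual, the calls over one (block, phase
type) form an observation string over {S, N, M}:

* ``S`` — the segregating allele was observed (het or hom toward it),
* ``N`` — a confident genotype showing only the constant allele,
* ``M`` — no data.

A population-level minor-allele-frequency window (default 0.075-0.425
around the 0.25 expectation under 1:3 allele segregation) removes likely
false TC sites before strings are built.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .io_formats import Genotype, PhasedBlock, VariantRecord

#: observation symbol codes used in matrix form
SYM_N, SYM_S, SYM_M = 0, 1, 2
SYMBOL_CHARS = {SYM_N: "N", SYM_S: "S", SYM_M: "M"}
CHAR_TO_SYM = {v: k for k, v in SYMBOL_CHARS.items()}


@dataclass(frozen=True)
class TestcrossSite:
    scaffold_id: str
    position: int
    parent_id: str
    block_id: str
    seg_phase: int  # homolog (0/1) carrying the segregating allele
    seg_allele: str
    const_allele: str

    def __post_init__(self) -> None:
        if self.seg_allele == self.const_allele:
            raise ValueError("segregating and constant allele identical")
        if self.seg_phase not in (0, 1):
            raise ValueError("seg_phase must be 0 or 1")


@dataclass(frozen=True)
class MafWindow:
    """Allowed minor-allele-frequency range for candidate TC sites."""

    min_maf: float = 0.075
    max_maf: float = 0.425

    def __post_init__(self) -> None:
        if not 0 <= self.min_maf < self.max_maf <= 0.5:
            raise ValueError("require 0 <= min_maf < max_maf <= 0.5")

    def contains(self, maf: float) -> bool:
        return self.min_maf <= maf <= self.max_maf


@dataclass
class ObservationString:
    """Calls of one individual over one (block, phase type)."""

    individual_id: str
    parent_id: str
    block_id: str
    phase_type: int
    symbols: str  # over {S,N,M}
    depths: Sequence[int]
    positions: Sequence[int]

    def __post_init__(self) -> None:
        if not (len(self.symbols) == len(self.depths) == len(self.positions)):
            raise ValueError("symbols/depths/positions length mismatch")
        pos = list(self.positions)
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("positions not strictly increasing")
        for s, d in zip(self.symbols, self.depths):
            if d == 0 and s != "M":
                raise ValueError("zero depth requires symbol M")


@dataclass
class ObservationMatrix:
    """All individuals' observation strings of one (parent, block, phase).

    ``symbols`` and ``depths`` are (n_individuals, n_sites) arrays; symbol
    codes are ``SYM_N``/``SYM_S``/``SYM_M``. This is the unit the HMM
    decodes (vectorised across individuals).
    """

    parent_id: str
    block_id: str
    scaffold_id: str
    phase_type: int
    individuals: tuple[str, ...]
    positions: np.ndarray  # (n_sites,)
    symbols: np.ndarray    # (n_ind, n_sites) int8
    depths: np.ndarray     # (n_ind, n_sites) int32

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def strings(self) -> Iterator[ObservationString]:
        for i, ind in enumerate(self.individuals):
            yield ObservationString(
                ind, self.parent_id, self.block_id, self.phase_type,
                "".join(SYMBOL_CHARS[c] for c in self.symbols[i]),
                self.depths[i].tolist(), self.positions.tolist())


def _block_index(blocks: Iterable[PhasedBlock]
                 ) -> dict[tuple[str, int], tuple[PhasedBlock, str, str]]:
    idx = {}
    for b in blocks:
        for pos, p0, p1 in b.sites:
            idx[(b.scaffold_id, pos)] = (b, p0, p1)
    return idx


def classify_testcross_sites(
    joint_parent_records: Iterable[VariantRecord],
    parent_ids: Sequence[str],
    blocks_by_parent: Mapping[str, Iterable[PhasedBlock]],
    min_hom_depth: int = 8,
) -> tuple[list[TestcrossSite], Counter]:
    """Extract TC-segregating sites from a joint two-parent call.

    A site is emitted iff exactly one parent is heterozygous, the other is
    a confident homozygote (hom genotype at depth >= ``min_hom_depth``),
    site quality/mapping-quality gates passed upstream, and the het parent
    has the site phased in one of its blocks. The segregating phase is the
    phase column of that block carrying the het parent's parent-unique
    allele. Returns ``(sites, exclusion_counts)``.
    """
    if len(parent_ids) != 2:
        raise ValueError("joint call must contain exactly two parents")
    idx = {p: _block_index(blocks_by_parent[p]) for p in parent_ids}
    counts: Counter[str] = Counter()
    sites: list[TestcrossSite] = []
    for rec in joint_parent_records:
        counts["sites_in"] += 1
        if not rec.passes_quality:
            counts["excluded_low_quality"] += 1
            continue
        calls = dict(zip(parent_ids, rec.calls))
        if any(not c.mapping_quality_ok for c in calls.values()):
            counts["excluded_low_mq"] += 1
            continue
        gts = {p: c.genotype for p, c in calls.items()}
        het = [p for p in parent_ids if gts[p] == Genotype.HET]
        if len(het) == 2:
            counts["excluded_intercross"] += 1
            continue
        if len(het) == 0:
            if gts[parent_ids[0]] == gts[parent_ids[1]]:
                counts["excluded_monomorphic"] += 1
            else:
                counts["excluded_hom_hom"] += 1
            continue
        het_parent = het[0]
        hom_parent = parent_ids[1 - parent_ids.index(het_parent)]
        hom_call = calls[hom_parent]
        if hom_call.genotype not in (Genotype.HOM_REF, Genotype.HOM_ALT) \
                or hom_call.depth < min_hom_depth:
            counts["excluded_hom_unconfident"] += 1
            continue
        const_allele = (rec.ref_allele if hom_call.genotype == Genotype.HOM_REF
                        else rec.alt_allele)
        seg_allele = (rec.alt_allele if const_allele == rec.ref_allele
                      else rec.ref_allele)
        phased = idx[het_parent].get((rec.scaffold_id, rec.position))
        if phased is None:
            counts["excluded_unphased"] += 1
            continue
        block, p0, p1 = phased
        if seg_allele not in (p0, p1):
            counts["excluded_phase_allele_mismatch"] += 1
            continue
        seg_phase = 0 if p0 == seg_allele else 1
        counts["sites_emitted"] += 1
        sites.append(TestcrossSite(rec.scaffold_id, rec.position, het_parent,
                                   block.block_id, seg_phase, seg_allele,
                                   const_allele))
    return sites, counts


def site_maf(calls: Sequence, seg_allele_is_alt: bool) -> float | None:
    """Minor-allele frequency at a site from progeny genotype calls.

    Alleles are counted from called genotypes: a het contributes one copy
    of each allele, a hom contributes two copies of its allele (even at
    depth 1 — the VCF genotype is the only evidence). Missing calls are
    excluded from the denominator. Returns None when all calls are missing.
    """
    seg = const = 0
    for c in calls:
        g = c.genotype
        if g == Genotype.MISSING:
            continue
        if g == Genotype.HET:
            seg += 1
            const += 1
        elif (g == Genotype.HOM_ALT) == seg_allele_is_alt:
            seg += 2
        else:
            const += 2
    total = seg + const
    if total == 0:
        return None
    freq = seg / total
    return min(freq, 1.0 - freq)


@dataclass
class StringBuildResult:
    matrices: list[ObservationMatrix]
    counts: Counter = field(default_factory=Counter)
    site_mafs: dict[tuple[str, int], float] = field(default_factory=dict)


def build_observation_strings(
    tc_sites: Sequence[TestcrossSite],
    progeny_records: Iterable[VariantRecord],
    individuals: Sequence[str],
    maf: MafWindow | None = MafWindow(),
) -> StringBuildResult:
    """Assemble per-(parent, block, phase) observation matrices.

    Sites whose population MAF falls outside the window are removed from
    every string (sites with undefined MAF — all progeny missing — are
    retained and counted). Progeny sites with no TC classification are
    ignored; TC sites absent from the progeny call contribute nothing.
    """
    by_coord = {(s.scaffold_id, s.position): s for s in tc_sites}
    counts: Counter[str] = Counter()
    # per TC site: (genotype codes, depths, ref, alt) across individuals
    per_site: dict[tuple[str, int],
                   tuple[np.ndarray, np.ndarray, str, str]] = {}
    for rec in progeny_records:
        key = (rec.scaffold_id, rec.position)
        site = by_coord.get(key)
        if site is None:
            counts["progeny_sites_not_tc"] += 1
            continue
        gt = np.fromiter((int(c.genotype) for c in rec.calls), dtype=np.int8,
                         count=len(rec.calls))
        dp = np.fromiter((c.depth for c in rec.calls), dtype=np.int32,
                         count=len(rec.calls))
        per_site[key] = (gt, dp, rec.ref_allele, rec.alt_allele)
    return build_observation_strings_from_site_table(
        tc_sites, per_site, individuals, maf, counts)


def build_observation_strings_from_site_table(
    tc_sites: Sequence[TestcrossSite],
    per_site: Mapping[tuple[str, int],
                      tuple[np.ndarray, np.ndarray, str, str]],
    individuals: Sequence[str],
    maf: MafWindow | None = MafWindow(),
    counts: Counter | None = None,
) -> StringBuildResult:
    """Array-backed core of :func:`build_observation_strings`.

    ``per_site`` maps (scaffold, position) to per-individual genotype-code
    and depth vectors plus the site's ref/alt alleles; the simulator feeds
    this directly without materialising VCF records.
    """
    counts = counts if counts is not None else Counter()
    site_mafs: dict[tuple[str, int], float] = {}
    groups: dict[tuple[str, str, int], list[TestcrossSite]] = {}
    for s in sorted(tc_sites, key=lambda s: (s.parent_id, s.block_id,
                                             s.seg_phase, s.position)):
        key = (s.scaffold_id, s.position)
        if key not in per_site:
            counts["tc_sites_absent_from_progeny"] += 1
            continue
        groups.setdefault((s.parent_id, s.block_id, s.seg_phase),
                          []).append(s)

    matrices: list[ObservationMatrix] = []
    n_ind = len(individuals)
    for (parent, block, phase), sites in groups.items():
        kept: list[tuple[TestcrossSite, bool]] = []
        for s in sites:
            gt, dp, ref, alt = per_site[(s.scaffold_id, s.position)]
            if {s.seg_allele, s.const_allele} != {ref, alt}:
                counts["sites_allele_mismatch"] += 1
                continue
            seg_is_alt = s.seg_allele == alt
            m = _site_maf_from_codes(gt, seg_is_alt)
            if m is None:
                counts["sites_maf_undefined_retained"] += 1
                kept.append((s, seg_is_alt))
                continue
            site_mafs[(s.scaffold_id, s.position)] = m
            if maf is not None and not maf.contains(m):
                counts["sites_maf_filtered"] += 1
                continue
            kept.append((s, seg_is_alt))
        if not kept:
            counts["groups_empty_after_maf"] += 1
            continue
        positions = np.array([s.position for s, _ in kept], dtype=np.int64)
        sym = np.full((n_ind, len(kept)), SYM_M, dtype=np.int8)
        dep = np.zeros((n_ind, len(kept)), dtype=np.int32)
        for j, (s, seg_is_alt) in enumerate(kept):
            gt, dp, _, _ = per_site[(s.scaffold_id, s.position)]
            sym[:, j] = _symbols_for_site(gt, seg_is_alt)
            dep[:, j] = dp
        matrices.append(ObservationMatrix(
            parent, block, kept[0][0].scaffold_id, phase, tuple(individuals),
            positions, sym, dep))
        counts["strings_built"] += n_ind
    return StringBuildResult(matrices, counts, site_mafs)


def _site_maf_from_codes(gt: np.ndarray, seg_is_alt: bool) -> float | None:
    """Scalar-site MAF from a genotype-code vector (same convention as
    :func:`site_maf`)."""
    nonmiss = gt != int(Genotype.MISSING)
    total = 2 * int(nonmiss.sum())
    if total == 0:
        return None
    het = int((gt == int(Genotype.HET)).sum())
    hom_seg_code = int(Genotype.HOM_ALT) if seg_is_alt else int(Genotype.HOM_REF)
    seg = het + 2 * int((gt == hom_seg_code).sum())
    freq = seg / total
    return min(freq, 1.0 - freq)


def _symbols_for_site(gt: np.ndarray, seg_is_alt: bool) -> np.ndarray:
    """Map genotype codes to observation symbols for one site."""
    sym = np.full(gt.shape, SYM_M, dtype=np.int8)
    het = gt == int(Genotype.HET)
    hom_alt = gt == int(Genotype.HOM_ALT)
    hom_ref = gt == int(Genotype.HOM_REF)
    hom_seg = hom_alt if seg_is_alt else hom_ref
    hom_const = hom_ref if seg_is_alt else hom_alt
    sym[het | hom_seg] = SYM_S
    sym[hom_const] = SYM_N
    return sym
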
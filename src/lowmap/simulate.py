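"""Synthetic F1 cross generator with complete truth tracking.

Emulates the study design the pipeline targets: two heterozygous,
phase-unknown parents of an outbreeding diploid; a draft assembly whose
scaffolds tile 17 chromosomes in an order and orientation the assembler
does not know; parental heterozygous SNPs concentrated in phased haplotype
blocks at a density of ~1 SNP / 59 bp, with one parent carrying long
homozygous tracts; an F1 progeny of 163 individuals produced by Haldane
(no-interference) meioses; and low-pass (0.5-1x) sequencing of the progeny
with Poisson read depth, allele dropout at depth-1 heterozygous sites,
read miscalls and multi-mapping false heterozygous evidence.

Every stochastic choice flows from one seed via spawned sub-streams, so a
fixed seed reproduces the dataset byte-for-byte; truth tables (inherited
homolog per block, crossover positions, scaffold layout, TC-site roster)
make every pipeline stage checkable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .io_formats import (Genotype, PhasedBlock, SampleCall, VariantRecord,
                         write_phased_blocks_hapcut, write_phased_blocks_tsv,
                         write_vcf)

PARENTS = ("P1", "P2")
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated cross (defaults = target design)."""

    n_chromosomes: int = 17
    chromosome_length_cM: float = 90.0
    scaffolds_per_chromosome: int = 6
    scaffold_length_bp: int = 150_000
    scaffold_length_cv: float = 0.2      # relative spread of lengths
    blocks_per_scaffold: int = 4
    block_span_bp: int = 4_800           # SNP-dense island hosting one block
    snp_spacing_bp: float = 59.0         # mean spacing inside blocks
    roh_fraction: float = 0.3            # of P2's genome in homozygous runs
    intercross_fraction: float = 0.05    # extra sites het in both parents
    hom_alt_fraction: float = 0.1        # hom parent is alt/alt at a TC site
    n_progeny: int = 163
    coverage: float = 0.75               # mean progeny depth (0.5-1x design)
    parent_coverage: float = 45.0
    miscall_rate: float = 0.01
    mismap_het_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("roh_fraction", "intercross_fraction",
                     "hom_alt_fraction", "miscall_rate", "mismap_het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_progeny < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one progeny and chromosome")


@dataclass
class TruthSet:
    """Ground truth of one simulated cross."""

    individuals: list[str]
    scaffolds: pd.DataFrame          # scaffold_id, chromosome, order_index,
    #                                  orientation, length, offset_bp
    block_homolog: dict[str, pd.DataFrame]   # parent -> blocks x individuals
    block_crossover: dict[str, pd.DataFrame]  # parent -> bool, same shape
    crossovers: dict[tuple[str, str, int], tuple[int, np.ndarray]]
    tc_roster: pd.DataFrame          # true TC sites with block and phase


@dataclass
class SimulatedCross:
    """In-memory dataset: inputs for every pipeline stage plus truth."""

    config: SimConfig
    scaffolds: pd.DataFrame
    sites: pd.DataFrame
    blocks: dict[str, list[PhasedBlock]]
    individuals: list[str]
    truth: TruthSet
    parent_gt: np.ndarray     # (n_sites, 2) Genotype codes
    parent_dp: np.ndarray
    progeny_gt: np.ndarray    # (n_sites, n_progeny) Genotype codes
    progeny_dp: np.ndarray

    # -- record streams (the same objects a VCF round-trip would yield) --

    def joint_parent_records(self) -> Iterator[VariantRecord]:
        for i, row in enumerate(self.sites.itertuples()):
            calls = tuple(
                SampleCall(Genotype(int(self.parent_gt[i, j])),
                           int(self.parent_dp[i, j]))
                for j in range(2))
            yield VariantRecord(row.scaffold, int(row.pos), row.ref, row.alt,
                                222.0, calls)

    def progeny_site_table(self) -> dict[tuple[str, int],
                                         tuple[np.ndarray, np.ndarray,
                                               str, str]]:
        """Per-site arrays for the fast observation-string path."""
        out = {}
        for i, row in enumerate(self.sites.itertuples()):
            out[(row.scaffold, int(row.pos))] = (
                self.progeny_gt[i], self.progeny_dp[i], row.ref, row.alt)
        return out

    def scaffold_lengths(self) -> dict[str, int]:
        return dict(zip(self.scaffolds["scaffold_id"],
                        self.scaffolds["length"].astype(int)))


# ---------------------------------------------------------------------------
# Genome and parents
# ---------------------------------------------------------------------------

def _simulate_scaffolds(cfg: SimConfig, rng: np.random.Generator
                        ) -> pd.DataFrame:
    rows = []
    sid = 0
    for chrom in range(1, cfg.n_chromosomes + 1):
        offset = 0
        for k in range(cfg.scaffolds_per_chromosome):
            lo = 1.0 - cfg.scaffold_length_cv
            hi = 1.0 + cfg.scaffold_length_cv
            length = int(round(cfg.scaffold_length_bp
                               * rng.uniform(lo, hi)))
            orientation = "+" if rng.random() < 0.5 else "-"
            rows.append((f"scaffold_{sid:04d}", chrom, k, orientation,
                         length, offset))
            offset += length
            sid += 1
    return pd.DataFrame(rows, columns=["scaffold_id", "chromosome",
                                       "order_index", "orientation",
                                       "length", "offset_bp"])


def _chrom_bp(scaffold_row, local_pos: np.ndarray) -> np.ndarray:
    """Local scaffold coordinates -> chromosomal bp."""
    if scaffold_row.orientation == "+":
        return scaffold_row.offset_bp + local_pos
    return scaffold_row.offset_bp + scaffold_row.length - local_pos + 1


def _block_sites(cfg: SimConfig, rng: np.random.Generator, length: int,
                 parity: int) -> list[np.ndarray]:
    """Renewal-process site positions for each block island of a scaffold.

    Positions are snapped to one parity per parent so the two parents'
    independent site sets can never collide at a coordinate (a collision
    would be an intercross site, which is generated separately).
    """
    out = []
    slot = length / cfg.blocks_per_scaffold
    for k in range(cfg.blocks_per_scaffold):
        span = min(cfg.block_span_bp, int(slot * 0.9))
        start = slot * k + rng.uniform(0, max(slot - span, 1))
        n_max = max(int(span / cfg.snp_spacing_bp * 3), 8)
        gaps = rng.exponential(cfg.snp_spacing_bp, size=n_max)
        pos = start + np.cumsum(gaps)
        pos = pos[pos < start + span]
        pos = np.floor(pos).astype(np.int64)
        pos = pos - (pos % 2) + parity
        pos = np.unique(pos)
        pos = pos[(pos >= 2) & (pos <= length)]
        out.append(pos)
    return out


def simulate_parents(cfg: SimConfig, rng: np.random.Generator | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame,
                                dict[str, list[PhasedBlock]]]:
    """Generate the assembly layout, parental het sites and phased blocks.

    Returns ``(scaffolds, sites, blocks)``. ``sites`` covers everything a
    joint two-parent call would contain: per parent het-in-one-parent
    sites inside phased blocks (TC candidates) and a fraction of
    intercross sites het in both parents (never phased). P2 carries
    homozygous runs covering ``roh_fraction`` of each chromosome: no P2
    het sites fall inside them.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    scaffolds = _simulate_scaffolds(cfg, rng)
    chrom_len = scaffolds.groupby("chromosome")["length"].sum().to_dict()
    # one homozygous run per chromosome for P2
    roh: dict[int, tuple[float, float]] = {}
    for chrom, total in chrom_len.items():
        span = cfg.roh_fraction * total
        start = rng.uniform(0, total - span) if span < total else 0.0
        roh[chrom] = (start, start + span)

    rows = []
    blocks: dict[str, list[PhasedBlock]] = {p: [] for p in PARENTS}
    for parity, parent in enumerate(PARENTS):
        for scaf in scaffolds.itertuples():
            for bnum, pos in enumerate(
                    _block_sites(cfg, rng, scaf.length, parity)):
                if parent == "P2":
                    cb = _chrom_bp(scaf, pos)
                    lo, hi = roh[scaf.chromosome]
                    pos = pos[(cb < lo) | (cb >= hi)]
                if pos.size < 2:
                    continue
                block_id = f"{parent}_{scaf.scaffold_id}_b{bnum}"
                ref = rng.choice(_BASES, size=pos.size)
                alt_idx = (np.searchsorted(_BASES, ref)
                           + rng.integers(1, 4, size=pos.size)) % 4
                alt = _BASES[alt_idx]
                alt_hom = rng.integers(0, 2, size=pos.size)
                other_hom_alt = rng.random(pos.size) < cfg.hom_alt_fraction
                sites = []
                for i in range(pos.size):
                    rows.append((scaf.scaffold_id, int(pos[i]),
                                 scaf.chromosome,
                                 int(_chrom_bp(scaf, pos[i : i + 1])[0]),
                                 str(ref[i]), str(alt[i]), parent, block_id,
                                 int(alt_hom[i]) if parent == "P1" else -1,
                                 int(alt_hom[i]) if parent == "P2" else -1,
                                 bool(other_hom_alt[i])))
                    p0 = alt[i] if alt_hom[i] == 0 else ref[i]
                    p1 = alt[i] if alt_hom[i] == 1 else ref[i]
                    sites.append((int(pos[i]), str(p0), str(p1)))
                blocks[parent].append(
                    PhasedBlock(parent, block_id, scaf.scaffold_id, sites))

    n_tc = len(rows)
    n_ic = int(round(cfg.intercross_fraction * n_tc))
    taken = {(r[0], r[1]) for r in rows}
    scaf_list = list(scaffolds.itertuples())
    made = 0
    while made < n_ic:
        scaf = scaf_list[int(rng.integers(0, len(scaf_list)))]
        p = int(rng.integers(1, scaf.length + 1))
        if (scaf.scaffold_id, p) in taken:
            continue
        taken.add((scaf.scaffold_id, p))
        ref = str(rng.choice(_BASES))
        alt = str(_BASES[(int(np.searchsorted(_BASES, ref))
                          + int(rng.integers(1, 4))) % 4])
        rows.append((scaf.scaffold_id, p, scaf.chromosome,
                     int(_chrom_bp(scaf, np.array([p]))[0]), ref, alt,
                     "both", "", int(rng.integers(0, 2)),
                     int(rng.integers(0, 2)), False))
        made += 1

    sites = pd.DataFrame(rows, columns=[
        "scaffold", "pos", "chromosome", "chrom_bp", "ref", "alt",
        "het_parent", "block_id", "p1_alt_hom", "p2_alt_hom",
        "other_hom_alt"]).sort_values(["scaffold", "pos"],
                                      ignore_index=True)
    return scaffolds, sites, blocks


# ---------------------------------------------------------------------------
# Meiosis and progeny calls
# ---------------------------------------------------------------------------

def _gamete(cfg: SimConfig, rng: np.random.Generator, chrom_bp_len: int
            ) -> tuple[int, np.ndarray]:
    """One meiotic product: (starting homolog, crossover bp positions)."""
    n_xo = rng.poisson(cfg.chromosome_length_cM / 100.0)
    xo = np.sort(rng.uniform(0, chrom_bp_len, size=n_xo))
    return int(rng.integers(0, 2)), xo


def _homolog_at(start: int, xo: np.ndarray, bp: np.ndarray) -> np.ndarray:
    return (start + np.searchsorted(xo, bp)) % 2


def simulate_progeny(cfg: SimConfig, scaffolds: pd.DataFrame,
                     sites: pd.DataFrame,
                     rng: np.random.Generator | None = None
                     ) -> tuple[TruthSet, dict[str, np.ndarray]]:
    """Simulate meioses and per-site inherited homologs.

    Crossover counts are Poisson(length_cM / 100) per gamete with uniform
    positions (Haldane model, no interference; recombination uniform per
    bp). Returns the truth set plus, per parent, the (n_sites, n_progeny)
    matrix of inherited homologs at every site of ``sites`` (meaningful
    where that parent is heterozygous).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    individuals = [f"F1_{i + 1:03d}" for i in range(cfg.n_progeny)]
    chrom_len = scaffolds.groupby("chromosome")["length"].sum().to_dict()
    chroms = sorted(chrom_len)
    crossovers: dict[tuple[str, str, int], tuple[int, np.ndarray]] = {}
    for ind in individuals:
        for parent in PARENTS:
            for chrom in chroms:
                crossovers[(parent, ind, chrom)] = _gamete(
                    cfg, rng, chrom_len[chrom])

    n_sites = len(sites)
    chrom_arr = sites["chromosome"].to_numpy()
    bp_arr = sites["chrom_bp"].to_numpy()
    inherited = {p: np.zeros((n_sites, cfg.n_progeny), dtype=np.int8)
                 for p in PARENTS}
    for chrom in chroms:
        mask = chrom_arr == chrom
        bp = bp_arr[mask]
        for j, ind in enumerate(individuals):
            for parent in PARENTS:
                start, xo = crossovers[(parent, ind, chrom)]
                inherited[parent][mask, j] = _homolog_at(start, xo, bp)

    block_homolog: dict[str, pd.DataFrame] = {}
    block_crossover: dict[str, pd.DataFrame] = {}
    for parent in PARENTS:
        own = sites["het_parent"] == parent
        hom_rows = {}
        xo_rows = {}
        for block_id, grp in sites[own].groupby("block_id", sort=True):
            h = inherited[parent][grp.index.to_numpy()]
            majority = (h.mean(axis=0) >= 0.5).astype(np.int8)
            hom_rows[block_id] = majority
            xo_rows[block_id] = (h != h[0]).any(axis=0)
        block_homolog[parent] = pd.DataFrame.from_dict(
            hom_rows, orient="index", columns=individuals)
        block_crossover[parent] = pd.DataFrame.from_dict(
            xo_rows, orient="index", columns=individuals)

    tc_mask = sites["het_parent"].isin(PARENTS)
    tc = sites[tc_mask].copy()
    alt_hom = np.where(tc["het_parent"] == "P1", tc["p1_alt_hom"],
                       tc["p2_alt_hom"])
    seg_is_alt = ~tc["other_hom_alt"].to_numpy()
    tc_roster = pd.DataFrame({
        "scaffold": tc["scaffold"], "pos": tc["pos"],
        "parent": tc["het_parent"], "block_id": tc["block_id"],
        "seg_allele": np.where(seg_is_alt, tc["alt"], tc["ref"]),
        "const_allele": np.where(seg_is_alt, tc["ref"], tc["alt"]),
        "seg_phase": np.where(seg_is_alt, alt_hom, 1 - alt_hom),
    }).reset_index(drop=True)

    truth = TruthSet(individuals, scaffolds, block_homolog, block_crossover,
                     crossovers, tc_roster)
    return truth, inherited


def simulate_calls(cfg: SimConfig, sites: pd.DataFrame,
                   inherited: Mapping[str, np.ndarray],
                   rng: np.random.Generator | None = None
                   ) -> tuple[np.ndarray, np.ndarray,
                              np.ndarray, np.ndarray]:
    """Low-coverage progeny calls and deep parental calls at every site.

    Per site and individual the read depth is Poisson(coverage); at a true
    heterozygote the reads split Binomial(d, 0.5) (a single read can never
    yield a het call — allele dropout); each read is miscalled to the
    other allele with ``miscall_rate``; with ``mismap_het_rate`` a true
    homozygote gains one spurious read of the other allele. The genotype
    is called directly from observed alleles: both seen -> het, one seen
    -> hom, none -> missing. Returns ``(progeny_gt, progeny_dp, parent_gt,
    parent_dp)``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    n_sites = len(sites)
    n = cfg.n_progeny

    # transmitted allele (0=ref, 1=alt) from each parent
    allele = {}
    for parent, col in (("P1", "p1_alt_hom"), ("P2", "p2_alt_hom")):
        alt_hom = sites[col].to_numpy()
        is_het = ((sites["het_parent"] == parent)
                  | (sites["het_parent"] == "both")).to_numpy()
        fixed = np.where(sites["other_hom_alt"].to_numpy(), 1, 0)
        a = np.where(is_het[:, None],
                     (inherited[parent] == alt_hom[:, None]).astype(np.int8),
                     fixed[:, None].astype(np.int8))
        allele[parent] = a
    a1, a2 = allele["P1"], allele["P2"]

    dp = rng.poisson(cfg.coverage, size=(n_sites, n)).astype(np.int32)
    het = a1 != a2
    n_alt = np.where(het, rng.binomial(dp, 0.5), dp * a1)
    n_ref = dp - n_alt
    if cfg.miscall_rate > 0:
        flip_r = rng.binomial(n_ref, cfg.miscall_rate)
        flip_a = rng.binomial(n_alt, cfg.miscall_rate)
        n_ref = n_ref - flip_r + flip_a
        n_alt = n_alt - flip_a + flip_r
    if cfg.mismap_het_rate > 0:
        hom = ~het
        gain = hom & (rng.random((n_sites, n)) < cfg.mismap_het_rate)
        gain_alt = gain & (a1 == 0)
        gain_ref = gain & (a1 == 1)
        n_alt = n_alt + gain_alt
        n_ref = n_ref + gain_ref
        dp = dp + gain
    progeny_gt = np.full((n_sites, n), int(Genotype.MISSING), dtype=np.int8)
    covered = dp > 0
    progeny_gt[covered & (n_ref > 0) & (n_alt > 0)] = int(Genotype.HET)
    progeny_gt[covered & (n_alt > 0) & (n_ref == 0)] = int(Genotype.HOM_ALT)
    progeny_gt[covered & (n_ref > 0) & (n_alt == 0)] = int(Genotype.HOM_REF)

    # deep parental calls (error-free at this coverage for the purpose of
    # the joint call; the pipeline's gates are still exercised)
    parent_dp = rng.poisson(cfg.parent_coverage, size=(n_sites, 2)) \
        .astype(np.int32)
    parent_dp = np.maximum(parent_dp, 1)
    parent_gt = np.empty((n_sites, 2), dtype=np.int8)
    for j, parent in enumerate(PARENTS):
        is_het = ((sites["het_parent"] == parent)
                  | (sites["het_parent"] == "both")).to_numpy()
        fixed_alt = sites["other_hom_alt"].to_numpy()
        parent_gt[:, j] = np.where(
            is_het, int(Genotype.HET),
            np.where(fixed_alt, int(Genotype.HOM_ALT),
                     int(Genotype.HOM_REF)))
    return progeny_gt, dp, parent_gt, parent_dp


def simulate_cross(cfg: SimConfig) -> SimulatedCross:
    """Run the full generator: parents, meioses, low-coverage calls."""
    root = np.random.SeedSequence(cfg.seed)
    s_parents, s_progeny, s_calls = root.spawn(3)
    scaffolds, sites, blocks = simulate_parents(
        cfg, np.random.default_rng(s_parents))
    truth, inherited = simulate_progeny(
        cfg, scaffolds, sites, np.random.default_rng(s_progeny))
    progeny_gt, progeny_dp, parent_gt, parent_dp = simulate_calls(
        cfg, sites, inherited, np.random.default_rng(s_calls))
    return SimulatedCross(cfg, scaffolds, sites, blocks, truth.individuals,
                          truth, parent_gt, parent_dp, progeny_gt,
                          progeny_dp)


# ---------------------------------------------------------------------------
# On-disk emission
# ---------------------------------------------------------------------------

_GT_TO_PAIR = {int(Genotype.HOM_REF): (0, 0), int(Genotype.HET): (0, 1),
               int(Genotype.HOM_ALT): (1, 1),
               int(Genotype.MISSING): (None, None)}


def write_dataset(cross: SimulatedCross, outdir: str | Path) -> dict:
    """Write all pipeline inputs plus truth tables; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = [(r.scaffold_id, int(r.length))
               for r in cross.scaffolds.itertuples()]

    def vcf_rows(gt: np.ndarray, dp: np.ndarray):
        for i, row in enumerate(cross.sites.itertuples()):
            gts = [_GT_TO_PAIR[int(g)] for g in gt[i]]
            yield (row.scaffold, int(row.pos), row.ref, row.alt, 222.0,
                   gts, dp[i])

    write_vcf(out / "parents.vcf", list(PARENTS),
              vcf_rows(cross.parent_gt, cross.parent_dp), contigs)
    write_vcf(out / "progeny.vcf", cross.individuals,
              vcf_rows(cross.progeny_gt, cross.progeny_dp), contigs)
    for parent in PARENTS:
        write_phased_blocks_tsv(cross.blocks[parent],
                                out / f"blocks_{parent}.tsv")
        write_phased_blocks_hapcut(cross.blocks[parent],
                                   out / f"blocks_{parent}.hapcut")
    cross.scaffolds[["scaffold_id", "length"]].to_csv(
        out / "scaffold_lengths.tsv", sep="\t", index=False)
    cross.scaffolds.to_csv(out / "truth_scaffold_layout.tsv", sep="\t",
                           index=False)
    cross.truth.tc_roster.to_csv(out / "truth_tc_sites.tsv", sep="\t",
                                 index=False)
    for parent in PARENTS:
        cross.truth.block_homolog[parent].rename_axis("block_id").to_csv(
            out / f"truth_block_homolog_{parent}.tsv", sep="\t")
    manifest = {
        "config": asdict(cross.config),
        "files": sorted(p.name for p in out.iterdir()
                        if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
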
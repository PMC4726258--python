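"""Readers and writers for the on-disk formats of the pipeline.

Handles multi-sample VCF (via pysam), HAPCUT-style phased haplotype block
files (plus a plain-TSV dialect), genetic-map TSV, the rotated genotype
matrix exported for map construction (R/qtl-style "csvr" layout), the
scaffold anchoring table, and AGP pseudomolecule layouts.

All coordinates are 1-based and inclusive, matching VCF.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam


class Genotype(enum.IntEnum):
    """Diploid biallelic genotype of one sample at one site."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = 3


@dataclass(frozen=True)
class SampleCall:
    """One sample's call at one site.

    ``depth == 0`` always implies ``genotype == MISSING`` (enforced at parse
    time); ``mapping_quality_ok`` reflects the site-level mapping quality
    gate (per-sample MQ is not available in a standard multi-sample call).
    """

    genotype: Genotype
    depth: int
    mapping_quality_ok: bool = True

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("negative depth")
        if self.depth == 0 and self.genotype != Genotype.MISSING:
            raise ValueError("depth 0 requires missing genotype")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP site with one call per sample of the roster."""

    scaffold_id: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    site_quality: float
    calls: tuple[SampleCall, ...]
    passes_quality: bool = True

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")


class VcfFormatError(ValueError):
    pass


class VcfReader:
    """Stream biallelic SNP records from a VCF 4.x file.

    Multi-allelic and indel records are excluded (counted per reason);
    records below the site-quality threshold are *flagged*, not dropped,
    so downstream stages can report them. Iterating yields
    :class:`VariantRecord` in file order; the sample roster is available as
    :attr:`samples` immediately after construction.
    """

    def __init__(self, path: str | Path, min_qual: float = 20.0,
                 min_mq: float = 25.0):
        self.path = str(path)
        self.min_qual = min_qual
        self.min_mq = min_mq
        try:
            self._vcf = pysam.VariantFile(self.path)
        except (OSError, ValueError) as exc:
            raise VcfFormatError(f"cannot parse VCF {self.path}: {exc}") from exc
        if "GT" not in self._vcf.header.formats:
            raise VcfFormatError(f"{self.path}: VCF lacks a GT FORMAT field")
        self.samples: tuple[str, ...] = tuple(self._vcf.header.samples)
        self.counts: Counter[str] = Counter()

    def __iter__(self) -> Iterator[VariantRecord]:
        for rec in self._vcf:
            self.counts["records_in"] += 1
            if rec.alts is None or len(rec.alts) != 1:
                self.counts["excluded_multiallelic"] += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref == "." or alt == ".":
                self.counts["excluded_not_snp"] += 1
                continue
            qual = float(rec.qual) if rec.qual is not None else 0.0
            mq = rec.info.get("MQ", None)
            mq_ok = True if mq is None else float(mq) >= self.min_mq
            calls = []
            for name in self.samples:
                s = rec.samples[name]
                gt = s.get("GT", (None, None))
                dp = s.get("DP", None)
                depth = int(dp) if dp is not None else 0
                if gt is None or None in gt or len(gt) != 2 or depth == 0:
                    calls.append(SampleCall(Genotype.MISSING, 0, mq_ok))
                    continue
                a, b = gt
                if a == 0 and b == 0:
                    g = Genotype.HOM_REF
                elif a == 1 and b == 1:
                    g = Genotype.HOM_ALT
                else:
                    g = Genotype.HET
                calls.append(SampleCall(g, depth, mq_ok))
            passes = qual >= self.min_qual
            if not passes:
                self.counts["flagged_below_quality"] += 1
            self.counts["records_emitted"] += 1
            yield VariantRecord(rec.chrom, rec.pos, ref, alt, qual,
                                tuple(calls), passes_quality=passes)


def read_vcf(path: str | Path, min_qual: float = 20.0,
             min_mq: float = 25.0) -> VcfReader:
    """Open a VCF for streaming; see :class:`VcfReader`."""
    return VcfReader(path, min_qual=min_qual, min_mq=min_mq)


def write_vcf(path: str | Path, samples: Sequence[str],
              records: Iterable[tuple[str, int, str, str, float,
                                      Sequence[tuple[int | None, int | None]],
                                      Sequence[int]]],
              contigs: Sequence[tuple[str, int]]) -> None:
    """Write an uncompressed multi-sample VCF.

    ``records`` yields ``(scaffold, pos, ref, alt, qual, genotypes, depths)``
    where each genotype is an allele-index pair (``(None, None)`` = missing).
    """
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for scaffold, pos, ref, alt, qual, gts, dps in records:
            rec = out.new_record(contig=scaffold, start=pos - 1,
                                 stop=pos, alleles=(ref, alt), qual=qual)
            rec.info["MQ"] = 60.0
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = gts[i]
                rec.samples[s]["DP"] = int(dps[i])
            out.write(rec)


# ---------------------------------------------------------------------------
# Phased haplotype blocks
# ---------------------------------------------------------------------------

@dataclass
class PhasedBlock:
    """A parental haplotype block: phased heterozygous sites on one scaffold.

    ``sites`` is an ordered list of ``(position, phase0_allele,
    phase1_allele)``; the two alleles are always the site's ref and alt in
    some order (heterozygous by construction).
    """

    parent_id: str
    block_id: str
    scaffold_id: str
    sites: list[tuple[int, str, str]] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.sites) < 2:
            raise ValueError(f"block {self.block_id}: fewer than 2 sites")
        pos = [s[0] for s in self.sites]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(
                f"block {self.block_id}: positions not strictly increasing")


def read_phased_blocks(path: str | Path, dialect: str = "hapcut",
                       parent_id: str = "") -> tuple[list[PhasedBlock], Counter]:
    """Parse a phased-block file.

    ``dialect='hapcut'``: blocks start with a ``BLOCK:`` header; variant
    lines carry ``index hap0 hap1 chrom pos ref alt ...``; ``********``
    terminates a block. Sites with unresolved phase (``-``) are skipped and
    counted; blocks left with fewer than 2 sites are discarded and counted.

    ``dialect='tsv'``: tab-separated with a header line
    ``block_id scaffold position phase0_allele phase1_allele``.

    Returns ``(blocks, counts)``.
    """
    counts: Counter[str] = Counter()
    blocks: list[PhasedBlock] = []
    if dialect == "hapcut":
        blocks.extend(_read_hapcut(Path(path), parent_id, counts))
    elif dialect == "tsv":
        blocks.extend(_read_blocks_tsv(Path(path), parent_id, counts))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for b in blocks:
        b.validate()
    return blocks, counts


def _read_hapcut(path: Path, parent_id: str,
                 counts: Counter) -> Iterator[PhasedBlock]:
    cur: PhasedBlock | None = None
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("*"):
                continue
            if line.startswith("BLOCK:"):
                if cur is not None:
                    yield from _finish_block(cur, counts)
                n += 1
                cur = PhasedBlock(parent_id, f"{parent_id}_block{n:06d}", "")
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise VcfFormatError(
                    f"{path}:{lineno}: malformed HAPCUT variant line")
            if cur is None:
                raise VcfFormatError(
                    f"{path}:{lineno}: variant line before any BLOCK header")
            _, h0, h1, chrom, pos, ref, alt = fields[:7]
            if h0 == "-" or h1 == "-":
                counts["sites_unphased_skipped"] += 1
                continue
            p0 = ref if h0 == "0" else alt
            p1 = ref if h1 == "0" else alt
            if not cur.scaffold_id:
                cur.scaffold_id = chrom
            cur.sites.append((int(pos), p0, p1))
    if cur is not None:
        yield from _finish_block(cur, counts)


def _finish_block(block: PhasedBlock, counts: Counter) -> Iterator[PhasedBlock]:
    if len(block.sites) < 2:
        counts["blocks_discarded_short"] += 1
        return
    counts["blocks_read"] += 1
    yield block


def _read_blocks_tsv(path: Path, parent_id: str,
                     counts: Counter) -> Iterator[PhasedBlock]:
    df = pd.read_csv(path, sep="\t", dtype={"block_id": str, "scaffold": str})
    required = {"block_id", "scaffold", "position",
                "phase0_allele", "phase1_allele"}
    missing = required - set(df.columns)
    if missing:
        raise VcfFormatError(f"{path}: missing columns {sorted(missing)}")
    for block_id, grp in df.groupby("block_id", sort=False):
        keep = (grp["phase0_allele"] != "-") & (grp["phase1_allele"] != "-")
        counts["sites_unphased_skipped"] += int((~keep).sum())
        grp = grp[keep]
        if len(grp) < 2:
            counts["blocks_discarded_short"] += 1
            continue
        block = PhasedBlock(parent_id, str(block_id),
                            str(grp["scaffold"].iloc[0]),
                            list(zip(grp["position"].astype(int),
                                     grp["phase0_allele"],
                                     grp["phase1_allele"])))
        counts["blocks_read"] += 1
        yield block


def write_phased_blocks_tsv(blocks: Iterable[PhasedBlock],
                            path: str | Path) -> None:
    rows = [(b.block_id, b.scaffold_id, p, a0, a1)
            for b in blocks for (p, a0, a1) in b.sites]
    pd.DataFrame(rows, columns=["block_id", "scaffold", "position",
                                "phase0_allele", "phase1_allele"]
                 ).to_csv(path, sep="\t", index=False)


def write_phased_blocks_hapcut(blocks: Iterable[PhasedBlock],
                               path: str | Path) -> None:
    """Emit blocks in the HAPCUT text dialect (ref/alt inferred per site)."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"BLOCK: offset: 1 len: {len(b.sites)} "
                     f"phased: {len(b.sites)}\n")
            for i, (pos, p0, p1) in enumerate(b.sites, 1):
                # phase columns are allele indices; phase-0 column first
                ref, alt = (p0, p1)  # ref defined as the phase-0 allele here
                fh.write(f"{i}\t0\t1\t{b.scaffold_id}\t{pos}\t{ref}\t{alt}\n")
            fh.write("********\n")


# ---------------------------------------------------------------------------
# Genetic maps, genotype matrix, anchoring table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMapEntry:
    marker_id: str
    linkage_group: int | str
    position_cM: float


def read_genetic_map(path: str | Path) -> pd.DataFrame:
    """Read a map TSV with columns marker_id, linkage_group, position_cM."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    required = {"marker_id", "linkage_group", "position_cM"}
    if missing := required - set(df.columns):
        raise VcfFormatError(f"{path}: missing columns {sorted(missing)}")
    if df["marker_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate marker_id")
    if (df["position_cM"] < 0).any():
        raise ValueError(f"{path}: negative cM positions")
    return df


def write_genetic_map(entries: pd.DataFrame, path: str | Path) -> None:
    entries[["marker_id", "linkage_group", "position_cM"]].to_csv(
        path, sep="\t", index=False)


#: genotype-matrix export codes for the inherited parental homolog
GENOTYPE_CODES = {"h0": "A", "h1": "H", "missing": "-"}
CODE_TO_HOMOLOG = {v: k for k, v in GENOTYPE_CODES.items()}


def write_genotype_matrix(calls: pd.DataFrame, path: str | Path,
                          genetic_map: pd.DataFrame | None = None) -> None:
    """Export merged homolog calls as a rotated (marker-per-row) CSV.

    ``calls``: index = marker_id, columns = individuals, values in
    {'h0','h1','missing'}. Coding in the file is A (homolog 0), H (homolog
    1), ``-`` (missing) — the two-state backcross-style coding of a
    pseudo-testcross parental map. Map positions are left blank for
    unmapped markers.
    """
    if calls.index.duplicated().any():
        raise ValueError("duplicate marker_id in genotype matrix")
    pos: dict[str, tuple] = {}
    if genetic_map is not None:
        pos = {r.marker_id: (r.linkage_group, r.position_cM)
               for r in genetic_map.itertuples()}
    with open(path, "w") as fh:
        fh.write("# rotated genotype matrix; coding: A=homolog0, "
                 "H=homolog1, -=missing\n")
        fh.write(",".join(["marker_id", "linkage_group", "position_cM"]
                          + list(calls.columns)) + "\n")
        for marker_id, row in calls.iterrows():
            lg, cm = pos.get(str(marker_id), ("", ""))
            codes = [GENOTYPE_CODES[v] for v in row]
            fh.write(",".join([str(marker_id), str(lg), str(cm)] + codes)
                     + "\n")


def read_genotype_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-parse a rotated genotype matrix; returns (calls, map_entries)."""
    df = pd.read_csv(path, comment="#", dtype=str).fillna("")
    individuals = [c for c in df.columns
                   if c not in ("marker_id", "linkage_group", "position_cM")]
    calls = df.set_index("marker_id")[individuals].apply(
        lambda col: col.map(CODE_TO_HOMOLOG))
    mapped = df[df["position_cM"] != ""]
    entries = pd.DataFrame({
        "marker_id": mapped["marker_id"],
        "linkage_group": mapped["linkage_group"],
        "position_cM": mapped["position_cM"].astype(float),
    }).reset_index(drop=True)
    return calls, entries


ANCHOR_COLUMNS = ["scaffold_id", "chromosome", "position_cM",
                  "orientation", "n_markers"]


def write_anchoring_table(anchored: pd.DataFrame, path: str | Path) -> None:
    anchored[ANCHOR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_anchoring_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold_id": str,
                                            "orientation": str})
    if missing := set(ANCHOR_COLUMNS) - set(df.columns):
        raise VcfFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_agp(anchored: pd.DataFrame, scaffold_lengths: dict[str, int],
              path: str | Path, gap_size: int = 100) -> None:
    """Emit an AGP 2.x pseudomolecule layout from an anchoring table.

    Scaffolds are ordered by cM within each chromosome; unoriented
    scaffolds are written as '+' with the component left unflipped (AGP has
    no unknown orientation for W components; '?' is written instead).
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for chrom, grp in anchored.groupby("chromosome", sort=True):
            grp = grp.sort_values(["position_cM", "scaffold_id"])
            start = 1
            part = 0
            for i, row in enumerate(grp.itertuples()):
                if i > 0:
                    part += 1
                    fh.write(f"chr{chrom}\t{start}\t{start + gap_size - 1}\t"
                             f"{part}\tN\t{gap_size}\tcontig\tno\tna\n")
                    start += gap_size
                length = scaffold_lengths[row.scaffold_id]
                part += 1
                ori = row.orientation if row.orientation in "+-" else "?"
                fh.write(f"chr{chrom}\t{start}\t{start + length - 1}\t{part}"
                         f"\tW\t{row.scaffold_id}\t1\t{length}\t{ori}\n")
                start += length
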
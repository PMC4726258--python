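"""Two-point linkage, genetic binning, scaffold anchoring and map statistics.

Markers are merged block calls coded h0/h1 (a backcross-style 1:1
segregation, one map per heterozygous parent). Pairwise recombination
fractions and LOD scores drive grouping (connected components at LOD >= 10
and rf <= 0.20 by default); markers with identical segregation collapse
into genetic bins; a naive nearest-neighbour ordering with Haldane
distances provides map positions when no externally computed order is
supplied. Scaffolds are placed at the mean genetic position of their
markers and oriented by the correlation of genetic with physical
coordinates; doublet concordance between the two parental maps validates
the anchoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LinkageParams:
    min_lod: float = 10.0
    max_rf: float = 0.20
    min_shared: int = 10  # informative individuals required per pair

    def __post_init__(self) -> None:
        if self.min_lod <= 0:
            raise ValueError("min_lod must be positive")
        if not 0.0 < self.max_rf <= 0.5:
            raise ValueError("max_rf must be in (0, 0.5]")


@dataclass(frozen=True)
class AnchorParams:
    min_abs_pearson: float = 0.50  # strict >
    doublet_window_cM: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_abs_pearson <= 1.0:
            raise ValueError("min_abs_pearson must be in [0, 1]")
        if self.doublet_window_cM <= 0:
            raise ValueError("doublet_window_cM must be positive")


@dataclass(frozen=True)
class AnchoredScaffold:
    scaffold_id: str
    chromosome: int | str
    position_cM: float
    orientation: str  # '+' | '-' | '.'
    n_markers: int


def genotypes_to_numeric(calls: pd.DataFrame) -> np.ndarray:
    """h0/h1/missing table (markers x individuals) -> 0/1/NaN array."""
    mapping = {"h0": 0.0, "h1": 1.0, "missing": np.nan}
    return calls.apply(lambda col: col.map(mapping)).to_numpy(dtype=np.float64)


def two_point(a: np.ndarray, b: np.ndarray, min_shared: int = 10
              ) -> tuple[float, float]:
    """Recombination fraction and LOD for one marker pair.

    Parental phase across scaffolds is arbitrary in a pseudo-testcross, so
    the phase minimising rf is taken (rf = min(D, N-D)/N over the N
    individuals called in both). LOD is the backcross two-point statistic
    R log10 rf + (N-R) log10(1-rf) + N log10 2, with the rf -> 0 limit
    N log10 2. Pairs with fewer than ``min_shared`` shared calls are
    undefined (NaN, NaN).
    """
    valid = ~np.isnan(a) & ~np.isnan(b)
    n = int(valid.sum())
    if n < min_shared:
        return float("nan"), float("nan")
    d = int((a[valid] != b[valid]).sum())
    r = min(d, n - d)
    rf = r / n
    if r == 0:
        lod = n * np.log10(2.0)
    else:
        lod = r * np.log10(rf) + (n - r) * np.log10(1.0 - rf) \
            + n * np.log10(2.0)
    return float(rf), float(lod)


def pairwise_linkage(G: np.ndarray, min_shared: int = 10
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs rf/LOD via matrix products.

    ``G`` is (markers x individuals) over {0, 1, NaN}. Returns ``(rf, lod,
    n_shared)`` square matrices; pairs with < ``min_shared`` shared calls
    are NaN. Identical to :func:`two_point` per pair.
    """
    M = (~np.isnan(G)).astype(np.float64)
    X = np.nan_to_num(G) * M
    N = M @ M.T
    # discordant count: x_i (1-x_j) + (1-x_i) x_j over shared calls
    D = X @ (M - X).T + (M - X) @ X.T
    R = np.minimum(D, N - D)
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = R / N
        lod = np.where(
            R == 0,
            N * np.log10(2.0),
            R * np.log10(np.where(rf > 0, rf, 1.0))
            + (N - R) * np.log10(np.where(rf < 1, 1.0 - rf, 1.0))
            + N * np.log10(2.0))
    bad = N < min_shared
    rf[bad] = np.nan
    lod[bad] = np.nan
    np.fill_diagonal(rf, 0.0)
    np.fill_diagonal(lod, np.nan)
    return rf, lod, N


def group_markers(marker_ids: Sequence[str], rf: np.ndarray, lod: np.ndarray,
                  params: LinkageParams = LinkageParams()
                  ) -> tuple[list[list[int]], list[int]]:
    """Linkage groups as connected components of the qualifying-edge graph.

    An edge joins markers i, j when lod >= min_lod and rf <= max_rf.
    Returns (groups, singletons) as index lists; groups are sorted by size
    (largest first) then by smallest member index.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(marker_ids)))
    ii, jj = np.nonzero(np.triu(
        (lod >= params.min_lod) & (rf <= params.max_rf), k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = [sorted(c) for c in nx.connected_components(g)]
    groups = sorted((c for c in comps if len(c) > 1),
                    key=lambda c: (-len(c), c[0]))
    singletons = sorted(i for c in comps if len(c) == 1 for i in c)
    return groups, singletons


def bin_markers(G: np.ndarray, members: Sequence[int]
                ) -> list[tuple[list[int], np.ndarray]]:
    """Collapse markers with identical segregation into genetic bins.

    Markers join an existing bin when they never disagree with the bin
    consensus at a co-called individual; the consensus is the columnwise
    union of its members' calls. Returns ``(member_indices, consensus)``
    per bin, in first-seen order.
    """
    bins: list[tuple[list[int], np.ndarray]] = []
    for idx in members:
        row = G[idx]
        placed = False
        for mem, cons in bins:
            both = ~np.isnan(row) & ~np.isnan(cons)
            if not np.any(row[both] != cons[both]):
                mem.append(idx)
                fill = np.isnan(cons) & ~np.isnan(row)
                cons[fill] = row[fill]
                placed = True
                break
        if not placed:
            bins.append(([idx], row.copy()))
    return bins


def order_within_group(rf: np.ndarray) -> list[int]:
    """Greedy nearest-neighbour chain over a bin-level rf matrix (naive).

    Starts from the closest pair and repeatedly appends the nearest unused
    bin to whichever chain end offers the smaller rf. NaN entries (too few
    shared calls) are treated as unlinked (rf 0.5). Externally computed
    orders, when available, should always be preferred over this fallback.
    """
    m = rf.shape[0]
    if m <= 1:
        return list(range(m))
    d = np.where(np.isnan(rf), 0.5, rf).astype(np.float64)
    np.fill_diagonal(d, np.inf)
    start = int(np.argmin(d))
    a, b = divmod(start, m)
    chain = [a, b]
    used = {a, b}
    while len(chain) < m:
        free = [i for i in range(m) if i not in used]
        head, tail = chain[0], chain[-1]
        hi = min(free, key=lambda i: (d[head, i], i))
        ti = min(free, key=lambda i: (d[tail, i], i))
        if d[head, hi] < d[tail, ti]:
            chain.insert(0, hi)
            used.add(hi)
        else:
            chain.append(ti)
            used.add(ti)
    return chain


def haldane_cm(rf: float) -> float:
    """Map distance in cM under the Haldane (no-interference) function."""
    rf = min(max(rf, 0.0), 0.499)
    return float(-50.0 * np.log(1.0 - 2.0 * rf))


def build_map(calls: pd.DataFrame,
              params: LinkageParams = LinkageParams()
              ) -> tuple[pd.DataFrame, dict]:
    """Group, bin and order markers; assign cM positions.

    ``calls`` is the filtered marker table (markers x individuals over
    h0/h1/missing). Returns a map table (marker_id, linkage_group,
    position_cM — every member marker of a bin shares its position) and a
    details dict (bins per group, singleton markers).
    """
    ids = list(calls.index)
    G = genotypes_to_numeric(calls)
    rf, lod, _ = pairwise_linkage(G, params.min_shared)
    groups, singletons = group_markers(ids, rf, lod, params)
    rows = []
    details: dict = {"n_groups": len(groups),
                     "singletons": [ids[i] for i in singletons],
                     "bins_per_group": []}
    for gnum, members in enumerate(groups, start=1):
        bins = bin_markers(G, members)
        reps = [mem[0] for mem, _ in bins]
        sub_rf = rf[np.ix_(reps, reps)]
        order = order_within_group(sub_rf)
        pos = 0.0
        positions = {}
        for k, bin_idx in enumerate(order):
            if k > 0:
                prev = order[k - 1]
                step = sub_rf[prev, bin_idx]
                pos += haldane_cm(0.5 if np.isnan(step) else float(step))
            positions[bin_idx] = pos
        details["bins_per_group"].append(len(bins))
        for bin_idx, (mem, _) in enumerate(bins):
            for marker in mem:
                rows.append((ids[marker], gnum, positions[bin_idx]))
    map_df = pd.DataFrame(rows, columns=["marker_id", "linkage_group",
                                         "position_cM"])
    return map_df, details


# ---------------------------------------------------------------------------
# Scaffold placement and orientation
# ---------------------------------------------------------------------------

def place_scaffold(markers: pd.DataFrame,
                   params: AnchorParams = AnchorParams()
                   ) -> AnchoredScaffold | None:
    """Place one scaffold from its mapped markers.

    ``markers``: columns scaffold_id, physical_pos, linkage_group,
    position_cM. The majority linkage group wins (ties -> ambiguous, not
    placed, None returned); position is the mean cM of the majority-group
    markers; orientation is '+'/'-' when |Pearson r| of physical vs
    genetic position exceeds the threshold, else '.'.
    """
    counts = markers["linkage_group"].value_counts()
    if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
        return None
    lg = counts.index[0]
    grp = markers[markers["linkage_group"] == lg]
    pos = float(grp["position_cM"].mean())
    orientation = "."
    if len(grp) >= 2:
        phys = grp["physical_pos"].to_numpy(dtype=float)
        gen = grp["position_cM"].to_numpy(dtype=float)
        if np.std(phys) > 0 and np.std(gen) > 0:
            r = float(np.corrcoef(phys, gen)[0, 1])
            if r > params.min_abs_pearson:
                orientation = "+"
            elif r < -params.min_abs_pearson:
                orientation = "-"
    return AnchoredScaffold(str(markers["scaffold_id"].iloc[0]), lg, pos,
                            orientation, int(len(grp)))


def anchor_scaffolds(map_df: pd.DataFrame, marker_meta: pd.DataFrame,
                     params: AnchorParams = AnchorParams()
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Place every scaffold with mapped markers.

    ``marker_meta``: columns marker_id, scaffold_id, physical_pos (marker
    midpoint on the scaffold, bp). Returns the anchoring table and the
    scaffolds left ambiguous (markers split across groups with no
    majority).
    """
    merged = map_df.merge(marker_meta, on="marker_id", how="inner")
    rows = []
    ambiguous: list[str] = []
    for scaffold_id, grp in merged.groupby("scaffold_id", sort=True):
        placed = place_scaffold(grp, params)
        if placed is None:
            ambiguous.append(str(scaffold_id))
            continue
        rows.append((placed.scaffold_id, placed.chromosome,
                     placed.position_cM, placed.orientation,
                     placed.n_markers))
    table = pd.DataFrame(rows, columns=["scaffold_id", "chromosome",
                                        "position_cM", "orientation",
                                        "n_markers"])
    return table, ambiguous


# ---------------------------------------------------------------------------
# Validation statistics
# ---------------------------------------------------------------------------

def align_group_directions(map1: pd.DataFrame, map2: pd.DataFrame
                           ) -> pd.DataFrame:
    """Reverse linkage groups of ``map2`` that run against ``map1``.

    A genetic map has no intrinsic left end, so independently built maps
    can disagree on direction group by group. For every map2 group the
    positions of scaffolds shared with map1 are correlated against their
    map1 positions (using the map1 group holding most of the shared
    scaffolds); anticorrelated groups are reflected (max - position).
    Returns the adjusted copy of ``map2``.
    """
    m1 = map1.set_index("scaffold_id")
    out = map2.copy()
    for chrom, grp in map2.groupby("chromosome"):
        shared = grp[grp["scaffold_id"].isin(m1.index)]
        if len(shared) < 2:
            continue
        partner = m1.loc[shared["scaffold_id"], "chromosome"].mode().iloc[0]
        anchors = shared[m1.loc[shared["scaffold_id"],
                                "chromosome"].to_numpy() == partner]
        if len(anchors) < 2:
            continue
        other = m1.loc[anchors["scaffold_id"], "position_cM"].to_numpy()
        own = anchors["position_cM"].to_numpy()
        if np.std(other) == 0 or np.std(own) == 0:
            continue
        if np.corrcoef(own, other)[0, 1] < 0:
            sel = out["chromosome"] == chrom
            top = out.loc[sel, "position_cM"].max()
            out.loc[sel, "position_cM"] = top - out.loc[sel, "position_cM"]
    return out


def concordance_percent(n_concordant: int, n_discordant: int) -> float:
    total = n_concordant + n_discordant
    if total == 0:
        raise ValueError("no comparable doublets")
    return 100.0 * n_concordant / total


def doublet_concordance(map1: pd.DataFrame, map2: pd.DataFrame,
                        params: AnchorParams = AnchorParams(),
                        min_scaffold_len: int | None = None,
                        scaffold_lengths: Mapping[str, int] | None = None,
                        reference: str = "both") -> dict:
    """Concordance of scaffold doublets between two anchoring tables.

    A doublet is a pair of scaffolds anchored in both maps, on a shared
    chromosome in each, separated by at most the window in the reference
    map (``reference='first'``) or in either map (``'both'``, the default,
    deduplicated). Concordant means the reciprocal order agrees; pairs
    tied in either map are skipped and counted; pairs split across
    chromosomes in the other map are skipped and counted. The optional
    length filter keeps pairs where both scaffolds reach
    ``min_scaffold_len``.
    """
    if reference not in ("first", "both"):
        raise ValueError("reference must be 'first' or 'both'")
    m1 = map1.set_index("scaffold_id")
    m2 = map2.set_index("scaffold_id")
    shared = sorted(set(m1.index) & set(m2.index))
    if min_scaffold_len is not None:
        if scaffold_lengths is None:
            raise ValueError("length filter requires scaffold_lengths")
        shared = [s for s in shared
                  if scaffold_lengths[s] >= min_scaffold_len]
    n_conc = n_disc = n_tied = n_split = 0
    for a, b in combinations(shared, 2):
        within1 = (m1.at[a, "chromosome"] == m1.at[b, "chromosome"]
                   and abs(m1.at[a, "position_cM"] - m1.at[b, "position_cM"])
                   <= params.doublet_window_cM)
        within2 = (m2.at[a, "chromosome"] == m2.at[b, "chromosome"]
                   and abs(m2.at[a, "position_cM"] - m2.at[b, "position_cM"])
                   <= params.doublet_window_cM)
        qualifies = within1 if reference == "first" else (within1 or within2)
        if not qualifies:
            continue
        if m1.at[a, "chromosome"] != m1.at[b, "chromosome"] \
                or m2.at[a, "chromosome"] != m2.at[b, "chromosome"]:
            n_split += 1
            continue
        d1 = m1.at[a, "position_cM"] - m1.at[b, "position_cM"]
        d2 = m2.at[a, "position_cM"] - m2.at[b, "position_cM"]
        if d1 == 0 or d2 == 0:
            n_tied += 1
            continue
        if (d1 > 0) == (d2 > 0):
            n_conc += 1
        else:
            n_disc += 1
    pct = (concordance_percent(n_conc, n_disc)
           if n_conc + n_disc else float("nan"))
    return {"n_concordant": n_conc, "n_discordant": n_disc,
            "n_tied_skipped": n_tied, "n_split_skipped": n_split,
            "percent_concordant": pct}


def bins_from_map(map_df: pd.DataFrame) -> pd.DataFrame:
    """Collapse a marker-level map to one entry per genetic bin.

    Markers sharing (linkage_group, position_cM) occupy one bin; the bin
    keeps the first marker's id and a member count.
    """
    bins = (map_df.groupby(["linkage_group", "position_cM"], sort=True)
            .agg(marker_id=("marker_id", "first"),
                 n_markers=("marker_id", "size"))
            .reset_index())
    return bins[["marker_id", "linkage_group", "position_cM", "n_markers"]]


def mean_interbin_spacing(total_length_cM: float, n_bins: int,
                          n_groups: int) -> float:
    """Average inter-bin distance: map length over inter-bin intervals.

    The interval count is bins - groups (a group of b bins spans b - 1
    intervals).
    """
    intervals = n_bins - n_groups
    if intervals <= 0:
        raise ValueError("no inter-bin intervals")
    return total_length_cM / intervals


def map_summary(map_df: pd.DataFrame) -> dict:
    """Total length, bin count and mean inter-bin spacing of a bin map.

    Expects one entry per genetic bin. Total length sums per-group spans
    (max - min position); the spacing denominator is the number of
    inter-bin intervals, bins - groups (single-bin groups contribute zero
    length and zero intervals).
    """
    if len(map_df) < 2:
        raise ValueError("need at least 2 bins")
    lengths = map_df.groupby("linkage_group")["position_cM"] \
        .agg(lambda s: s.max() - s.min())
    n_bins = int(len(map_df))
    n_groups = int(map_df["linkage_group"].nunique())
    total = float(lengths.sum())
    try:
        spacing = mean_interbin_spacing(total, n_bins, n_groups)
    except ValueError:
        spacing = float("nan")
    return {"total_length_cM": total, "n_bins": n_bins,
            "n_groups": n_groups, "mean_spacing_cM": spacing}


def anchored_fraction_percent(anchored_bp: float, assembly_total_bp: float
                              ) -> int:
    """Anchored percentage of the assembly, rounded for reporting."""
    if assembly_total_bp <= 0:
        raise ValueError("assembly size must be positive")
    return round(100.0 * anchored_bp / assembly_total_bp)


def anchoring_summary(anchored: pd.DataFrame,
                      scaffold_lengths: Mapping[str, int],
                      assembly_total_bp: float) -> dict:
    """Anchored/oriented base-pair totals for an anchoring table."""
    missing = [s for s in anchored["scaffold_id"]
               if s not in scaffold_lengths]
    if missing:
        raise KeyError(f"unknown scaffold ids: {missing[:5]}")
    anchored_bp = int(sum(scaffold_lengths[s]
                          for s in anchored["scaffold_id"]))
    oriented = anchored[anchored["orientation"].isin(["+", "-"])]
    oriented_bp = int(sum(scaffold_lengths[s]
                          for s in oriented["scaffold_id"]))
    return {"anchored_bp": anchored_bp,
            "anchored_fraction_pct": anchored_fraction_percent(
                anchored_bp, assembly_total_bp),
            "oriented_bp": oriented_bp,
            "n_anchored": int(len(anchored)),
            "n_oriented": int(len(oriented))}
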
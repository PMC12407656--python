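"""Tile-based inference of transmitted and non-transmitted parental alleles.

Given phased haplotypes for an offspring and one or both parents, each
chromosome is cut into tiles of adjacent markers (default 150).  Every tile of
the offspring haplotype assigned to a parent is matched against that parent's
two haplotypes by Hamming distance; the best-matching parental haplotype is
the transmitted source for the tile, recombination showing up as a change of
source between tiles.  An optional change-point refinement places each source
change at marker resolution.  The alleles of the non-chosen parental haplotype
form the non-transmitted dataset; for a pair family (one genotyped parent) the
missing parent's non-transmitted alleles are recorded as missing, while its
transmitted alleles are taken to be the unassigned offspring haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simfam import MISSING, GeneticMap, HaplotypeSet, TransmissionTruth

logger = logging.getLogger(__name__)

DEFAULT_TILE_SIZE = 150
MIN_INFORMATIVE = 10

__all__ = [
    "Tile",
    "TileMatch",
    "TransmissionRecord",
    "TransmissionMap",
    "ConcordanceReport",
    "tile_partition",
    "match_tiles",
    "assign_parent_of_origin",
    "refine_breakpoints",
    "infer_transmission",
    "infer_all",
    "concordance",
]


@dataclass(frozen=True)
class Tile:
    """Half-open marker index range [start, end) on one chromosome."""

    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class TileMatch:
    """Per-tile mismatch counts and assigned source haplotype (1 or 2)."""

    tiles: list
    mismatch1: np.ndarray
    mismatch2: np.ndarray
    source: np.ndarray          # int8 in {1, 2}
    tie: np.ndarray             # bool
    low_info: np.ndarray        # bool


@dataclass
class TransmissionRecord:
    """Inferred transmission for one offspring.

    ``transmitted[role]`` / ``nontransmitted[role]`` are per-marker allele
    vectors (-1 = missing); ``source[role]`` gives the parental haplotype of
    origin (0 where the parent is not genotyped); ``hap_assignment`` maps
    parent role -> offspring haplotype index.
    """

    offspring: str
    hap_assignment: dict
    transmitted: dict = field(default_factory=dict)
    nontransmitted: dict = field(default_factory=dict)
    source: dict = field(default_factory=dict)
    breakpoints: dict = field(default_factory=dict)
    margin: float = 0.0
    ambiguous: bool = False


@dataclass
class TransmissionMap:
    gmap: GeneticMap
    records: dict = field(default_factory=dict)

    def offspring(self) -> list:
        return list(self.records)


@dataclass
class ConcordanceReport:
    compared: int
    concordant: int
    per_chrom: pd.DataFrame

    @property
    def rate(self) -> float:
        return self.concordant / self.compared if self.compared else float("nan")


def tile_partition(n_markers: int, tile_size: int = DEFAULT_TILE_SIZE) -> list:
    """Cut ``n_markers`` into consecutive tiles of ``tile_size``.

    A trailing remainder shorter than half a tile is merged into the previous
    tile; a longer remainder stands as its own tile.
    """
    if tile_size < 2:
        raise ValueError("tile_size must be >= 2")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    bounds = list(range(0, n_markers, tile_size))
    tiles = [Tile(b, min(b + tile_size, n_markers)) for b in bounds]
    if len(tiles) > 1 and tiles[-1].size < tile_size / 2:
        last = tiles.pop()
        prev = tiles.pop()
        tiles.append(Tile(prev.start, last.end))
    return tiles


def _mismatch_cumsums(off_hap: np.ndarray, parent: np.ndarray):
    """Prefix sums of per-marker mismatch indicators vs each parental haplotype,
    counting only markers where both offspring and parent alleles are observed."""
    valid = (off_hap >= 0) & (parent[0] >= 0) & (parent[1] >= 0)
    d1 = ((off_hap != parent[0]) & valid).astype(np.int32)
    d2 = ((off_hap != parent[1]) & valid).astype(np.int32)
    z = np.zeros(1, dtype=np.int64)
    return (
        np.concatenate([z, np.cumsum(d1)]),
        np.concatenate([z, np.cumsum(d2)]),
        valid,
    )


def match_tiles(
    off_hap: np.ndarray,
    parent: np.ndarray,
    tiles: list,
    min_informative: int = MIN_INFORMATIVE,
) -> TileMatch:
    """Assign each tile of an offspring haplotype to a parental haplotype.

    The source is the haplotype with fewer mismatches over the tile's
    non-missing markers.  Ties keep the previous tile's assignment
    (continuity); a first-tile tie defaults to haplotype 1 and is flagged.
    Tiles with fewer than ``min_informative`` informative markers
    (parent heterozygous, non-missing) inherit a neighbour's assignment and
    are flagged low-information.
    """
    c1, c2, valid = _mismatch_cumsums(off_hap, parent)
    het = (parent[0] != parent[1]) & (parent[0] >= 0) & (parent[1] >= 0) & (off_hap >= 0)
    chet = np.concatenate([np.zeros(1, dtype=np.int64), np.cumsum(het)])

    T = len(tiles)
    m1 = np.empty(T, dtype=np.int64)
    m2 = np.empty(T, dtype=np.int64)
    info = np.empty(T, dtype=np.int64)
    for t, tile in enumerate(tiles):
        m1[t] = c1[tile.end] - c1[tile.start]
        m2[t] = c2[tile.end] - c2[tile.start]
        info[t] = chet[tile.end] - chet[tile.start]

    source = np.zeros(T, dtype=np.int8)
    tie = np.zeros(T, dtype=bool)
    low_info = info < min_informative
    prev = 0  # 0 = undecided
    for t in range(T):
        if low_info[t]:
            source[t] = prev  # back-filled below if leading
        elif m1[t] < m2[t]:
            source[t] = 1
        elif m2[t] < m1[t]:
            source[t] = 2
        else:
            tie[t] = True
            source[t] = prev if prev else 1
        if source[t]:
            prev = source[t]
    # leading undecided tiles inherit the first decided assignment
    if (source == 0).any():
        decided = np.flatnonzero(source != 0)
        fill = source[decided[0]] if len(decided) else 1
        source[source == 0] = fill
    return TileMatch(tiles, m1, m2, source, tie, low_info)


def _besttile_cost(off_hap: np.ndarray, parent: np.ndarray, tiles: list) -> int:
    """Genome-wide sum of per-tile best mismatch counts (the matching score)."""
    c1, c2, _ = _mismatch_cumsums(off_hap, parent)
    total = 0
    for tile in tiles:
        total += min(c1[tile.end] - c1[tile.start], c2[tile.end] - c2[tile.start])
    return int(total)


def assign_parent_of_origin(
    off_haps: np.ndarray,
    parents: dict,
    gmap: GeneticMap,
    tile_size: int = DEFAULT_TILE_SIZE,
):
    """Map offspring haplotypes to parents by genome-wide best-tile mismatch.

    ``parents`` maps role ('mother'/'father') to a (2, M) haplotype array or
    None when that parent is not genotyped.  Trios consider both pairings of
    offspring haplotypes to parents; pairs assign the better-matching
    offspring haplotype to the single genotyped parent.  Returns
    (assignment dict role -> offspring hap index, margin, ambiguous flag).
    A zero margin falls back to the fixed rule haplotype 1 -> mother (or the
    genotyped parent) and is flagged ambiguous.
    """
    tiles = []
    for chrom in gmap.chroms:
        sl = gmap.chrom_slice(chrom)
        tiles += [Tile(t.start + sl.start, t.end + sl.start)
                  for t in tile_partition(sl.stop - sl.start, tile_size)]

    genotyped = {r: h for r, h in parents.items() if h is not None}
    if not genotyped:
        raise ValueError("at least one parent must be genotyped")

    cost = {
        (h, role): _besttile_cost(off_haps[h], hap, tiles)
        for h in (0, 1)
        for role, hap in genotyped.items()
    }
    if len(genotyped) == 2:
        a = cost[(0, "mother")] + cost[(1, "father")]
        b = cost[(0, "father")] + cost[(1, "mother")]
        margin = abs(a - b)
        if a < b:
            assignment = {"mother": 0, "father": 1}
        elif b < a:
            assignment = {"mother": 1, "father": 0}
        else:
            assignment = {"mother": 0, "father": 1}
            return assignment, 0.0, True
        return assignment, float(margin), False
    role = next(iter(genotyped))
    c0, c1 = cost[(0, role)], cost[(1, role)]
    margin = abs(c0 - c1)
    other = "father" if role == "mother" else "mother"
    if c0 == c1:
        return {role: 0, other: 1}, 0.0, True
    best = 0 if c0 < c1 else 1
    return {role: best, other: 1 - best}, float(margin), False


def refine_breakpoints(
    source_tiles: TileMatch, off_hap: np.ndarray, parent: np.ndarray
) -> tuple[np.ndarray, list]:
    """Expand tile-level sources to marker resolution with change-point search.

    For each source change between adjacent tiles, the union of the two tiles
    is scanned for the breakpoint minimizing total mismatches (old source
    before, new source after).  Returns the per-marker source vector (over the
    local chromosome index space) and the list of breakpoint marker indices.
    """
    tiles = source_tiles.tiles
    n = tiles[-1].end
    c1, c2, _ = _mismatch_cumsums(off_hap, parent)
    cums = {1: c1, 2: c2}
    src = np.empty(n, dtype=np.int8)
    for t, tile in enumerate(tiles):
        src[tile.start:tile.end] = source_tiles.source[t]

    breakpoints = []
    prev_bp = 0
    for t in range(len(tiles) - 1):
        s, s2 = source_tiles.source[t], source_tiles.source[t + 1]
        if s == s2:
            continue
        lo = max(tiles[t].start, prev_bp)
        hi = tiles[t + 1].end
        cs, cn = cums[int(s)], cums[int(s2)]
        cands = np.arange(lo, hi + 1)
        cost = (cs[cands] - cs[lo]) + (cn[hi] - cn[cands])
        bp = int(cands[np.argmin(cost)])
        src[lo:bp] = s
        src[bp:hi] = s2
        breakpoints.append(bp)
        prev_bp = bp
    return src, breakpoints


def _source_vector(
    off_hap: np.ndarray,
    parent: np.ndarray,
    gmap: GeneticMap,
    tile_size: int,
    refine: bool,
):
    """Per-marker transmitted-source vector for one offspring hap vs one parent."""
    M = gmap.n_markers
    src = np.empty(M, dtype=np.int8)
    bps = []
    for chrom in gmap.chroms:
        sl = gmap.chrom_slice(chrom)
        tiles = tile_partition(sl.stop - sl.start, tile_size)
        tm = match_tiles(off_hap[sl], parent[:, sl], tiles)
        if refine:
            local_src, local_bps = refine_breakpoints(tm, off_hap[sl], parent[:, sl])
        else:
            local_src = np.empty(sl.stop - sl.start, dtype=np.int8)
            for t, tile in enumerate(tiles):
                local_src[tile.start:tile.end] = tm.source[t]
            local_bps = [
                tiles[t + 1].start
                for t in range(len(tiles) - 1)
                if tm.source[t] != tm.source[t + 1]
            ]
        src[sl] = local_src
        bps += [(chrom, b) for b in local_bps]
    return src, bps


def infer_transmission(
    offspring_id: str,
    off_haps: np.ndarray,
    parents: dict,
    gmap: GeneticMap,
    tile_size: int = DEFAULT_TILE_SIZE,
    refine: bool = True,
) -> TransmissionRecord:
    """Infer transmitted/non-transmitted alleles for one family.

    For each genotyped parent, the offspring haplotype assigned to that parent
    is traced tile-by-tile through the parent's haplotypes; the transmitted
    allele at each marker is the source haplotype's allele and the
    non-transmitted allele is the other haplotype's.  For a non-genotyped
    parent the transmitted alleles are the unassigned offspring haplotype and
    the non-transmitted alleles are all missing.
    """
    assignment, margin, ambiguous = assign_parent_of_origin(
        off_haps, parents, gmap, tile_size
    )
    rec = TransmissionRecord(
        offspring_id, assignment, margin=margin, ambiguous=ambiguous
    )
    M = gmap.n_markers
    idx = np.arange(M)
    for role in ("mother", "father"):
        h = assignment[role]
        parent = parents.get(role)
        if parent is None:
            rec.transmitted[role] = off_haps[h].copy()
            rec.nontransmitted[role] = np.full(M, MISSING, dtype=np.int8)
            rec.source[role] = np.zeros(M, dtype=np.int8)
            rec.breakpoints[role] = []
            continue
        src, bps = _source_vector(off_haps[h], parent, gmap, tile_size, refine)
        # the transmitted allele is the one the offspring actually carries on
        # the haplotype assigned to this parent; the non-transmitted allele is
        # the parent's genotype complement.  Markers where the offspring
        # allele is Mendelian-inconsistent with the parent (possible only
        # with phase or genotype errors) fall back to the source-complement
        # haplotype; markers with a missing parent allele yield missing NT.
        transmitted = off_haps[h].astype(np.int16)
        dosage = parent[0].astype(np.int16) + parent[1]
        nt = dosage - transmitted
        bad = (nt < 0) | (nt > 1)
        nt[bad] = parent[2 - src, idx][bad]
        nt[(parent[0] < 0) | (parent[1] < 0) | (transmitted < 0)] = MISSING
        rec.transmitted[role] = transmitted.astype(np.int8)
        rec.nontransmitted[role] = nt.astype(np.int8)
        rec.source[role] = src
        rec.breakpoints[role] = bps
    return rec


def infer_all(
    haps: HaplotypeSet,
    pedigree: pd.DataFrame,
    tile_size: int = DEFAULT_TILE_SIZE,
    refine: bool = True,
) -> TransmissionMap:
    """Run transmission inference for every offspring with >= 1 genotyped parent.

    Non-genotyped offspring (or offspring with no genotyped parent) are
    skipped with a logged warning.
    """
    tmap = TransmissionMap(haps.gmap)
    for fam, sub in pedigree.groupby("family_id", sort=False):
        parent_hap = {}
        for role in ("mother", "father"):
            row = sub[sub["role"] == role]
            if len(row) and bool(row["genotyped"].iloc[0]):
                parent_hap[role] = haps.haps[row["individual_id"].iloc[0]]
            else:
                parent_hap[role] = None
        for _, row in sub[sub["role"] == "offspring"].iterrows():
            oid = row["individual_id"]
            if not bool(row["genotyped"]) or oid not in haps.haps:
                logger.warning("offspring %s not genotyped; skipped", oid)
                continue
            if parent_hap["mother"] is None and parent_hap["father"] is None:
                logger.warning("family %s has no genotyped parent; %s skipped", fam, oid)
                continue
            tmap.records[oid] = infer_transmission(
                oid, haps.haps[oid], parent_hap, haps.gmap, tile_size, refine
            )
    return tmap


def concordance(
    tmap: TransmissionMap,
    truth: TransmissionTruth,
    haps: HaplotypeSet,
    pedigree: pd.DataFrame,
) -> ConcordanceReport:
    """Fraction of inferred non-transmitted alleles matching simulator truth.

    Only non-missing inferred alleles of genotyped parents are compared; the
    truth non-transmitted allele at a marker is the parental haplotype NOT
    recorded as the transmission source.
    """
    shared = [o for o in tmap.records if o in truth.source]
    if not shared:
        raise ValueError("no overlapping families between inference and truth")
    ped = pedigree.set_index("individual_id")
    fam_parent = {}
    for _, row in pedigree[pedigree["role"].isin(["mother", "father"])].iterrows():
        fam_parent[(row["family_id"], row["role"])] = (
            row["individual_id"], bool(row["genotyped"])
        )
    gmap = tmap.gmap
    chrom_arr = gmap.table["chrom"].to_numpy()
    per_chrom: dict = {c: [0, 0] for c in gmap.chroms}
    compared = concordant = 0
    idx = np.arange(gmap.n_markers)
    for oid in shared:
        fam = ped.loc[oid, "family_id"]
        rec = tmap.records[oid]
        for role in ("mother", "father"):
            pid, genotyped = fam_parent[(fam, role)]
            if not genotyped:
                continue
            inferred_nt = rec.nontransmitted[role]
            src_true = truth.source[oid][role]
            truth_nt = haps.haps[pid][2 - src_true, idx]
            ok = inferred_nt >= 0
            match = (inferred_nt == truth_nt) & ok
            compared += int(ok.sum())
            concordant += int(match.sum())
            for c in gmap.chroms:
                m = chrom_arr == c
                per_chrom[c][0] += int((ok & m).sum())
                per_chrom[c][1] += int((match & m).sum())
    table = pd.DataFrame(
        [
            (c, v[0], v[1], v[1] / v[0] if v[0] else np.nan)
            for c, v in per_chrom.items()
        ],
        columns=["chrom", "compared", "concordant", "rate"],
    )
    return ConcordanceReport(compared, concordant, table)
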
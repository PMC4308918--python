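"""Candidate novel-miRNA catalog processing.

Per-library discovery tools emit candidate hairpin arms with slightly jittered
genomic coordinates.  This module merges candidates across libraries treating
coordinates within +/- 2 bp as equivalent (transitive closure), filters the
merged catalog against annotation tracks of other small-RNA species (snoRNA,
tRNA, ...), and assigns systematic NOVEL[M/S]XXXXX names.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from intervaltree import IntervalTree

CHROM_RE = re.compile(r"^(chr)?([0-9]{1,2}|[XYM]|MT)$")


@dataclass(frozen=True)
class CandidateInterval:
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    arm: str  # 'mature' or 'star'
    source_sample: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.arm not in ("mature", "star"):
            raise ValueError(f"bad arm {self.arm!r}")


@dataclass
class NovelMiRNA:
    interval: CandidateInterval
    support: set = field(default_factory=set)
    name: str = ""
    blacklist_overlaps: set = field(default_factory=set)
    retained: bool = True


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _check_chrom_naming(intervals) -> None:
    prefixed = {iv.chrom for iv in intervals if iv.chrom.startswith("chr")}
    bare = {iv.chrom for iv in intervals if not iv.chrom.startswith("chr")}
    if prefixed and bare:
        raise ValueError(
            "inconsistent chromosome naming (mixed 'chr' prefix): "
            f"{sorted(prefixed)[:3]} vs {sorted(bare)[:3]}"
        )


def merge_candidates(per_sample: dict[str, list[CandidateInterval]], tol: int = 2) -> list[NovelMiRNA]:
    """Merge candidates across libraries, treating two intervals as duplicates
    when chrom, strand and arm match and both |start diff| and |end diff|
    are <= tol.  Merging is the transitive closure of this pairwise relation.

    The representative interval of a merged group is its modal coordinate
    pair (ties broken by smallest start, then smallest end); support records
    the contributing sample ids.  Output is sorted by
    (chrom, start, end, strand).
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    flat: list[CandidateInterval] = []
    for sample, ivs in per_sample.items():
        for iv in ivs:
            if iv.source_sample != sample:
                iv = CandidateInterval(iv.chrom, iv.start, iv.end, iv.strand, iv.arm, sample)
            flat.append(iv)
    _check_chrom_naming(flat)

    # group by (chrom, strand, arm); within a group, only pairs whose starts
    # are within tol can be equivalent, so a sort by start bounds the scan
    keys = sorted(range(len(flat)), key=lambda i: (flat[i].chrom, flat[i].strand, flat[i].arm, flat[i].start, flat[i].end))
    uf = _UnionFind(len(flat))
    for pos, i in enumerate(keys):
        a = flat[i]
        for j in keys[pos + 1 :]:
            b = flat[j]
            if (b.chrom, b.strand, b.arm) != (a.chrom, a.strand, a.arm) or b.start - a.start > tol:
                break
            if abs(b.end - a.end) <= tol:
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(flat)):
        groups.setdefault(uf.find(i), []).append(i)

    out: list[NovelMiRNA] = []
    for members in groups.values():
        coords: dict[tuple[int, int], int] = {}
        for i in members:
            key = (flat[i].start, flat[i].end)
            coords[key] = coords.get(key, 0) + 1
        rep_start, rep_end = min(coords, key=lambda c: (-coords[c], c[0], c[1]))
        proto = flat[members[0]]
        rep = CandidateInterval(proto.chrom, rep_start, rep_end, proto.strand, proto.arm, "")
        out.append(NovelMiRNA(interval=rep, support={flat[i].source_sample for i in members}))
    out.sort(key=lambda n: (n.interval.chrom, n.interval.start, n.interval.end, n.interval.strand))
    return out


def filter_rna_species(
    catalog: list[NovelMiRNA],
    blacklist: dict[str, list[tuple[str, int, int, str]]],
    allowlist: set[str] | None = None,
    stranded: bool = False,
) -> list[NovelMiRNA]:
    """Flag catalog entries overlapping (>= 1 bp) other-RNA-species tracks.

    ``blacklist`` maps a species label (e.g. 'tRNA', 'snoRNA') to a list of
    (chrom, start, end, strand) intervals.  Overlapping candidates get
    ``retained=False`` with the species label recorded, unless their name is
    in ``allowlist`` — then they stay retained but keep the annotation.
    """
    allowlist = allowlist or set()
    trees: dict[str, dict[tuple, IntervalTree]] = {}
    for label, ivs in blacklist.items():
        for chrom, start, end, strand in ivs:
            if start >= end:
                raise ValueError(f"malformed blacklist interval {chrom}:{start}-{end} in track {label}")
            key = (chrom, strand) if stranded else (chrom,)
            trees.setdefault(label, {}).setdefault(key, IntervalTree()).addi(start, end)
    for entry in catalog:
        iv = entry.interval
        key = (iv.chrom, iv.strand) if stranded else (iv.chrom,)
        hits = {
            label
            for label, by_key in trees.items()
            if key in by_key and by_key[key].overlap(iv.start, iv.end)
        }
        entry.blacklist_overlaps = hits
        entry.retained = not hits or entry.name in allowlist
    return catalog


def assign_names(catalog: list[NovelMiRNA], start_index: int = 1, trailing_arm: bool = True) -> list[NovelMiRNA]:
    """Assign NOVEL[M|S]XXXXX names (zero-padded 5-digit index, consecutive in
    catalog order).  With ``trailing_arm`` the arm letter is repeated as a
    suffix (the dialect seen in published identifiers, e.g. NOVELM00203M)."""
    idx = start_index
    for entry in catalog:
        if idx > 99999:
            raise ValueError("name index overflow past 99999")
        letter = "M" if entry.interval.arm == "mature" else "S"
        entry.name = f"NOVEL{letter}{idx:05d}" + (letter if trailing_arm else "")
        idx += 1
    return catalog


def read_bed(path) -> list[tuple[str, int, int, str, str, str]]:
    """Read BED6 rows as (chrom, start, end, name, score, strand)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: {line!r}") from exc
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "0"
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append((parts[0], start, end, name, score, strand))
    return rows


def write_catalog_bed(catalog: list[NovelMiRNA], path) -> None:
    """Write the catalog as BED6: name = assigned name, score = support size."""
    with open(path, "w") as fh:
        for entry in catalog:
            iv = entry.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{entry.name or '.'}\t{len(entry.support)}\t{iv.strand}\n"
            )


def read_candidates_bed(path, sample: str, arm_field: bool = True) -> list[CandidateInterval]:
    """Read one library's candidate BED; the name column encodes the arm
    ('mature' or 'star')."""
    out = []
    for chrom, start, end, name, _score, strand in read_bed(path):
        arm = name if name in ("mature", "star") else "mature"
        out.append(CandidateInterval(chrom, start, end, strand, arm, sample))
    return out
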
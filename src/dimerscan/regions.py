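"""Region-set handling: BED I/O, replicate merging, target/control construction.

Coordinates are BED-style 0-based half-open throughout.  Input region sets
are declared *strong* (strongly cell-type-specific, e.g. DNase-seq open
chromatin: reduced to the portions unique to each cell type before testing)
or *weak* (e.g. ChIP-seq peaks: used as-is).  The control dataset is the
union of all input regions and defines the empirical background universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int]


class BedError(ValueError):
    """Record-level BED problem, carrying the offending line number."""


def _merge(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping or bookended intervals."""
    out: list[Interval] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            if end > prev[2]:
                out[-1] = (chrom, prev[1], end)
        else:
            out.append((chrom, start, end))
    return out


def _subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Base-pair subtraction a \\ b; both inputs must be normalized."""
    out: list[Interval] = []
    by_chrom: dict[str, list[Interval]] = {}
    for iv in b:
        by_chrom.setdefault(iv[0], []).append(iv)
    for chrom, start, end in a:
        cur = start
        for _, bs, be in by_chrom.get(chrom, ()):
            if be <= cur or bs >= end:
                continue
            if bs > cur:
                out.append((chrom, cur, min(bs, end)))
            cur = max(cur, be)
            if cur >= end:
                break
        if cur < end:
            out.append((chrom, cur, end))
    return out


@dataclass
class RegionSet:
    """A named, normalized set of genomic intervals."""

    name: str
    kind: str = "derived"  # strong | weak | derived
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("strong", "weak", "derived"):
            raise ValueError(f"unknown region-set kind {self.kind!r}")
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(
                    f"region set {self.name!r}: zero-length or inverted interval "
                    f"{chrom}:{start}-{end}")
        self.intervals = _merge(self.intervals)

    @property
    def total_bp(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def subtract(self, other: "RegionSet", name: str | None = None) -> "RegionSet":
        return RegionSet(name or self.name, self.kind,
                         _subtract(self.intervals, other.intervals))

    def clipped(self, chrom_sizes: dict[str, int]) -> "RegionSet":
        """Clip intervals to chromosome ends; drop those on absent chromosomes."""
        kept: list[Interval] = []
        for chrom, start, end in self.intervals:
            if chrom not in chrom_sizes:
                raise BedError(f"region set {self.name!r}: chromosome {chrom!r} "
                               "absent from genome")
            size = chrom_sizes[chrom]
            if start >= size:
                logger.warning("%s: interval %s:%d-%d beyond chromosome end, dropped",
                               self.name, chrom, start, end)
                continue
            if end > size:
                logger.warning("%s: interval %s:%d-%d clipped to chromosome end %d",
                               self.name, chrom, start, end, size)
                end = size
            kept.append((chrom, start, end))
        return RegionSet(self.name, self.kind, kept)


@dataclass
class DatasetBundle:
    """Target region sets plus the control (union-of-inputs) set."""

    targets: list[RegionSet]
    control: RegionSet


def read_bed(path: str, name: str | None = None, kind: str = "derived") -> RegionSet:
    """Read a BED3+ file into a normalized RegionSet; extra columns ignored."""
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise BedError(f"{path}:{lineno}: zero-length interval "
                               f"{chrom}:{start}-{end}")
            intervals.append((chrom, start, end))
    if not intervals:
        logger.warning("BED file %s contains no intervals", path)
    return RegionSet(name or path, kind, intervals)


def write_bed(rs: RegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in rs.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def merge_replicates(sets: list[RegionSet], name: str) -> RegionSet:
    """Union of replicate region sets for one cell type."""
    if not sets:
        raise ValueError("merge_replicates requires at least one region set")
    intervals = [iv for rs in sets for iv in rs.intervals]
    return RegionSet(name, sets[0].kind, intervals)


def build_targets(strong: list[RegionSet], weak: list[RegionSet]) -> DatasetBundle:
    """Derive target datasets and the control from declared inputs.

    Each strong set is reduced to the base pairs not covered by any *other*
    strong set (its cell-type-unique portion); weak sets pass through
    unchanged.  The control is the union of all input regions, taken before
    any subtraction.
    """
    control_intervals = [iv for rs in (*strong, *weak) for iv in rs.intervals]
    control = RegionSet("control", "derived", control_intervals)
    targets: list[RegionSet] = []
    for i, rs in enumerate(strong):
        others = [iv for j, other in enumerate(strong) if j != i
                  for iv in other.intervals]
        unique = _subtract(rs.intervals, _merge(others))
        if not unique:
            logger.warning("strong dataset %s has no cell-type-unique regions", rs.name)
        targets.append(RegionSet(rs.name, "strong", unique))
    targets.extend(RegionSet(rs.name, "weak", list(rs.intervals)) for rs in weak)
    return DatasetBundle(targets=targets, control=control)
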
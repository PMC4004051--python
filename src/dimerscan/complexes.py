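"""Motif complexes: canonical forms, enumeration, and instance detection.

A motif complex is an ordered pair of motifs on given strands at a fixed
spacing, where spacing is the number of intervening base pairs between the
proximal edges of the two motifs (negative spacing means overlap).  A
complex and its reverse complement describe the same double-stranded object,
so each is stored in a canonical form: the lexicographically smaller of the
two equivalent (left_id, right_id, left_strand, right_strand, spacing)
tuples.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

_FLIP = {"+": "-", "-": "+"}


@dataclass(frozen=True, order=True)
class MotifComplex:
    """An ordered motif pair with strands and spacing (canonical or not)."""

    left_id: str
    right_id: str
    left_strand: str
    right_strand: str
    spacing: int

    def astuple(self) -> tuple:
        return (self.left_id, self.right_id, self.left_strand,
                self.right_strand, self.spacing)

    def reverse_complement(self) -> "MotifComplex":
        return MotifComplex(self.right_id, self.left_id,
                            _FLIP[self.right_strand], _FLIP[self.left_strand],
                            self.spacing)

    @property
    def is_self_rc(self) -> bool:
        """True for palindromic arrangements equal to their reverse complement."""
        return self.astuple() == self.reverse_complement().astuple()

    def span(self, lengths: Mapping[str, int]) -> int:
        """Total genomic footprint: L_left + L_right + spacing."""
        return lengths[self.left_id] + lengths[self.right_id] + self.spacing

    @property
    def signature(self) -> str:
        return (f"{self.left_id}({self.left_strand})/"
                f"{self.right_id}({self.right_strand})/s={self.spacing}")

    @property
    def orientation_key(self) -> tuple:
        """Pair + orientation + left-right ordering, ignoring spacing."""
        return (self.left_id, self.right_id, self.left_strand, self.right_strand)


def canonicalize(c: MotifComplex) -> MotifComplex:
    """Return the canonical representative of {c, reverse_complement(c)}."""
    rc = c.reverse_complement()
    return c if c.astuple() <= rc.astuple() else rc


def default_min_spacing(len1: int, len2: int) -> int:
    """Largest allowed overlap: one bp short of covering the shorter motif."""
    return -(min(len1, len2) - 1)


def enumerate_complexes(motif1_id: str, motif2_id: str,
                        min_spacing: int, max_spacing: int) -> list[MotifComplex]:
    """All distinct canonical complexes of a pair over a spacing window.

    For distinct motifs there are exactly 4 orientation classes per spacing;
    for a homodimer exactly 3 (direct repeat, convergent, divergent).
    """
    if max_spacing < min_spacing:
        raise ValueError("max_spacing must be >= min_spacing")
    out: set[MotifComplex] = set()
    for s in range(min_spacing, max_spacing + 1):
        for ls in "+-":
            for rs in "+-":
                out.add(canonicalize(MotifComplex(motif1_id, motif2_id, ls, rs, s)))
                if motif1_id != motif2_id:
                    out.add(canonicalize(MotifComplex(motif2_id, motif1_id, ls, rs, s)))
    return sorted(out)


def reported_spacing(c: MotifComplex, trim_left, trim_right) -> int | None:
    """Spacing between the proximal edges of the *trimmed* motifs.

    ``trim_left``/``trim_right`` are :class:`~dimerscan.motifs.TrimmedView`
    objects for the complex's left and right motif.  The proximal flank of
    the left motif is its 3' end when on '+' (so its right trim applies) and
    its 5' end when on '-'; symmetrically for the right motif.  Returns
    ``None`` when either motif trims to zero length.
    """
    if trim_left.trimmed_length == 0 or trim_right.trimmed_length == 0:
        return None
    t1 = trim_left.right_offset if c.left_strand == "+" else trim_left.left_offset
    t2 = trim_right.left_offset if c.right_strand == "+" else trim_right.right_offset
    return c.spacing + t1 + t2


class ComplexInstance(NamedTuple):
    """A genomic occurrence of a canonical complex.

    ``arrangement_strand`` is '+' when the canonical left-to-right reading is
    realized on the forward genomic strand, '-' when on the reverse.
    """

    chrom: str
    span_start: int
    span_end: int
    arrangement_strand: str


class Hit(NamedTuple):
    """A motif match inside one region (coordinates are genomic)."""

    start: int
    end: int
    strand: str
    score: float


def pair_instances(
    hits1: Mapping[tuple, Sequence[Hit]],
    hits2: Mapping[tuple, Sequence[Hit]],
    motif1_id: str,
    motif2_id: str,
    min_spacing: int,
    max_spacing: int,
) -> dict[MotifComplex, list[ComplexInstance]]:
    """Detect all instances of every canonical complex of a motif pair.

    ``hits1``/``hits2`` map region keys to hit lists sorted by start (as
    produced by the scanner).  Both hits of an instance must lie in the same
    region.  Placements sharing the identical genomic span and canonical
    complex are counted once.
    """
    same = motif1_id == motif2_id
    out: dict[MotifComplex, dict[tuple, ComplexInstance]] = {}

    def emit(first: Hit, second: Hit, first_id: str, second_id: str, chrom: str) -> None:
        s = second.start - first.end
        if s < min_spacing or s > max_spacing:
            return
        arr = MotifComplex(first_id, second_id, first.strand, second.strand, s)
        canon = canonicalize(arr)
        strand = "+" if arr.astuple() == canon.astuple() else "-"
        inst = ComplexInstance(chrom, first.start, second.end, strand)
        key = (chrom, first.start, second.end)
        bucket = out.setdefault(canon, {})
        if key not in bucket:
            bucket[key] = inst

    for region, lst1 in hits1.items():
        lst2 = hits2.get(region)
        if not lst2:
            continue
        chrom = region[0]
        starts2 = [h.start for h in lst2]
        for h1 in lst1:
            # second hit must start within the spacing window of h1's end
            lo = bisect_left(starts2, h1.end + min_spacing)
            hi = bisect_right(starts2, h1.end + max_spacing)
            for h2 in lst2[lo:hi]:
                if same and h1 == h2:
                    continue
                emit(h1, h2, motif1_id, motif2_id, chrom)
            if not same:
                # arrangements with motif2 leftmost
                len2 = lst2[0].end - lst2[0].start
                lo = bisect_left(starts2, h1.start - max_spacing - len2)
                hi = bisect_right(starts2, h1.start - min_spacing - len2)
                for h2 in lst2[lo:hi]:
                    emit(h2, h1, motif2_id, motif1_id, chrom)
    return {c: sorted(d.values()) for c, d in sorted(out.items())}
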
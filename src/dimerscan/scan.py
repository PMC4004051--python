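"""Motif scanning over region sets at calibrated log-odds thresholds.

Every window on either strand whose log-odds score reaches the motif's
calibrated threshold is reported as a hit.  Hits are confined to lie fully
inside a region (regions define the statistical universe for the enrichment
test), and ambiguous bases (N) contribute a log-odds of zero.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from pyfaidx import Fasta

from .complexes import Hit
from .motifs import Motif, ScoreThreshold
from .regions import RegionSet

_CODE = np.full(256, 4, dtype=np.int8)  # everything unknown -> 4 (N slot)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_RC_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)


class Genome:
    """Case-insensitive random access to an indexed FASTA file."""

    def __init__(self, path: str):
        self.path = path
        self._fasta = Fasta(path, sequence_always_upper=True, as_raw=True)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(rec) for name, rec in self._fasta.records.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self._fasta[chrom][start:end])

    def fetch_codes(self, chrom: str, start: int, end: int) -> np.ndarray:
        seq = self.fetch(chrom, start, end)
        return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def background_frequencies(genome: Genome, rs: RegionSet) -> np.ndarray:
    """Strand-averaged 0-order A,C,G,T frequencies of the region set (N ignored).

    Frequencies are averaged with their complement (A with T, C with G):
    scanning is double-stranded, so the background must score both strands of
    a site consistently, which also makes results invariant under
    reverse-complementing the genome.
    """
    counts = np.zeros(4)
    for chrom, start, end in rs.intervals:
        codes = genome.fetch_codes(chrom, start, end)
        counts += np.bincount(codes[codes < 4], minlength=4)[:4]
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    freqs = counts / total
    return (freqs + freqs[::-1]) / 2.0


def _score_matrix(m: Motif, background: np.ndarray) -> np.ndarray:
    """5 x L log-odds matrix; row 4 (N) scores zero."""
    lom = m.log_odds(background)
    return np.vstack([lom, np.zeros(m.length)])


def _window_scores(codes: np.ndarray, smat: np.ndarray) -> np.ndarray:
    L = smat.shape[1]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(L):
        scores += smat[codes[j: j + n], j]
    return scores


def scan(
    genome: Genome,
    rs: RegionSet,
    motifs: Sequence[Motif],
    thresholds: Mapping[str, ScoreThreshold],
    background: np.ndarray | None = None,
) -> dict[str, dict[tuple, list[Hit]]]:
    """Scan every motif over every region on both strands.

    Returns ``hits[motif_id][region_key]`` = list of :class:`Hit` in
    deterministic (start, strand) order, where ``region_key`` is the
    ``(chrom, start, end)`` tuple of the region.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    smats = {}
    for m in motifs:
        fwd = _score_matrix(m, bg)
        rev = _score_matrix(m.reverse_complement(), bg)
        smats[m.id] = (fwd, rev, m.length)
    out: dict[str, dict[tuple, list[Hit]]] = {m.id: {} for m in motifs}
    for region in rs.intervals:
        chrom, start, end = region
        codes = genome.fetch_codes(chrom, start, end)
        for m in motifs:
            fwd, rev, L = smats[m.id]
            thr = thresholds[m.id].threshold
            hits: list[Hit] = []
            sf = _window_scores(codes, fwd)
            sr = _window_scores(codes, rev)
            if sf.size:
                for pos in np.flatnonzero(sf >= thr):
                    hits.append(Hit(start + int(pos), start + int(pos) + L, "+",
                                    float(sf[pos])))
                for pos in np.flatnonzero(sr >= thr):
                    hits.append(Hit(start + int(pos), start + int(pos) + L, "-",
                                    float(sr[pos])))
            if hits:
                hits.sort(key=lambda h: (h.start, h.strand))
                out[m.id][region] = hits
    return out


def hits_to_bed(hits: Mapping[str, Mapping[tuple, Sequence[Hit]]], path: str) -> None:
    """Dump hits as BED6 (name = motif id, score = bits x 100, rounded)."""
    rows = []
    for motif_id, per_region in hits.items():
        for (chrom, _, _), lst in per_region.items():
            for h in lst:
                rows.append((chrom, h.start, h.end, motif_id,
                             int(round(h.score * 100)), h.strand))
    rows.sort()
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
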
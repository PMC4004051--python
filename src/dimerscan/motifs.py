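"""Motif representation, format I/O, information content, trimming, thresholds.

A motif is a nucleotide count matrix (4 rows in A, C, G, T order, one column
per position).  Probabilities are derived from counts with a symmetric
pseudocount so that log-odds scores are always finite.  Match-score
thresholds are calibrated per motif from the exact distribution of the
log-odds score of sequences drawn from the motif's own probability model:
the threshold is the largest score whose upper-tail mass still reaches the
requested sensitivity (0.8 by default).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: complement permutation of the A,C,G,T rows
_COMPLEMENT = np.array([3, 2, 1, 0])

#: per-base pseudocount added to each count before normalisation
DEFAULT_PSEUDOCOUNT = 0.25
#: score discretisation bin width (bits) for the threshold dynamic program
SCORE_BIN_WIDTH = 0.01

UNIFORM_BACKGROUND = np.full(4, 0.25)


class MotifParseError(ValueError):
    """Raised when a motif record cannot be parsed; names the record."""


@dataclass
class Motif:
    """A nucleotide count matrix with identity.

    Parameters
    ----------
    id : str
        Unique identifier (accession or name).
    counts : ndarray of shape (4, L)
        Nonnegative base counts, rows in A, C, G, T order.
    name : str
        Human-readable name; defaults to ``id``.
    source_format : str
        One of ``TRANSFAC``, ``JASPAR``, ``SwissRegulon``, ``MEME`` or
        ``synthetic``.
    pseudocount : float
        Per-base pseudocount used when deriving probabilities.
    """

    id: str
    counts: np.ndarray
    name: str = ""
    source_format: str = "synthetic"
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"motif {self.id!r}: counts must be a 4 x L matrix")
        if self.counts.shape[1] < 1:
            raise ValueError(f"motif {self.id!r}: length must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError(f"motif {self.id!r}: negative counts")
        if not self.name:
            self.name = self.id

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def probs(self) -> np.ndarray:
        """Column-stochastic probability matrix with pseudocounts."""
        pc = self.pseudocount
        col_sums = self.counts.sum(axis=0)
        return (self.counts + pc) / (col_sums + 4 * pc)

    def reverse_complement(self) -> "Motif":
        rc = self.counts[_COMPLEMENT][:, ::-1]
        return Motif(self.id, rc, name=self.name,
                     source_format=self.source_format, pseudocount=self.pseudocount)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=0))

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """Per-position log2 odds matrix against a 0-order background."""
        bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
        return np.log2(self.probs / bg[:, None])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Motif({self.id!r}, L={self.length})"


@dataclass(frozen=True)
class TrimmedView:
    """Offsets of low-information flanking columns dropped from a motif."""

    motif_id: str
    left_offset: int
    right_offset: int
    trimmed_length: int


@dataclass(frozen=True)
class ScoreThreshold:
    """A calibrated log-odds cutoff for one motif."""

    motif_id: str
    sensitivity: float
    threshold: float


def information_content(m: Motif) -> tuple[np.ndarray, float]:
    """Per-column and total information content in bits.

    The per-column IC is ``2 + sum_b p(b) log2 p(b)`` with ``0 log 0 := 0``;
    it lies in [0, 2] and is invariant under reverse complement.
    """
    p = m.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    col_ic = 2.0 + plogp.sum(axis=0)
    col_ic = np.clip(col_ic, 0.0, 2.0)
    return col_ic, float(col_ic.sum())


def trim_motif(m: Motif, ic_cutoff: float = 0.25) -> TrimmedView:
    """Drop flanking columns whose IC is at or below ``ic_cutoff`` bits.

    Columns are removed repeatedly from the outside in; interior low-IC
    columns are retained.  A motif whose every column is uninformative trims
    to length 0 (callers doing spacing analysis must skip such motifs).
    """
    col_ic, _ = information_content(m)
    left = 0
    right = 0
    n = m.length
    while left < n and col_ic[left] <= ic_cutoff:
        left += 1
    while right < n - left and col_ic[n - 1 - right] <= ic_cutoff:
        right += 1
    trimmed = n - left - right
    if trimmed == 0:
        logger.warning("motif %s trimmed to zero length (all columns IC <= %.3g bit)",
                       m.id, ic_cutoff)
        left, right = n, 0
    return TrimmedView(m.id, left, right, trimmed)


def calibrate_threshold(
    m: Motif,
    sensitivity: float = 0.8,
    background: np.ndarray | None = None,
    bin_width: float = SCORE_BIN_WIDTH,
) -> ScoreThreshold:
    """Calibrate the log-odds score cutoff reaching a target sensitivity.

    The exact distribution of the log-odds score of sequences drawn from the
    motif's own probability model is computed by dynamic programming over
    columns, with per-column scores discretised by flooring to ``bin_width``
    bits.  The returned threshold is the largest discretised score whose
    upper-tail mass is at least ``sensitivity``; flooring guarantees the
    realised sensitivity never falls below the target (it may exceed it by
    the mass of one score class plus up to L * bin_width of slack).
    """
    if not 0 < sensitivity <= 1:
        raise ValueError("sensitivity must lie in (0, 1]")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    probs = m.probs
    with np.errstate(divide="ignore"):
        lom = np.log2(probs / bg[:, None])
    # bases with zero probability are never drawn; keep their bins finite
    lom = np.where(probs > 0, lom, 0.0)
    # floor, not round: the discretised score never exceeds the true score,
    # so the upper-tail mass at the returned threshold is a lower bound and
    # the realised sensitivity cannot fall below the target
    idx = np.floor(lom / bin_width).astype(np.int64)

    # DP over columns: dist[i] = P(cumulative score bin == base + i)
    dist = np.array([1.0])
    base = 0
    for j in range(m.length):
        shifts = [(int(idx[b, j]), probs[b, j]) for b in range(4) if probs[b, j] > 0]
        smin = min(sh for sh, _ in shifts)
        smax = max(sh for sh, _ in shifts)
        new = np.zeros(dist.size + smax - smin)
        for sh, p in shifts:
            new[sh - smin: sh - smin + dist.size] += p * dist
        dist = new
        base += smin
    scores = (base + np.arange(dist.size)) * bin_width
    nz = dist > 0
    scores = scores[nz]
    masses = dist[nz]
    # upper-tail mass, scanning from the top score down
    order = np.argsort(scores)[::-1]
    tail = np.cumsum(masses[order])
    k = int(np.searchsorted(tail, sensitivity - 1e-12))
    k = min(k, len(order) - 1)
    thr = float(scores[order][k])
    return ScoreThreshold(m.id, sensitivity, thr)


# ---------------------------------------------------------------------------
# format readers / writer
# ---------------------------------------------------------------------------

_FORMATS = ("TRANSFAC", "JASPAR", "SwissRegulon", "MEME")


def parse_motifs(path: str, fmt: str, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[Motif]:
    """Parse a motif library file.

    ``fmt`` is one of ``TRANSFAC``, ``JASPAR``, ``SwissRegulon`` (accepted as
    TRANSFAC-like count blocks) or ``MEME`` (plain-text output with
    letter-probability matrices).  Record order is preserved.
    """
    key = fmt.strip().lower()
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        logger.warning("motif file %s is empty", path)
        return []
    if key in ("transfac", "swissregulon"):
        fmt_name = "TRANSFAC" if key == "transfac" else "SwissRegulon"
        return _parse_transfac_like(text, fmt_name, pseudocount)
    if key == "jaspar":
        return _parse_jaspar(text, pseudocount)
    if key == "meme":
        return _parse_meme(text, pseudocount)
    raise ValueError(f"unknown motif format {fmt!r}; expected one of {_FORMATS}")


_NUM = r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?"


def _parse_transfac_like(text: str, fmt_name: str, pseudocount: float) -> list[Motif]:
    motifs: list[Motif] = []
    rec_id = None
    rec_name = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rec_id, rec_name, rows
        if rows:
            mid = rec_id or rec_name or f"motif_{len(motifs) + 1}"
            counts = np.array(rows, dtype=float).T  # rows are positions -> (4, L)
            motifs.append(Motif(mid, counts, name=rec_name or mid,
                                source_format=fmt_name, pseudocount=pseudocount))
        rec_id = rec_name = None
        rows = []

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        tag = line.split(None, 1)[0]
        if line.startswith("//"):
            flush()
        elif tag in ("AC", "ID"):
            val = line[2:].strip()
            if rec_id is None and val:
                rec_id = val
        elif tag == "NA":
            rec_name = line[2:].strip() or rec_name
        elif tag in ("P0", "PO"):
            continue  # column header
        elif re.fullmatch(r"\d+", tag):
            fields = line.split()
            nums = [f for f in fields[1:] if re.fullmatch(_NUM, f)]
            if len(nums) < 4:
                raise MotifParseError(
                    f"record {rec_id or rec_name or '?'}: matrix row at line {lineno} "
                    f"has {len(nums)} numeric columns, expected 4")
            rows.append([float(x) for x in nums[:4]])
        # other tags (XX, BF, CC, ...) are ignored
    flush()
    return motifs


def _parse_jaspar(text: str, pseudocount: float) -> list[Motif]:
    motifs: list[Motif] = []
    header = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal header, rows
        if header is None and not rows:
            return
        if len(rows) != 4:
            raise MotifParseError(
                f"record {header or '?'}: expected 4 base rows, found {len(rows)}")
        parts = header.split(None, 1) if header else ["?"]
        mid = parts[0]
        name = parts[1].strip() if len(parts) > 1 else mid
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise MotifParseError(f"record {mid}: base rows have unequal lengths {sorted(lengths)}")
        motifs.append(Motif(mid, np.array(rows, float), name=name,
                            source_format="JASPAR", pseudocount=pseudocount))
        header = None
        rows = []

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
        else:
            body = line
            mm = re.match(r"^([ACGTacgt])\s*[\[|]?\s*(.*?)\s*\]?\s*$", body)
            if mm:
                body = mm.group(2)
            body = body.replace("[", " ").replace("]", " ")
            nums = [float(x) for x in body.split()]
            if nums:
                rows.append(nums)
    flush()
    return motifs


def _parse_meme(text: str, pseudocount: float) -> list[Motif]:
    motifs: list[Motif] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            fields = line.split()
            mid = fields[1] if len(fields) > 1 else f"motif_{len(motifs) + 1}"
            name = fields[2] if len(fields) > 2 else mid
            nsites = 20.0
            width = None
            # seek the letter-probability matrix header
            j = i + 1
            while j < len(lines) and "letter-probability matrix" not in lines[j]:
                if lines[j].strip().startswith("MOTIF"):
                    break
                j += 1
            if j >= len(lines) or "letter-probability matrix" not in lines[j]:
                raise MotifParseError(f"record {mid}: no letter-probability matrix found")
            hdr = lines[j]
            mw = re.search(r"w=\s*(\d+)", hdr)
            mn = re.search(r"nsites=\s*(\d+)", hdr)
            if mw:
                width = int(mw.group(1))
            if mn:
                nsites = float(mn.group(1))
            rows = []
            j += 1
            while j < len(lines):
                vals = lines[j].split()
                if len(vals) >= 4 and all(re.fullmatch(_NUM, v) for v in vals[:4]):
                    rows.append([float(v) for v in vals[:4]])
                    j += 1
                    if width is not None and len(rows) == width:
                        break
                elif not lines[j].strip():
                    j += 1
                    if rows:
                        break
                else:
                    break
            if width is not None and len(rows) != width:
                raise MotifParseError(
                    f"record {mid}: expected {width} matrix rows, found {len(rows)}")
            probs = np.array(rows, float).T  # (4, L)
            counts = probs * nsites
            motifs.append(Motif(mid, counts, name=name, source_format="MEME",
                                pseudocount=pseudocount))
            i = j
        else:
            i += 1
    return motifs


def write_transfac(motifs: list[Motif], path: str) -> None:
    """Write motifs as TRANSFAC-style count blocks (round-trips with the reader)."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f"AC {m.id}\nXX\nNA {m.name}\nXX\nP0 A C G T\n")
            for j in range(m.length):
                vals = " ".join(_fmt_num(m.counts[b, j]) for b in range(4))
                fh.write(f"{j + 1:02d} {vals}\n")
            fh.write("XX\n//\n")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))
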
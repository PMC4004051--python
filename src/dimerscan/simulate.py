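"""Synthetic fixtures with planted dimers, and the dimer-detection benchmark.

The generator emulates the inputs of a regulatory-region dimer screen: a
genome of background sequence (i.i.d. or first-order Markov), region sets
tiled without overlap (one BED per dataset), and, per plant specification, a
deterministic number of dimer instances --- sequences sampled from the two
motifs' probability models placed at the specified orientation and spacing
at uniformly chosen in-region offsets, on a uniformly chosen genomic strand.
Everything is reproducible from the seed, and every planted instance is
recorded in a truth table.

The benchmark mirrors a sensitivity/false-positive protocol over a gold
standard of known dimeric motif pairs versus random pairs: each pair is
scored by the best enrichment p-value over all its complexes and datasets,
and an ROC curve plus AUC is computed across p-value thresholds.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .complexes import MotifComplex, canonicalize
from .motifs import BASES, Motif

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PlantSpec:
    """One planted complex: which, where, and how often."""

    complex: MotifComplex
    target_name: str
    plant_rate: float

    def __post_init__(self) -> None:
        if not 0 <= self.plant_rate <= 1:
            raise ValueError("plant_rate must lie in [0, 1]")


@dataclass(frozen=True)
class BackgroundPairSpec:
    """Baseline co-occurrence of a motif pair at random structures.

    Instances are planted in every dataset at ``rate`` (fraction of regions),
    each with an orientation and spacing drawn uniformly from the screened
    window.  This emulates the genome-wide baseline of motif pairs that the
    pair-level correction of the enrichment model normalises against.
    """

    motif1_id: str
    motif2_id: str
    rate: float
    min_spacing: int = 0
    max_spacing: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.rate <= 1:
            raise ValueError("rate must lie in [0, 1]")


@dataclass
class Fixture:
    fasta: str
    beds: dict[str, str]
    truth: pd.DataFrame
    datasets: list[str] = field(default_factory=list)


def random_motif(rng: np.random.Generator, length: int, strength: float = 0.85,
                 motif_id: str = "M", total: float = 100.0) -> Motif:
    """A synthetic motif: at each column one random base carries ``strength``
    of the probability mass, the rest is spread uniformly."""
    consensus = rng.integers(0, 4, size=length)
    probs = np.full((4, length), (1 - strength) / 3)
    probs[consensus, np.arange(length)] = strength
    return Motif(motif_id, probs * total, source_format="synthetic")


def shifted_motif(m: Motif, motif_id: str) -> Motif:
    """The same motif shifted one column left: columns 2..L plus a uniform
    trailing column.  Its matches sit 1 bp right of the parent's matches,
    which makes it a controlled source of shadow predictions."""
    L = m.length
    counts = np.zeros((4, L))
    counts[:, : L - 1] = m.counts[:, 1:]
    counts[:, L - 1] = m.counts[:, L - 1].sum() / 4.0
    return Motif(motif_id, counts, source_format="synthetic")


def _oriented_probs(m: Motif, strand: str) -> np.ndarray:
    return m.probs if strand == "+" else m.reverse_complement().probs


def composite_site_probs(m_left: Motif, m_right: Motif, c: MotifComplex,
                         background: np.ndarray) -> np.ndarray:
    """Per-position base probabilities of one planted composite site.

    The left motif occupies span positions [0, L1), the right motif
    [L1 + s, L1 + s + L2), both in their arrangement orientation; intervening
    positions follow the background.  Where the motifs overlap (negative
    spacing) the column distribution is the normalised product of the two
    motif columns, the maximum-likelihood model of a shared composite core.
    """
    L1, L2 = m_left.length, m_right.length
    span = L1 + L2 + c.spacing
    if span <= 0:
        raise ValueError(f"complex {c.signature} has non-positive span")
    probs = np.tile(background[:, None], (1, span)).astype(float)
    left = _oriented_probs(m_left, c.left_strand)
    right = _oriented_probs(m_right, c.right_strand)
    probs[:, :L1] = left
    r0 = L1 + c.spacing
    for j in range(L2):
        col = right[:, j]
        if r0 + j < L1:  # overlap with the left motif
            col = probs[:, r0 + j] * col
            col = col / col.sum()
        probs[:, r0 + j] = col
    return probs


def generate_fixture(
    out_dir: str,
    motifs: dict[str, Motif],
    datasets: list[str],
    n_regions: int,
    region_length: int,
    plants: list[PlantSpec],
    seed: int,
    background_pairs: list[BackgroundPairSpec] = (),
    background: np.ndarray | None = None,
    markov: np.ndarray | None = None,
    gap: int = 10,
    chrom: str = "chr1",
) -> Fixture:
    """Write a synthetic genome (FASTA) plus one BED per dataset.

    Each dataset gets ``n_regions`` non-overlapping regions of
    ``region_length`` bp, tiled consecutively on one chromosome with ``gap``
    bp of background between regions.  ``background`` gives 0-order base
    frequencies (uniform by default); ``markov`` may give a 4x4 first-order
    transition matrix instead.  For each plant, ``round(plant_rate *
    n_regions)`` regions of its dataset receive exactly one instance.
    """
    rng = np.random.default_rng(seed)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    total_regions = n_regions * len(datasets)
    genome_len = total_regions * (region_length + gap) + gap

    if markov is None:
        codes = rng.choice(4, size=genome_len, p=bg)
    else:
        trans = np.asarray(markov, float)
        trans = trans / trans.sum(axis=1, keepdims=True)
        codes = np.empty(genome_len, dtype=np.int64)
        codes[0] = rng.choice(4, p=bg)
        for i in range(1, genome_len):
            codes[i] = rng.choice(4, p=trans[codes[i - 1]])
    seq = np.array(list(BASES))[codes]

    regions: dict[str, list[tuple[int, int]]] = {}
    pos = gap
    for ds in datasets:
        lst = []
        for _ in range(n_regions):
            lst.append((pos, pos + region_length))
            pos += region_length + gap
        regions[ds] = lst

    truth_rows = []
    occupied: dict[tuple[str, int], list[tuple[int, int]]] = {}

    def place(c: MotifComplex, dataset: str, ridx: int, kind: str) -> None:
        m_left, m_right = motifs[c.left_id], motifs[c.right_id]
        span = c.span({c.left_id: m_left.length, c.right_id: m_right.length})
        if span > region_length:
            raise ValueError(f"planted span {span} exceeds region length {region_length}")
        site_probs = composite_site_probs(m_left, m_right, c, bg)
        # never overwrite an earlier plant: resample the offset until free
        off = None
        for attempt in range(500):
            # if the chosen region is crowded, spill into another one
            r = ridx if attempt < 50 else int(rng.integers(0, n_regions))
            taken = occupied.setdefault((dataset, r), [])
            cand = int(rng.integers(0, region_length - span + 1))
            if all(cand + span <= s or cand >= e for s, e in taken):
                off = cand
                ridx = r
                break
        if off is None:
            raise ValueError(f"dataset {dataset} too crowded to place {c.signature}")
        occupied[(dataset, ridx)].append((off, off + span))
        rstart, _ = regions[dataset][ridx]
        composite_seq = "".join(
            BASES[rng.choice(4, p=site_probs[:, j])] for j in range(span))
        genomic_strand = "+" if rng.random() < 0.5 else "-"
        placed = composite_seq if genomic_strand == "+" else _revcomp(composite_seq)
        seq[rstart + off: rstart + off + span] = list(placed)
        truth_rows.append({
            "dataset": dataset, "chrom": chrom,
            "span_start": rstart + off, "span_end": rstart + off + span,
            "complex": c.signature, "arrangement_strand": genomic_strand,
            "kind": kind,
        })

    for plant in plants:
        c = canonicalize(plant.complex)
        if plant.target_name not in regions:
            raise ValueError(f"unknown dataset {plant.target_name!r}")
        n_plant = int(round(plant.plant_rate * n_regions))
        chosen = rng.choice(n_regions, size=n_plant, replace=False)
        for ridx in sorted(chosen):
            place(c, plant.target_name, ridx, "plant")

    for bp in background_pairs:
        n_plant = int(round(bp.rate * n_regions))
        for ds in datasets:
            chosen = rng.choice(n_regions, size=n_plant, replace=False)
            for ridx in sorted(chosen):
                s = int(rng.integers(bp.min_spacing, bp.max_spacing + 1))
                ls = "+" if rng.random() < 0.5 else "-"
                rs = "+" if rng.random() < 0.5 else "-"
                c = canonicalize(MotifComplex(bp.motif1_id, bp.motif2_id, ls, rs, s))
                place(c, ds, ridx, "background")

    os.makedirs(out_dir, exist_ok=True)
    fasta_path = os.path.join(out_dir, "genome.fa")
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        s = "".join(seq)
        for i in range(0, len(s), 80):
            fh.write(s[i: i + 80] + "\n")
    for idx_path in (fasta_path + ".fai",):
        if os.path.exists(idx_path):
            os.remove(idx_path)  # force reindex of the fresh sequence

    beds = {}
    for ds in datasets:
        path = os.path.join(out_dir, f"{ds}.bed")
        with open(path, "w") as fh:
            for start, end in regions[ds]:
                fh.write(f"{chrom}\t{start}\t{end}\n")
        beds[ds] = path
    truth = pd.DataFrame(truth_rows, columns=["dataset", "chrom", "span_start",
                                              "span_end", "complex",
                                              "arrangement_strand", "kind"])
    return Fixture(fasta=fasta_path, beds=beds, truth=truth, datasets=list(datasets))


def compatible_overlap_partner(m_left: Motif, partner: Motif, overlap: int,
                               left_strand: str, right_strand: str) -> Motif:
    """Rebuild ``partner`` so it can overlap ``m_left`` by ``overlap`` columns.

    Real overlapping dimers share a composite core: the first ``overlap``
    columns of the right motif (in arrangement orientation) are made equal to
    the last columns of the left motif, so that a planted overlapping
    instance satisfies both motifs simultaneously.
    """
    if not 1 <= overlap <= min(m_left.length, partner.length):
        raise ValueError("overlap out of range")
    o1 = m_left.counts if left_strand == "+" else m_left.counts[::-1, ::-1]
    o2 = (partner.counts if right_strand == "+" else partner.counts[::-1, ::-1]).copy()
    o2[:, :overlap] = o1[:, -overlap:]
    counts = o2 if right_strand == "+" else o2[::-1, ::-1]
    return Motif(partner.id, counts, name=partner.name, source_format="synthetic")


def planted_dimer_fixture(
    out_dir: str,
    seed: int,
    spacing: int,
    orientation: tuple[str, str],
    plant_rate: float = 0.3,
    n_regions: int = 200,
    region_length: int = 500,
    motif_length: int = 8,
    strength: float = 0.85,
    baseline_rate: float = 0.1,
    n_background_datasets: int = 5,
) -> tuple[Fixture, MotifComplex, list[Motif]]:
    """Standard planted-dimer study condition: one complex planted in one
    target dataset, several background datasets diluting the control, and a
    baseline of pair occurrences at random structures in every dataset.

    For negative spacings the partner motif is rebuilt to share the overlap
    columns, as a genuine overlapping dimer would.  Returns the fixture, the
    planted canonical complex, and the motif library (four motifs).
    """
    rng = np.random.default_rng(seed)
    motifs = {f"M{i}": random_motif(rng, motif_length, strength, f"M{i}")
              for i in range(1, 5)}
    ls, rs = orientation
    if spacing < 0:
        motifs["M2"] = compatible_overlap_partner(
            motifs["M1"], motifs["M2"], -spacing, ls, rs)
    planted = canonicalize(MotifComplex("M1", "M2", ls, rs, spacing))
    datasets = ["tgt"] + [f"bg{i + 1}" for i in range(n_background_datasets)]
    fx = generate_fixture(
        out_dir, motifs, datasets, n_regions, region_length,
        [PlantSpec(planted, "tgt", plant_rate)], seed=seed,
        background_pairs=[BackgroundPairSpec("M1", "M2", baseline_rate, 0, 18)])
    return fx, planted, list(motifs.values())


def shadow_cluster_fixture(
    out_dir: str,
    seed: int,
    plant_rate: float = 0.4,
    n_regions: int = 200,
    region_length: int = 500,
) -> tuple[Fixture, list[MotifComplex], list[Motif], list[tuple[str, str]]]:
    """Two planted dimers plus controlled shadow predictions.

    The library contains, for each planted pair, a one-column-shifted copy of
    the left motif; the shifted motif matches one bp to the right of every
    parent match, so each planted dimer also surfaces as a complex with the
    shifted motif at a spacing one bp smaller, with genomic instances
    overlapping the parent's --- the redundancy pattern instance-overlap
    clustering is built to absorb.  Returns the fixture, the two planted
    canonical complexes, the motif library, and the pairs to screen.
    """
    rng = np.random.default_rng(seed)
    a = random_motif(rng, 8, 0.9, "A")
    b = random_motif(rng, 8, 0.9, "B")
    c = random_motif(rng, 8, 0.9, "C")
    d = random_motif(rng, 8, 0.9, "D")
    motifs = {m.id: m for m in
              [a, shifted_motif(a, "A2"), b, c, shifted_motif(c, "C2"), d]}
    planted = [canonicalize(MotifComplex("A", "B", "+", "+", 5)),
               canonicalize(MotifComplex("C", "D", "+", "-", 8))]
    datasets = ["tgt", "bg1", "bg2", "bg3"]
    fx = generate_fixture(
        out_dir, motifs, datasets, n_regions, region_length,
        [PlantSpec(p, "tgt", plant_rate) for p in planted], seed=seed,
        background_pairs=[BackgroundPairSpec("A", "B", 0.2, 0, 18),
                          BackgroundPairSpec("C", "D", 0.2, 0, 18)])
    pairs = [("A", "B"), ("A2", "B"), ("C", "D"), ("C2", "D")]
    return fx, planted, list(motifs.values()), pairs


def reverse_complement_fixture(fx: Fixture, out_dir: str) -> Fixture:
    """Mirror a fixture: reverse-complement the genome, mirror the regions.

    Predictions of the enrichment screen are invariant under this transform
    (canonical complexes absorb strand), which makes it a strong end-to-end
    consistency check.
    """
    os.makedirs(out_dir, exist_ok=True)
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(fx.fasta) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    fasta_path = os.path.join(out_dir, "genome.fa")
    with open(fasta_path, "w") as fh:
        for chrom, s in seqs.items():
            rc = _revcomp(s.upper())
            fh.write(f">{chrom}\n")
            for i in range(0, len(rc), 80):
                fh.write(rc[i: i + 80] + "\n")
    if os.path.exists(fasta_path + ".fai"):
        os.remove(fasta_path + ".fai")
    beds = {}
    for ds, path in fx.beds.items():
        out = os.path.join(out_dir, f"{ds}.bed")
        rows = []
        with open(path) as fh:
            for line in fh:
                chrom, start, end = line.split()[:3]
                size = len(seqs[chrom])
                rows.append((chrom, size - int(end), size - int(start)))
        rows.sort()
        with open(out, "w") as fh:
            for chrom, start, end in rows:
                fh.write(f"{chrom}\t{start}\t{end}\n")
        beds[ds] = out
    return Fixture(fasta=fasta_path, beds=beds, truth=fx.truth.copy(),
                   datasets=list(fx.datasets))


def fit_fixture(fx: Fixture, motifs: list[Motif], screened: list[str] | None = None,
                **config_kwargs):
    """Run the enrichment model on a fixture; returns the fitted results.

    ``screened`` restricts the target datasets (the rest still contribute to
    the control); remaining keyword arguments go to
    :class:`~dimerscan.config.RunConfig`.
    """
    from .config import RunConfig
    from .model import DimerEnrichmentModel
    from .regions import build_targets, read_bed

    bundle = build_targets([read_bed(fx.beds[d], name=d, kind="strong")
                            for d in fx.datasets], [])
    if screened is not None:
        bundle.targets = [t for t in bundle.targets if t.name in screened]
    cfg = RunConfig(genome=fx.fasta, **config_kwargs)
    model = DimerEnrichmentModel(fx.fasta, motifs, bundle, cfg)
    return model.fit()


# ---------------------------------------------------------------------------
# benchmark
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkSet:
    """Gold-standard known dimeric pairs versus random pairs."""

    known_pairs: list[tuple[str, str]]
    random_pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.known_pairs:
            raise ValueError("the known-pair set must not be empty")
        overlap = set(map(frozenset, self.known_pairs)) & set(
            map(frozenset, self.random_pairs))
        if overlap:
            raise ValueError("known and random pair sets must be disjoint")


def sample_random_pairs(rng: np.random.Generator, motif_ids: list[str],
                        known_pairs: list[tuple[str, str]],
                        n: int) -> list[tuple[str, str]]:
    """Random motif pairs excluding any motif appearing in the known set."""
    known_motifs = {m for pair in known_pairs for m in pair}
    pool = [m for m in motif_ids if m not in known_motifs]
    pairs: set[tuple[str, str]] = set()
    attempts = 0
    while len(pairs) < n:
        a, b = rng.choice(len(pool), size=2, replace=False)
        pairs.add(tuple(sorted((pool[a], pool[b]))))
        attempts += 1
        if attempts > 100 * n:
            raise ValueError("motif pool too small for the requested pair count")
    return sorted(pairs)


def example_registry_path() -> str:
    """Path of the bundled synthetic example registry of known dimers."""
    return os.path.join(os.path.dirname(__file__), "data",
                        "known_dimers_synthetic.tsv")


def load_registry(path: str) -> pd.DataFrame:
    """Read a known-dimer registry (TSV: motif_id_1, motif_id_2, orientation,
    spacing, citation)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"motif_id_1", "motif_id_2", "orientation", "spacing"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry {path} lacks columns {sorted(missing)}")
    return df


def synthetic_benchmark(
    out_dir: str,
    seed: int,
    n_known: int = 8,
    n_random: int = 12,
    plant_rate: float = 0.0,
    n_regions: int = 150,
    region_length: int = 300,
    motif_length: int = 8,
    strength: float = 0.9,
    max_spacing: int = 15,
) -> tuple[pd.DataFrame, float]:
    """End-to-end benchmark on a synthetic fixture.

    Builds a motif library (two dedicated motifs per known pair plus a pool
    for random pairs), assigns each known pair a complex at a random
    orientation and spacing, optionally plants those complexes in the target
    dataset at ``plant_rate``, runs the full enrichment screen over known and
    random pairs, scores each pair by its best raw p-value, and returns the
    ROC table and AUC.  With ``plant_rate = 0`` known and random pairs are
    exchangeable and the AUC fluctuates around 0.5.
    """
    from .config import RunConfig
    from .model import DimerEnrichmentModel
    from .regions import build_targets, read_bed

    rng = np.random.default_rng(seed)
    motifs: dict[str, Motif] = {}
    known_pairs: list[tuple[str, str]] = []
    for i in range(n_known):
        a = random_motif(rng, motif_length, strength, motif_id=f"K{i}a")
        b = random_motif(rng, motif_length, strength, motif_id=f"K{i}b")
        motifs[a.id], motifs[b.id] = a, b
        known_pairs.append(tuple(sorted((a.id, b.id))))
    # dedicated motifs per random pair, mirroring the known-pair construction,
    # so that under no planting the two sets are exchangeable
    random_pairs: list[tuple[str, str]] = []
    for i in range(n_random):
        a = random_motif(rng, motif_length, strength, motif_id=f"R{i}a")
        b = random_motif(rng, motif_length, strength, motif_id=f"R{i}b")
        motifs[a.id], motifs[b.id] = a, b
        random_pairs.append(tuple(sorted((a.id, b.id))))
    bench = BenchmarkSet(known_pairs, random_pairs)

    plants = []
    if plant_rate > 0:
        for a, b in known_pairs:
            s = int(rng.integers(0, 11))
            ls, rs = str(rng.choice(["+", "-"])), str(rng.choice(["+", "-"]))
            plants.append(PlantSpec(
                canonicalize(MotifComplex(a, b, ls, rs, s)), "tgt", plant_rate))
    bg_pairs = [BackgroundPairSpec(a, b, 0.1, 0, 10)
                for a, b in bench.known_pairs + bench.random_pairs]
    datasets = ["tgt", "bg1", "bg2", "bg3"]
    fx = generate_fixture(out_dir, motifs, datasets, n_regions,
                          region_length, plants, seed=int(rng.integers(2**31)),
                          background_pairs=bg_pairs)
    cfg = RunConfig(genome=fx.fasta, scope="fixed-pair",
                    fixed_pairs=bench.known_pairs + bench.random_pairs,
                    max_spacing=max_spacing, seed=seed)
    bundle = build_targets([read_bed(fx.beds[d], name=d, kind="strong")
                            for d in fx.datasets], [])
    # screen only the planted dataset; the rest contribute to the control only
    bundle.targets = [t for t in bundle.targets if t.name == "tgt"]
    model = DimerEnrichmentModel(fx.fasta, list(motifs.values()), bundle, cfg)
    res = model.fit()
    pair_scores: dict[tuple[str, str], float] = {}
    for r in res.all_results:
        key = tuple(sorted((r.complex.left_id, r.complex.right_id)))
        pair_scores[key] = min(pair_scores.get(key, 1.0), r.p_raw)
    return run_benchmark(bench, pair_scores)


def run_benchmark(bench: BenchmarkSet, pair_scores: dict[tuple[str, str], float],
                  p_grid: np.ndarray | None = None) -> tuple[pd.DataFrame, float]:
    """ROC of known- vs random-pair detection over p-value thresholds.

    ``pair_scores`` maps each (sorted) motif pair to its best p-value over
    all complexes and datasets (1.0 for pairs with no testable complex).
    Sensitivity at threshold t is the fraction of known pairs with score
    <= t, FPR the same fraction among random pairs; AUC is the trapezoid
    area under the (FPR, sensitivity) curve.
    """
    def score(pair):
        return pair_scores.get(tuple(sorted(pair)), 1.0)

    known = np.array([score(p) for p in bench.known_pairs])
    rand = np.array([score(p) for p in bench.random_pairs])
    if p_grid is None:
        p_grid = np.unique(np.concatenate([known, rand, [0.0, 1.0]]))
    rows = []
    for t in np.sort(p_grid):
        rows.append({"threshold": float(t),
                     "sensitivity": float(np.mean(known <= t)),
                     "fpr": float(np.mean(rand <= t))})
    roc = pd.DataFrame(rows)
    # anchor the curve at (0,0) and (1,1)
    fpr = np.concatenate([[0.0], roc["fpr"].to_numpy(), [1.0]])
    sens = np.concatenate([[0.0], roc["sensitivity"].to_numpy(), [1.0]])
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return roc, auc
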
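"""Redundancy clustering of overrepresented motif complexes.

Motif libraries typically contain several motifs per factor, so one
underlying dimer surfaces as many similar predictions.  Significant
complexes are ranked by p-value and greedily merged: each result joins the
first earlier-ranked cluster member it matches under three tests, attempted
in order --- (1) identical canonical complex (only against cluster seeds),
(2) dimer-PWM similarity under an information-content-affine squared
Euclidean distance threshold (only against *signature* complexes: seeds or
identity-joined members), (3) overlap of genomic instances at the modal
relative offset (against signatures or similarity-joined members from the
same target dataset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .complexes import ComplexInstance
from .enrichment import EnrichmentResult
from .motifs import Motif, information_content
from .scan import Genome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterParams:
    """Clustering thresholds.

    ``alpha``/``beta``: slope and intercept of the ED^2 threshold
    ``ED^2 < alpha * IC(seed PWM) + beta``; ``gamma``: required fraction of
    excess instances shared for an instance-overlap join.
    """

    alpha: float = 0.05
    beta: float = 0.5
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or not 0 < self.gamma <= 1:
            raise ValueError("require alpha >= 0, beta >= 0, 0 < gamma <= 1")


@dataclass
class DimerCluster:
    """A ranked group of similar enrichment results; one predicted dimer."""

    cluster_id: int
    seed: EnrichmentResult
    members: list[tuple[EnrichmentResult, str]] = field(default_factory=list)
    dimer_pwm: Motif | None = None

    @property
    def best_p_adj(self) -> float:
        return min(r.p_adj for r, _ in self.members)

    @property
    def size(self) -> int:
        return len(self.members)


def dimer_pwm(instances: list[ComplexInstance], genome: Genome,
              motif_id: str = "dimer") -> Motif:
    """Position frequency matrix over the instances' genomic spans.

    Sequences are read in the canonical arrangement orientation (instances on
    the '-' arrangement strand are reverse complemented).  Ambiguous bases do
    not contribute counts.
    """
    if not instances:
        raise ValueError("cannot build a PWM from zero instances")
    spans = {inst.span_end - inst.span_start for inst in instances}
    if len(spans) != 1:
        raise AssertionError(f"mixed instance span lengths {sorted(spans)}")
    L = spans.pop()
    counts = np.zeros((4, L))
    for inst in instances:
        codes = genome.fetch_codes(inst.chrom, inst.span_start, inst.span_end)
        if inst.arrangement_strand == "-":
            codes = np.array([3, 2, 1, 0, 4], dtype=np.int8)[codes][::-1]
        for j, b in enumerate(codes):
            if b < 4:
                counts[b, j] += 1
    return Motif(motif_id, counts, source_format="synthetic")


def squared_euclidean_distance(p1: np.ndarray, p2: np.ndarray) -> float:
    """Minimal column-wise squared Euclidean distance between two PWMs.

    The shorter matrix is slid along the longer over every offset with at
    least one overlapping column, on both strands; columns outside the
    overlap are compared against the uniform background (0.25 per base).
    """
    best = np.inf
    uniform = np.full(4, 0.25)
    rc2 = p2[::-1, ::-1]
    L1, L2 = p1.shape[1], p2.shape[1]
    for q2 in (p2, rc2):
        for off in range(-(L2 - 1), L1):
            total = 0.0
            lo = min(0, off)
            hi = max(L1, off + L2)
            for col in range(lo, hi):
                in1 = 0 <= col < L1
                in2 = 0 <= col - off < L2
                if in1 and in2:
                    d = p1[:, col] - q2[:, col - off]
                elif in1:
                    d = p1[:, col] - uniform
                else:
                    d = q2[:, col - off] - uniform
                total += float(d @ d)
                if total >= best:
                    break
            best = min(best, total)
    return best


def test_identity(rn: EnrichmentResult, rk: EnrichmentResult) -> bool:
    """Same canonical complex (necessarily found in different datasets)."""
    return rn.complex == rk.complex


def test_similarity(pwm_n: Motif, pwm_k: Motif, params: ClusterParams) -> bool:
    """ED^2(PWM_n, PWM_k) < alpha * IC(PWM_k) + beta (strict)."""
    ed2 = squared_euclidean_distance(pwm_n.probs, pwm_k.probs)
    _, ic_k = information_content(pwm_k)
    return ed2 < params.alpha * ic_k + params.beta


def _modal_offset(inst_n: list[ComplexInstance],
                  inst_k: list[ComplexInstance]) -> tuple[int | None, dict[int, set]]:
    """Most common relative offset (k.start - n.start) among overlapping pairs.

    Ties break toward the smallest absolute offset, negative before positive.
    Also returns, per offset, the set of Rn instance indices realizing it.
    """
    by_offset: dict[int, set] = {}
    k_by_chrom: dict[str, list[ComplexInstance]] = {}
    for inst in inst_k:
        k_by_chrom.setdefault(inst.chrom, []).append(inst)
    for i, a in enumerate(inst_n):
        for b in k_by_chrom.get(a.chrom, ()):
            if a.span_start < b.span_end and b.span_start < a.span_end:
                by_offset.setdefault(b.span_start - a.span_start, set()).add(i)
    if not by_offset:
        return None, {}
    modal = min(by_offset, key=lambda o: (-len(by_offset[o]), abs(o), o > 0))
    return modal, by_offset


def test_instance_overlap(rn: EnrichmentResult, rk: EnrichmentResult,
                          params: ClusterParams) -> bool:
    """Excess-instance overlap at the modal relative spatial arrangement.

    Counts Rn instances having an Rk instance at the single most common
    relative offset; joins when this count reaches
    ``gamma * (C12(Rn) - E12(Rn))``.  At least one overlapping instance is
    always required, so a complex with no excess over the null cannot join
    vacuously.
    """
    modal, by_offset = _modal_offset(rn.instances, rk.instances)
    if modal is None:
        return False
    shared = len(by_offset[modal])
    return shared >= params.gamma * (rn.C12 - rn.E12)


def cluster_all(results: list[EnrichmentResult], genome: Genome,
                params: ClusterParams | None = None) -> list[DimerCluster]:
    """Greedy rank-based clustering; annotates cluster_id/join_type in place."""
    params = params or ClusterParams()
    order = sorted(results, key=lambda r: (r.p_raw, r.signature, r.target_name))
    clusters: list[DimerCluster] = []
    roles: list[str] = []            # join type of order[k]
    assignment: list[int] = []       # cluster index of order[k]
    pwm_cache: dict[int, Motif] = {}

    def pwm(i: int) -> Motif:
        if i not in pwm_cache:
            r = order[i]
            pwm_cache[i] = dimer_pwm(r.instances, genome,
                                     motif_id=f"{r.signature}|{r.target_name}")
        return pwm_cache[i]

    for n, rn in enumerate(order):
        join: tuple[int, str] | None = None
        for k in range(n):
            rk = order[k]
            role_k = roles[k]
            if role_k == "seed" and test_identity(rn, rk):
                join = (assignment[k], "identity")
                break
            if role_k in ("seed", "identity") and test_similarity(pwm(n), pwm(k), params):
                join = (assignment[k], "motif_similarity")
                break
            if (role_k in ("seed", "identity", "motif_similarity")
                    and rn.target_name == rk.target_name
                    and test_instance_overlap(rn, rk, params)):
                join = (assignment[k], "instance_overlap")
                break
        if join is None:
            cluster = DimerCluster(cluster_id=len(clusters) + 1, seed=rn)
            cluster.members.append((rn, "seed"))
            cluster.dimer_pwm = dimer_pwm(rn.instances, genome,
                                          motif_id=f"cluster_{cluster.cluster_id}")
            clusters.append(cluster)
            assignment.append(len(clusters) - 1)
            roles.append("seed")
            rn.cluster_id = cluster.cluster_id
            rn.join_type = "seed"
        else:
            ci, jt = join
            clusters[ci].members.append((rn, jt))
            assignment.append(ci)
            roles.append(jt)
            rn.cluster_id = clusters[ci].cluster_id
            rn.join_type = jt
    return clusters
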
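"""Bernoulli enrichment model for motif complexes with pair-level correction.

For a complex R in target dataset T, let C12 be its observed instance count,
N12 the number of possible placements in T, b12(R) the complex's empirical
probability in the control, and f12 / b12 the probabilities of the
underlying motif *pair* (in any screened orientation and spacing) in the
target and control respectively.  The enrichment p-value is the upper tail
of Binomial(N12, p) at C12 with success probability

    p = f12 * b12(R) / b12,

so that genuine pair-level enrichment in the target (f12 > b12) raises the
null expectation instead of producing spurious complex calls.  The expected
count under the null is E12 = N12 * p.  P-values are Bonferroni-corrected
over all complex-by-dataset hypotheses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import binom

from .complexes import ComplexInstance, MotifComplex
from .regions import RegionSet

logger = logging.getLogger(__name__)


def possible_placements(rs: RegionSet, span: int, self_symmetric: bool) -> int:
    """Number of distinct placements of a complex of footprint ``span``.

    Each region of length G contributes max(0, G - span + 1) start positions;
    non-palindromic complexes can occur in two genomic orientations, a
    self-reverse-complementary arrangement in only one.
    """
    if span <= 0:
        raise ValueError("complex span must be positive")
    base = sum(max(0, (end - start) - span + 1) for _, start, end in rs.intervals)
    return base * (1 if self_symmetric else 2)


def empirical_probability(count: int, placements: int) -> float:
    """Per-placement occurrence probability; undefined for zero placements."""
    if placements <= 0:
        raise ZeroDivisionError("no possible placements")
    return count / placements


def complex_pvalue(c12: int, n12: int, p_success: float) -> float:
    """Upper-tail binomial probability P(X >= C12), X ~ Bin(N12, p).

    Numerically stable (regularised incomplete beta) up to N12 ~ 1e7.
    """
    if c12 > n12:
        raise ValueError(f"C12={c12} exceeds N12={n12}")
    if not 0 <= p_success <= 1:
        raise ValueError(f"success probability {p_success} outside [0, 1]")
    if c12 <= 0:
        return 1.0
    return float(binom.sf(c12 - 1, n12, p_success))


def expected_count(n12: int, f12: float, b12_complex: float, b12_pair: float) -> float:
    """E12 = N12 * f12 * (b12_complex / b12_pair)."""
    if b12_pair <= 0:
        raise ZeroDivisionError("pair never observed in control (b12_pair = 0)")
    return n12 * f12 * (b12_complex / b12_pair)


def bonferroni(p_raw: float, n_hypotheses: int) -> float:
    if n_hypotheses <= 0:
        raise ValueError("hypothesis count must be positive")
    return min(1.0, p_raw * n_hypotheses)


@dataclass
class EnrichmentResult:
    """Per (complex, target dataset) enrichment statistics."""

    complex: MotifComplex
    target_name: str
    C12: int
    N12: int
    b12_complex: float
    f12: float
    b12_pair: float
    E12: float
    p_raw: float
    p_adj: float = 1.0
    instances: list[ComplexInstance] = field(default_factory=list)
    cluster_id: int | None = None
    join_type: str | None = None

    @property
    def signature(self) -> str:
        return self.complex.signature


def test_complex(
    c: MotifComplex,
    target: RegionSet,
    control: RegionSet,
    span: int,
    c12_target: int,
    c12_control: int,
    f12: float,
    b12_pair: float,
    instances: list[ComplexInstance],
    target_name: str,
) -> EnrichmentResult | None:
    """Assemble the enrichment result for one complex in one target.

    Returns None for untestable hypotheses (no placements or pair never seen
    in the control); such skips are logged and still count toward the
    Bonferroni hypothesis total, handled by the caller.
    """
    n12 = possible_placements(target, span, c.is_self_rc)
    if n12 == 0:
        return None
    n12_control = possible_placements(control, span, c.is_self_rc)
    if n12_control == 0 or b12_pair <= 0:
        logger.debug("skipping %s in %s: empty control universe", c.signature, target_name)
        return None
    if c12_control > 0:
        b12_complex = c12_control / n12_control
    elif c12_target > 0:
        # complex present in target but never in control: pseudo-probability
        b12_complex = 1.0 / (n12_control + 1)
    else:
        b12_complex = 0.0
    p_success = f12 * (b12_complex / b12_pair)
    if p_success > 1.0:
        logger.warning("success probability %.3g > 1 for %s in %s; clamped",
                       p_success, c.signature, target_name)
        p_success = 1.0
    e12 = n12 * p_success
    p_raw = complex_pvalue(c12_target, n12, p_success)
    return EnrichmentResult(
        complex=c, target_name=target_name, C12=c12_target, N12=n12,
        b12_complex=b12_complex, f12=f12, b12_pair=b12_pair,
        E12=e12, p_raw=p_raw, instances=instances)
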
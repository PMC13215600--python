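"""Disease-allele frequency estimation and qPCR fold-change arithmetic."""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class GenotypeCounts:
    """Carrier-screening panel counts: heterozygotes, hom-alt, panel size."""

    n_het: int
    n_homalt: int
    n_total: int

    def __post_init__(self):
        if min(self.n_het, self.n_homalt, self.n_total) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_het + self.n_homalt > self.n_total:
            raise ValueError("het + hom-alt exceeds panel size")


@dataclass
class AlleleFrequencyEstimate:
    f: float
    se: float
    counts: GenotypeCounts
    metadata: dict = field(default_factory=dict)


def allele_frequency(counts: GenotypeCounts) -> AlleleFrequencyEstimate:
    """Allele-counting estimator f = (n_het + 2 n_homalt) / (2 n).

    The standard error is the binomial SE sqrt(f (1-f) / 2n) over the 2n
    sampled alleles.  The metadata also records the radical-free variance
    quantity f(1-f)/2n, since the estimator is sometimes quoted without the
    square root.
    """
    if counts.n_total < 1:
        raise ValueError("panel size must be >= 1")
    n2 = 2 * counts.n_total
    f = (counts.n_het + 2 * counts.n_homalt) / n2
    var = f * (1 - f) / n2
    se = math.sqrt(var)
    return AlleleFrequencyEstimate(
        f=f,
        se=se,
        counts=counts,
        metadata={"se_definition": "binomial sqrt(f(1-f)/2n)", "variance_no_radical": var},
    )


def allele_frequency_se(estimate: AlleleFrequencyEstimate) -> float:
    return estimate.se


@dataclass
class DdctInput:
    ct_target_case: float
    ct_ref_case: float
    ct_target_ctrl: float
    ct_ref_ctrl: float

    def __post_init__(self):
        vals = (self.ct_target_case, self.ct_ref_case, self.ct_target_ctrl, self.ct_ref_ctrl)
        if not all(math.isfinite(v) and v > 0 for v in vals):
            raise ValueError("Ct values must be finite and positive")


def ddct_fold_change(inp: DdctInput) -> float:
    """Comparative threshold-cycle fold change 2^-((dCt_case) - (dCt_ctrl))."""
    ddct = (inp.ct_target_case - inp.ct_ref_case) - (inp.ct_target_ctrl - inp.ct_ref_ctrl)
    return 2.0 ** (-ddct)
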
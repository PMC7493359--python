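"""Feature-weight builders: per-modality (IPF-lasso) and MAF-based weights.

The integrative lasso with penalty factors (IPF-lasso) penalizes each data
modality (e.g. expression vs. genotypes) with its own multiplier.  With
the mixing parameter at 1 (pure lasso), supplying the per-modality factor
as the feature weight of every feature in that modality makes the weighted
lasso exactly the IPF-lasso: the effective per-modality penalty is
proportional to lam * factor_m.  Note that some IPF-lasso write-ups scale
the objective by 2n and absorb it into lambda; here the weights carry only
the modality ratios and the overall scale stays on the lambda grid.

MAF weights follow the genomic convention omega_j = 2*sqrt(MAF_j(1-MAF_j)):
a variant's penalty is proportional to its genotype standard deviation
under Hardy-Weinberg equilibrium, so rare variants are penalized less.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import WeightRangeError

__all__ = ["ModalitySpec", "ipf_feature_weights", "maf_weights"]


@dataclass(frozen=True)
class ModalitySpec:
    """Contiguous feature blocks per modality (in Z column order) and one
    positive penalty factor each."""

    sizes: np.ndarray
    penalty_factors: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=int)
        factors = np.asarray(self.penalty_factors, dtype=float)
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "penalty_factors", factors)
        if sizes.ndim != 1 or factors.ndim != 1 or sizes.shape != factors.shape:
            raise ValueError("sizes and penalty_factors must be equal-length vectors")
        if np.any(sizes < 1):
            raise ValueError("every modality must contain at least one feature")
        if np.any(factors <= 0) or np.any(~np.isfinite(factors)):
            raise WeightRangeError("penalty factors must be positive and finite")

    @property
    def p(self) -> int:
        return int(self.sizes.sum())


def ipf_feature_weights(spec: ModalitySpec) -> np.ndarray:
    """Expand modality penalty factors to a length-p feature-weight vector:
    omega_j = factor_m for every feature j in modality m."""
    return np.repeat(spec.penalty_factors, spec.sizes)


def maf_weights(maf: np.ndarray) -> np.ndarray:
    """omega_j = 2*sqrt(MAF_j * (1 - MAF_j)) for MAF_j in (0, 0.5].

    Raises WeightRangeError outside that range (a zero MAF would give
    weight 0 and silently unpenalize the variant).
    """
    m = np.asarray(maf, dtype=float)
    if np.any(~np.isfinite(m)) or np.any(m <= 0.0) or np.any(m > 0.5):
        raise WeightRangeError("minor allele frequencies must lie in (0, 0.5]")
    return 2.0 * np.sqrt(m * (1.0 - m))
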
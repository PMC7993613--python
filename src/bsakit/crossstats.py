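"""Cross-level statistics for a recessive F2 intercross.

Segregation against a Mendelian expectation (exact binomial), genotype vs
phenotype concordance under the recessive rule, expected pool allele
frequencies / dAF derived by enumerating F1 gamete combinations, and -dCq
expression normalisation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENOTYPES",
    "PHENOTYPES",
    "SegregationSummary",
    "ConcordanceTable",
    "ExpectedPoolDaf",
    "segregation_summary",
    "concordance_table",
    "expected_pool_daf",
    "delta_cq",
    "delta_cq_summary",
]

GENOTYPES = ("hom_ref", "het", "hom_mut")
PHENOTYPES = ("wild_type", "mutant")


@dataclass(frozen=True)
class SegregationSummary:
    n_total: int
    n_affected: int
    proportion_pct: float  # rounded to reporting precision
    expected_ratio: float
    p_value: float  # exact binomial, two-sided (minlike)


def segregation_summary(
    n_affected: int,
    n_total: int,
    expected_ratio: float = 0.25,
    pct_decimals: int = 0,
) -> SegregationSummary:
    """Affected proportion and exact two-sided binomial test vs the expected ratio.

    The proportion is reported in percent, rounded to ``pct_decimals``
    (whole percent by default).
    """
    if n_total <= 0 or not 0 <= n_affected <= n_total:
        raise ValueError("need 0 <= n_affected <= n_total with n_total > 0")
    if not 0.0 < expected_ratio < 1.0:
        raise ValueError("expected_ratio must lie in (0, 1)")
    pct = round(100.0 * n_affected / n_total, pct_decimals)
    if pct_decimals == 0:
        pct = float(int(pct))
    p = stats.binomtest(n_affected, n_total, expected_ratio, alternative="two-sided").pvalue
    return SegregationSummary(n_total, n_affected, pct, expected_ratio, float(p))


@dataclass(frozen=True)
class ConcordanceTable:
    """Genotype x phenotype cross-tabulation under the recessive rule."""

    counts: pd.DataFrame  # index GENOTYPES, columns PHENOTYPES
    discordant_count: int
    discordant_ids: tuple

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


def concordance_table(genotypes, phenotypes, ids=None) -> ConcordanceTable:
    """Cross-tabulate genotype vs phenotype and list discordant individuals.

    Discordance under the recessive rule: a homozygous mutant labelled
    wild-type, or a non-hom-mutant labelled mutant.
    """
    genotypes = list(genotypes)
    phenotypes = list(phenotypes)
    if len(genotypes) != len(phenotypes):
        raise ValueError("genotype and phenotype vectors differ in length")
    if ids is None:
        ids = list(range(len(genotypes)))
    counts = pd.DataFrame(0, index=list(GENOTYPES), columns=list(PHENOTYPES))
    discordant = []
    for ident, g, p in zip(ids, genotypes, phenotypes):
        if g not in GENOTYPES:
            raise ValueError(f"unknown genotype category {g!r}")
        if p not in PHENOTYPES:
            raise ValueError(f"unknown phenotype category {p!r}")
        counts.loc[g, p] += 1
        if (g == "hom_mut") != (p == "mutant"):
            discordant.append(ident)
    return ConcordanceTable(counts, len(discordant), tuple(discordant))


@dataclass(frozen=True)
class ExpectedPoolDaf:
    """Expected pool mutant-allele frequencies under an inheritance model.

    ``daf`` uses the F2 genotype distribution conditional on phenotype
    (phenotypically wild-type animals are 1/3 hom-ref : 2/3 het, giving a
    mutant-allele frequency of 1/3). ``daf_equal_carrier_weight`` is the
    alternative obtained by weighting hom-ref and het carriers equally
    (frequency 1/4), provided for comparison with reports quoting 0.75.
    """

    mutant_pool_freq: float
    wildtype_pool_freq: float
    daf: float
    daf_equal_carrier_weight: float


def expected_pool_daf(
    mode: str = "recessive", composition: str = "phenotype_selected"
) -> ExpectedPoolDaf:
    """Expected pool frequencies and dAF, by enumerating F1 gamete combinations.

    Each F1 parent transmits the mutant allele with probability 1/2; the 16
    equally likely ordered gamete pairs for (father, mother) x (two pooled
    chromosomes) give the F2 genotype distribution, conditioned on phenotype
    to form the pools.
    """
    if mode != "recessive":
        raise ValueError(f"unsupported inheritance mode {mode!r}")
    if composition != "phenotype_selected":
        raise ValueError(f"unsupported pool composition {composition!r}")
    # enumerate the 4 ordered gamete pairs per individual draw
    dist: dict[int, float] = {}
    for a, b in itertools.product((0, 1), repeat=2):
        dist[a + b] = dist.get(a + b, 0.0) + 0.25
    # mutant pool: conditional on genotype 2
    mut_freq = 1.0  # 2 mutant alleles / 2
    # wild-type pool: conditional on genotype != 2
    p_wt = 1.0 - dist[2]
    wt_freq = sum(g / 2.0 * p for g, p in dist.items() if g != 2) / p_wt
    # equal weighting of the two carrier genotype classes
    eq_freq = (0 / 2.0 + 1 / 2.0) / 2.0
    return ExpectedPoolDaf(
        mutant_pool_freq=mut_freq,
        wildtype_pool_freq=wt_freq,
        daf=mut_freq - wt_freq,
        daf_equal_carrier_weight=mut_freq - eq_freq,
    )


def delta_cq(cq_target: float, cq_reference: float) -> tuple[float, float]:
    """-dCq relative expression and the corresponding 2^(-dCq) fold change."""
    if not (math.isfinite(cq_target) and math.isfinite(cq_reference)):
        raise ValueError("Cq values must be finite")
    neg_dcq = -(cq_target - cq_reference)
    return neg_dcq, 2.0**neg_dcq


def delta_cq_summary(cq_targets, cq_references) -> pd.Series:
    """Replicate summary of -dCq: mean with min/max across paired replicates."""
    targets = np.asarray(cq_targets, dtype=float)
    refs = np.asarray(cq_references, dtype=float)
    if targets.shape != refs.shape or targets.size == 0:
        raise ValueError("need equal-length, nonempty replicate vectors")
    vals = -(targets - refs)
    return pd.Series(
        {
            "n_replicates": targets.size,
            "mean_neg_dcq": vals.mean(),
            "min_neg_dcq": vals.min(),
            "max_neg_dcq": vals.max(),
            "mean_fold": float(np.mean(2.0**vals)),
        }
    )
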
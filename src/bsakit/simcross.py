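"""Forward simulation of an F2 intercross with phenotype-based pooled sequencing.

Everything downstream of read mapping is emulated here: founder-fixed SNP
grids, recombinant F2 cohorts (Haldane model, no interference), phenotype
pooling with optional misclassification, Poisson/binomial pooled read counts
with a symmetric base-error flip, reference panels that lack the causal
allele, and noisy barcoded amplicon reads drawn from a known isoform mixture.

All randomness flows from ``CrossDesign.seed`` (or an explicit ``seed``
argument); identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "InvalidDesignError",
    "InvalidMixtureError",
    "CrossDesign",
    "FounderHaplotypes",
    "F2Cohort",
    "AmpliconRead",
    "simulate_founders",
    "simulate_gametes",
    "simulate_f2_cross",
    "pool_and_sequence",
    "simulate_unlinked_sites",
    "simulate_reference_panel",
    "panel_for_sites",
    "simulate_amplicon_reads",
    "simulate_bsa_dataset",
    "annotate_consequences",
    "make_prioritization_fixture",
    "expected_null_delta_af",
    "paper_design",
    "mapping_design",
]

_BASES = np.array(list("ACGT"))

# rng stream tags, one per operation, so stages are independent but reproducible
_RNG_FOUNDERS = 1
_RNG_CROSS = 2
_RNG_POOLSEQ = 3
_RNG_PANEL = 4
_RNG_AMPLICON = 5
_RNG_BACKGROUND = 6
_RNG_CONSEQ = 7


class InvalidDesignError(ValueError):
    """Raised when a CrossDesign (or derived input) is internally inconsistent."""


class InvalidMixtureError(ValueError):
    """Raised when an isoform mixture is malformed."""


@dataclass(frozen=True)
class CrossDesign:
    """Full specification of the simulated intercross, pooling, and sequencing.

    Attributes
    ----------
    n_f2 : number of F2 individuals produced by the F1 x F1 cross.
    pool_sizes : (mutant pool target, wild-type pool target). All
        mutant-labelled animals enter the mutant pool; at most
        ``pool_sizes[1]`` wild-type-labelled animals enter the other pool.
    chrom_length_bp : physical chromosome length.
    recomb_rate : Morgans per bp, uniform map.
    n_snps : founder-difference SNP count on the chromosome.
    causal_pos : bp coordinate of the recessive causal variant (snapped to
        the nearest simulated SNP).
    misphenotype_prob : probability that a homozygous-mutant F2 is labelled
        wild-type (and hence pooled with the wild types).
    coverage : mean read depth of the (mutant, wild-type) pools.
    base_error : per-read per-site symmetric allele flip probability.
    seed : master seed for every stage of the simulation.
    """

    n_f2: int = 52
    pool_sizes: tuple[int, int] = (12, 40)
    chrom_length_bp: int = 10_000_000
    recomb_rate: float = 5e-10
    n_snps: int = 5_000
    causal_pos: int = 5_000_000
    misphenotype_prob: float = 0.0
    coverage: tuple[float, float] = (37.6, 36.5)
    base_error: float = 0.001
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_f2 < 1:
            raise InvalidDesignError("n_f2 must be >= 1")
        if self.n_snps < 1:
            raise InvalidDesignError("n_snps must be >= 1")
        if self.chrom_length_bp < 1:
            raise InvalidDesignError("chromosome length must be positive")
        if len(self.pool_sizes) != 2 or min(self.pool_sizes) < 1:
            raise InvalidDesignError("pool_sizes must be two positive counts")
        if sum(self.pool_sizes) > self.n_f2:
            raise InvalidDesignError("pool sizes must sum to <= n_f2")
        for p in (self.misphenotype_prob, self.base_error):
            if not 0.0 <= p <= 1.0:
                raise InvalidDesignError("probabilities must lie in [0, 1]")
        if min(self.coverage) <= 0:
            raise InvalidDesignError("coverage must be positive")
        if not 1 <= self.causal_pos <= self.chrom_length_bp:
            raise InvalidDesignError("causal_pos must lie within the chromosome")
        if self.recomb_rate < 0:
            raise InvalidDesignError("recomb_rate must be >= 0")

    @property
    def morgans(self) -> float:
        """Genetic length of the chromosome."""
        return self.chrom_length_bp * self.recomb_rate

    def replace(self, **kw) -> "CrossDesign":
        return replace(self, **kw)


def paper_design(seed: int = 0, **overrides) -> CrossDesign:
    """Scaled-down default design mirroring the study cross.

    52 F2, pools of 12 mutant-labelled and 40 wild-type-labelled animals at
    mean depths 37.6X / 36.5X. The SNP grid is 5,000 markers over a sub-cM
    chromosome segment so that a 500-SNP window spans far less genetic
    distance than the identity-by-descent tract around the causal locus,
    matching the geometry of the original dense genome-wide scan.
    """
    return CrossDesign(seed=seed, **overrides)


def mapping_design(seed: int = 0, **overrides) -> CrossDesign:
    """Design variant with appreciable recombination across the chromosome.

    Used for end-to-end locus-recovery runs: the chromosome spans 1 Morgan,
    several times the expected identity-by-descent tract of the mutant pool
    (~2/26 Morgans), so heterozygosity recovers away from the causal locus
    and interval calling has a real signal-vs-flank contrast.
    """
    kw = dict(chrom_length_bp=50_000_000, recomb_rate=2e-8, causal_pos=25_000_000)
    kw.update(overrides)
    return CrossDesign(seed=seed, **kw)


@dataclass(frozen=True)
class FounderHaplotypes:
    """Founder SNP grid: the mutant founder is alt/alt and the wild-type
    founder ref/ref at every site, so allele 1 marks the mutant haplotype."""

    chrom: str
    positions: np.ndarray  # 1-based bp, sorted, unique
    causal_index: int

    @property
    def n_snps(self) -> int:
        return self.positions.size

    @property
    def causal_pos(self) -> int:
        return int(self.positions[self.causal_index])


@dataclass(frozen=True)
class F2Cohort:
    """Phased F2 genotypes plus phenotype labels and causal-genotype truth."""

    gametes: tuple[np.ndarray, np.ndarray]  # each (n_f2, n_snps), 1 = mutant-founder allele
    genotypes: np.ndarray  # (n_f2, n_snps) alt-allele dosage 0/1/2
    labeled_mutant: np.ndarray  # bool per individual, phenotype label
    causal_genotype: np.ndarray  # 0/1/2 at the causal SNP

    @property
    def n_f2(self) -> int:
        return self.genotypes.shape[0]


def _rng(design: CrossDesign, tag: int) -> np.random.Generator:
    return np.random.default_rng([design.seed, tag])


def simulate_founders(design: CrossDesign) -> FounderHaplotypes:
    """Draw the founder-difference SNP grid.

    SNP positions are uniform over the chromosome; the causal variant is the
    SNP closest to ``design.causal_pos``. The mutant founder carries the alt
    allele at every site (fixed differences between founders).
    """
    rng = _rng(design, _RNG_FOUNDERS)
    if design.n_snps > design.chrom_length_bp:
        raise InvalidDesignError("more SNPs than base pairs")
    positions = rng.choice(design.chrom_length_bp, size=design.n_snps, replace=False)
    positions = np.sort(positions) + 1  # 1-based
    causal_index = int(np.argmin(np.abs(positions - design.causal_pos)))
    return FounderHaplotypes(design.chrom, positions, causal_index)


def simulate_gametes(
    n: int, founders: FounderHaplotypes, design: CrossDesign, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` F1 gametes over the founder SNP grid.

    Crossover counts are Poisson(chromosome length in Morgans) and crossover
    positions uniform (Haldane, no interference). Because each F1 carries one
    all-alt and one all-ref chromosome, a gamete is fully described by its
    starting haplotype and the parity of crossovers left of each SNP.
    """
    lam = design.morgans
    counts = rng.poisson(lam, size=n)
    starts = rng.integers(0, 2, size=n)
    out = np.empty((n, founders.n_snps), dtype=np.uint8)
    for i in range(n):
        if counts[i] == 0:
            out[i] = starts[i]
            continue
        xo = np.sort(rng.uniform(0, design.chrom_length_bp, size=counts[i]))
        below = np.searchsorted(xo, founders.positions)
        out[i] = (starts[i] + below) % 2
    return out


def simulate_f2_cross(founders: FounderHaplotypes, design: CrossDesign) -> F2Cohort:
    """Form F2 individuals from two independent F1 gametes and label phenotypes.

    Phenotype follows the recessive rule (mutant-like iff homozygous for the
    causal allele) except that a homozygous mutant is mislabelled wild-type
    with probability ``misphenotype_prob``.
    """
    rng = _rng(design, _RNG_CROSS)
    g1 = simulate_gametes(design.n_f2, founders, design, rng)
    g2 = simulate_gametes(design.n_f2, founders, design, rng)
    genotypes = (g1 + g2).astype(np.int8)
    causal_genotype = genotypes[:, founders.causal_index].copy()
    labeled = causal_genotype == 2
    if design.misphenotype_prob > 0:
        flips = rng.random(design.n_f2) < design.misphenotype_prob
        labeled = labeled & ~flips
    return F2Cohort((g1, g2), genotypes, labeled, causal_genotype)


def _sequence_pool(
    freqs: np.ndarray,
    coverage: float,
    base_error: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (ref_count, alt_count) per site given true pool allele freqs.

    Depth ~ Poisson(coverage); alt reads ~ Binomial(depth, freq); then every
    read flips allele with probability ``base_error``.
    """
    depth = rng.poisson(coverage, size=freqs.size)
    alt_true = rng.binomial(depth, freqs)
    alt_kept = rng.binomial(alt_true, 1.0 - base_error)
    ref_flipped = rng.binomial(depth - alt_true, base_error)
    alt_obs = alt_kept + ref_flipped
    return depth - alt_obs, alt_obs


def _allele_strings(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_i], _BASES[alt_i]


def pool_and_sequence(
    cohort: F2Cohort, design: CrossDesign, founders: FounderHaplotypes
) -> pd.DataFrame:
    """Pool F2 animals by phenotype label and emit a pooled read-count table.

    All mutant-labelled animals enter the mutant pool. Up to
    ``design.pool_sizes[1]`` wild-type-labelled animals enter the wild-type
    pool (all of them when fewer are available). Returns a PoolSite table
    with columns chrom, pos, ref, alt, qual, mut_ref, mut_alt, wt_ref, wt_alt.
    """
    rng = _rng(design, _RNG_POOLSEQ)
    mut_idx = np.flatnonzero(cohort.labeled_mutant)
    wt_idx = np.flatnonzero(~cohort.labeled_mutant)
    if mut_idx.size == 0 or wt_idx.size == 0:
        raise InvalidDesignError("a phenotype pool has zero individuals")
    if wt_idx.size > design.pool_sizes[1]:
        wt_idx = np.sort(rng.choice(wt_idx, size=design.pool_sizes[1], replace=False))

    p_mut = cohort.genotypes[mut_idx].sum(axis=0) / (2 * mut_idx.size)
    p_wt = cohort.genotypes[wt_idx].sum(axis=0) / (2 * wt_idx.size)

    mut_ref, mut_alt = _sequence_pool(p_mut, design.coverage[0], design.base_error, rng)
    wt_ref, wt_alt = _sequence_pool(p_wt, design.coverage[1], design.base_error, rng)
    ref, alt = _allele_strings(founders.n_snps, rng)
    qual = np.clip(np.round(rng.normal(1500.0, 150.0, size=founders.n_snps)), 1, None)

    return pd.DataFrame(
        {
            "chrom": founders.chrom,
            "pos": founders.positions,
            "ref": ref,
            "alt": alt,
            "qual": qual,
            "mut_ref": mut_ref,
            "mut_alt": mut_alt,
            "wt_ref": wt_ref,
            "wt_alt": wt_alt,
        }
    )


def simulate_unlinked_sites(
    n_sites: int,
    pool_sizes: tuple[int, int] = (12, 40),
    coverage: tuple[float, float] = (37.6, 36.5),
    base_error: float = 0.001,
    seed: int = 0,
    chrom: str = "chrU1",
    spacing_bp: int = 1_000,
) -> pd.DataFrame:
    """Pooled counts at F2-segregating SNPs unlinked to the causal locus.

    At an unlinked founder-difference SNP each of the ``2n`` pooled
    chromosomes carries the alt allele independently with probability 1/2
    (Mendelian sampling), so pool frequencies are Binomial(2n, 1/2)/2n before
    sequencing noise. This is the genome-wide null background.
    """
    if n_sites < 1:
        raise InvalidDesignError("n_sites must be >= 1")
    rng = np.random.default_rng([seed, _RNG_BACKGROUND])
    n1, n2 = pool_sizes
    p_mut = rng.binomial(2 * n1, 0.5, size=n_sites) / (2 * n1)
    p_wt = rng.binomial(2 * n2, 0.5, size=n_sites) / (2 * n2)
    mut_ref, mut_alt = _sequence_pool(p_mut, coverage[0], base_error, rng)
    wt_ref, wt_alt = _sequence_pool(p_wt, coverage[1], base_error, rng)
    ref, alt = _allele_strings(n_sites, rng)
    qual = np.clip(np.round(rng.normal(1500.0, 150.0, size=n_sites)), 1, None)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(n_sites, dtype=np.int64) * spacing_bp + 1,
            "ref": ref,
            "alt": alt,
            "qual": qual,
            "mut_ref": mut_ref,
            "mut_alt": mut_alt,
            "wt_ref": wt_ref,
            "wt_alt": wt_alt,
        }
    )


def expected_null_delta_af(
    pool_sizes: tuple[int, int] = (12, 40),
    coverage: tuple[float, float] = (37.6, 36.5),
) -> float:
    """Closed-form expected |dAF| at unlinked sites.

    The difference of observed pool frequencies is approximately normal with
    variance 1/4(1/2n1 + 1/2n2) (Mendelian pool sampling) plus
    1/4(1/C1 + 1/C2) (read sampling at frequencies near 1/2); the mean
    absolute value of a centred normal is sd * sqrt(2/pi).
    """
    n1, n2 = pool_sizes
    c1, c2 = coverage
    var = 0.25 * (1 / (2 * n1) + 1 / (2 * n2)) + 0.25 * (1 / c1 + 1 / c2)
    return math.sqrt(var) * math.sqrt(2.0 / math.pi)


def simulate_reference_panel(
    founders: FounderHaplotypes,
    n_samples: int = 20,
    seed: int = 0,
    freq_range: tuple[float, float] = (0.1, 0.9),
) -> pd.DataFrame:
    """Genotypes of unrelated samples that all lack the causal alt allele.

    Non-causal sites are polymorphic with per-site alt frequencies drawn
    uniformly from ``freq_range``; the causal site is homozygous reference in
    every sample. Returns chrom/pos plus one 0/1/2 dosage column per sample.
    """
    return panel_for_sites(
        founders.chrom,
        founders.positions,
        causal_pos=founders.causal_pos,
        n_samples=n_samples,
        seed=seed,
        freq_range=freq_range,
    )


def panel_for_sites(
    chrom,
    positions,
    causal_pos=None,
    causal_chrom=None,
    n_samples: int = 20,
    seed: int = 0,
    freq_range: tuple[float, float] = (0.1, 0.9),
) -> pd.DataFrame:
    """Panel genotype table for arbitrary sites; see simulate_reference_panel."""
    if n_samples < 1:
        raise InvalidDesignError("n_samples must be >= 1")
    rng = np.random.default_rng([seed, _RNG_PANEL])
    positions = np.asarray(positions)
    n = positions.size
    chroms = np.broadcast_to(np.asarray(chrom, dtype=object), (n,))
    freqs = rng.uniform(freq_range[0], freq_range[1], size=n)
    geno = rng.binomial(2, freqs, size=(n_samples, n))
    if causal_pos is not None:
        mask = positions == causal_pos
        if causal_chrom is not None:
            mask &= chroms == causal_chrom
        geno[:, mask] = 0
    out = pd.DataFrame({"chrom": chroms, "pos": positions})
    for s in range(n_samples):
        out[f"sample_{s + 1}"] = geno[s]
    return out


@dataclass(frozen=True)
class AmpliconRead:
    """One simulated long read with its truth label."""

    read_id: str
    sequence: str
    true_isoform: str


def simulate_amplicon_reads(
    isoforms,
    mixture,
    barcode: str,
    adapter: str,
    n_reads: int,
    error_rate: float = 0.1,
    seed: int = 0,
) -> list[AmpliconRead]:
    """Draw noisy amplicon reads from a known isoform mixture.

    Each read is ``barcode + adapter + template`` with independent symmetric
    substitution errors at ``error_rate``; the template isoform is drawn from
    ``mixture``. ``isoforms`` is a sequence of objects with ``isoform_id`` and
    ``sequence`` attributes (or (id, sequence) pairs).
    """
    if len(barcode) != 7:
        raise InvalidMixtureError("barcode must be exactly 7 bases")
    mixture = np.asarray(mixture, dtype=float)
    if mixture.size != len(isoforms) or mixture.min() < 0 or abs(mixture.sum() - 1.0) > 1e-9:
        raise InvalidMixtureError("mixture must be non-negative and sum to 1")
    if not 0.0 <= error_rate <= 1.0:
        raise InvalidMixtureError("error_rate must lie in [0, 1]")
    pairs = []
    for iso in isoforms:
        if hasattr(iso, "isoform_id"):
            pairs.append((iso.isoform_id, iso.sequence))
        else:
            pairs.append((iso[0], iso[1]))
    rng = np.random.default_rng([seed, _RNG_AMPLICON])
    picks = rng.choice(len(pairs), size=n_reads, p=mixture)
    prefix = barcode + adapter
    reads = []
    for i, k in enumerate(picks):
        iso_id, template = pairs[k]
        seq = prefix + template
        if error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hit = np.flatnonzero(rng.random(arr.size) < error_rate)
            if hit.size:
                # replace each hit base with one of the three other bases
                base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
                lut = np.zeros(256, dtype=np.int64)
                lut[base_codes] = np.arange(4)
                arr[hit] = base_codes[(lut[arr[hit]] + rng.integers(1, 4, size=hit.size)) % 4]
            seq = arr.tobytes().decode()
        reads.append(AmpliconRead(f"read_{i + 1}", seq, iso_id))
    return reads


def simulate_bsa_dataset(
    design: CrossDesign,
    background_sites: int = 95_000,
    n_panel: int = 20,
) -> dict:
    """Run the full simulation: linked chromosome + unlinked background + panel.

    Returns a dict with keys ``sites`` (combined PoolSite table, sorted),
    ``panel`` (panel genotype table over the same sites), ``founders``,
    ``cohort``, ``causal_chrom`` and ``causal_pos``.
    """
    founders = simulate_founders(design)
    cohort = simulate_f2_cross(founders, design)
    linked = pool_and_sequence(cohort, design, founders)
    tables = [linked]
    if background_sites > 0:
        tables.append(
            simulate_unlinked_sites(
                background_sites,
                pool_sizes=design.pool_sizes,
                coverage=design.coverage,
                base_error=design.base_error,
                seed=design.seed,
            )
        )
    sites = pd.concat(tables, ignore_index=True)
    sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    panel = panel_for_sites(
        sites["chrom"].to_numpy(),
        sites["pos"].to_numpy(),
        causal_pos=founders.causal_pos,
        causal_chrom=founders.chrom,
        n_samples=n_panel,
        seed=design.seed,
    )
    return {
        "sites": sites,
        "panel": panel,
        "founders": founders,
        "cohort": cohort,
        "causal_chrom": founders.chrom,
        "causal_pos": founders.causal_pos,
    }


_DECOY_CONSEQUENCES = np.array(
    ["missense_variant", "frameshift_variant", "stop_gained", "stop_lost", "splice_acceptor_variant"]
)


def annotate_consequences(
    sites: pd.DataFrame,
    causal_chrom,
    causal_pos: int,
    seed: int = 0,
    decoy_fraction: float = 0.01,
) -> pd.DataFrame:
    """Attach consequence labels: the causal site becomes a splice-donor
    variant, a random ``decoy_fraction`` of other sites get protein-impact
    labels, and the rest are intergenic. Annotation itself is an input to the
    pipeline, so labels are assigned, not predicted."""
    rng = np.random.default_rng([seed, _RNG_CONSEQ])
    out = sites.copy()
    n = len(out)
    conseq = np.full(n, "intergenic_region", dtype=object)
    decoys = rng.random(n) < decoy_fraction
    conseq[decoys] = rng.choice(_DECOY_CONSEQUENCES, size=int(decoys.sum()))
    causal_mask = (out["chrom"] == causal_chrom) & (out["pos"] == causal_pos)
    conseq[causal_mask.to_numpy()] = "splice_donor_variant"
    out["consequence"] = conseq
    return out


def make_prioritization_fixture(seed: int = 0):
    """Deterministic fixture mirroring the study's candidate cascade counts.

    Inside a 5.4 Mb interval it plants 69 protein-impact variants: 61 with
    dAF <= 0.5, 8 with dAF > 0.5 of which exactly one (a splice-donor
    variant, dAF ~ 0.76) is absent from the reference panel. Additional
    variants that fail the quality, biallelic, depth-cap, impact, or region
    filters are sprinkled in to exercise every stage.

    Returns ``(variants, interval)`` where ``variants`` is an annotated
    PoolSite table with ``consequence`` and ``panel_alt_observed`` columns
    and ``interval`` is a one-row BED-like DataFrame.
    """
    rng = np.random.default_rng([seed, 99])
    interval = pd.DataFrame(
        {"chrom": ["chr1"], "start": [1_000_000], "end": [6_400_000]}
    )
    rows = []

    def add(pos, conseq, mut, wt, qual=500.0, alt="C", panel=0):
        rows.append(
            {
                "chrom": "chr1",
                "pos": pos,
                "ref": "A",
                "alt": alt,
                "qual": qual,
                "mut_ref": mut[0],
                "mut_alt": mut[1],
                "wt_ref": wt[0],
                "wt_alt": wt[1],
                "consequence": conseq,
                "panel_alt_observed": panel,
            }
        )

    impact_pool = ["missense_variant", "frameshift_variant", "stop_gained", "stop_lost"]
    positions = iter(range(1_050_000, 6_350_000, 55_000))

    # 61 impact variants with dAF <= 0.5 (both pools at depth 40 so dAF is
    # an exact multiple of 1/40)
    for i in range(61):
        daf_steps = int(rng.integers(0, 21))  # 0..20 -> dAF 0..0.5
        wt_alt = int(rng.integers(0, 41 - daf_steps))
        mut_alt = wt_alt + daf_steps
        add(
            next(positions),
            impact_pool[i % 4],
            (40 - mut_alt, mut_alt),
            (40 - wt_alt, wt_alt),
            panel=int(rng.integers(1, 6)),
        )
    # 7 with dAF > 0.5 but present in the panel
    for i in range(7):
        daf_steps = int(rng.integers(21, 41))  # dAF 0.525..1.0
        wt_alt = int(rng.integers(0, 41 - daf_steps))
        mut_alt = wt_alt + daf_steps
        add(
            next(positions),
            impact_pool[i % 4],
            (40 - mut_alt, mut_alt),
            (40 - wt_alt, wt_alt),
            panel=int(rng.integers(1, 6)),
        )
    # the causal splice-donor variant: dAF = |1 - 9/37| ~ 0.7568, panel-absent
    add(3_500_000, "splice_donor_variant", (0, 37), (28, 9), panel=0)

    # chaff removed by earlier stages
    for i in range(8):  # low/modifier impact
        add(next(positions), ["synonymous_variant", "intron_variant"][i % 2], (10, 30), (30, 10))
    for i in range(4):  # below the quality threshold
        add(next(positions), "missense_variant", (5, 35), (35, 5), qual=150.0)
    for i in range(3):  # multiallelic records
        add(next(positions), "missense_variant", (5, 35), (35, 5), alt="C,T")
    for i in range(4):  # repetitive-region depth blowups
        add(next(positions), "missense_variant", (40, 360), (360, 40))
    for i in range(5):  # strong variants outside the interval
        add(8_000_000 + i * 10_000, "missense_variant", (0, 40), (40, 0))

    variants = pd.DataFrame(rows).sort_values("pos").reset_index(drop=True)
    return variants, interval
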
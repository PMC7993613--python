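"""Candidate-variant prioritization cascade.

Reduces the variants inside a mapped interval to ranked causal candidates by
intersecting pure filters: region, quality/biallelic, per-pool depth cap,
annotation impact class, pool allele-frequency differentiation, and absence
from a reference panel. Filters are idempotent intersections, so the final
set is independent of their order; the stage-count report is not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .poolscan import delta_af_table

__all__ = [
    "DEFAULT_IMPACT_TABLE",
    "classify_impact",
    "depth_cap_filter",
    "quality_biallelic_filter",
    "impact_filter",
    "daf_criterion",
    "panel_absence_filter",
    "annotate_panel_presence",
    "region_filter",
    "prioritize",
    "CascadeReport",
]

log = logging.getLogger(__name__)

# Conventional SnpEff-style consequence -> impact class mapping, editable by
# callers. Annotation is consumed as input; only the class lookup lives here.
DEFAULT_IMPACT_TABLE: dict[str, str] = {
    "chromosome_number_variation": "HIGH",
    "exon_loss_variant": "HIGH",
    "frameshift_variant": "HIGH",
    "rare_amino_acid_variant": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "start_lost": "HIGH",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "transcript_ablation": "HIGH",
    "coding_sequence_variant": "MODERATE",
    "disruptive_inframe_deletion": "MODERATE",
    "disruptive_inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "inframe_insertion": "MODERATE",
    "missense_variant": "MODERATE",
    "regulatory_region_ablation": "MODERATE",
    "initiator_codon_variant": "LOW",
    "splice_region_variant": "LOW",
    "start_retained_variant": "LOW",
    "stop_retained_variant": "LOW",
    "synonymous_variant": "LOW",
    "3_prime_UTR_variant": "MODIFIER",
    "5_prime_UTR_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
    "intergenic_region": "MODIFIER",
    "intragenic_variant": "MODIFIER",
    "intron_variant": "MODIFIER",
    "non_coding_transcript_variant": "MODIFIER",
    "upstream_gene_variant": "MODIFIER",
    # short aliases
    "missense": "MODERATE",
    "nonsynonymous": "MODERATE",
    "frameshift": "HIGH",
    "splice_donor": "HIGH",
    "splice_acceptor": "HIGH",
    "synonymous": "LOW",
    "intergenic": "MODIFIER",
    "intron": "MODIFIER",
}

_IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")


def classify_impact(consequence: str, table: dict[str, str] | None = None) -> str | None:
    """Map a consequence label to HIGH/MODERATE/LOW/MODIFIER.

    Unknown labels yield None with a warning; callers exclude such variants.
    """
    table = DEFAULT_IMPACT_TABLE if table is None else table
    impact = table.get(consequence)
    if impact is None:
        warnings.warn(f"unknown consequence label {consequence!r}; variant excluded")
    return impact


def _pool_depths(sites: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    return sites["mut_ref"] + sites["mut_alt"], sites["wt_ref"] + sites["wt_alt"]


def depth_cap_filter(
    sites: pd.DataFrame,
    mean_depths: tuple[float, float] | None = None,
    multiplier: float = 2.0,
) -> pd.DataFrame:
    """Discard sites whose depth in either pool strictly exceeds
    ``multiplier`` times that pool's genome-wide mean depth.

    ``mean_depths`` defaults to the means of the supplied table; pass the
    genome-wide values explicitly when filtering a regional subset.
    """
    dm, dw = _pool_depths(sites)
    if mean_depths is None:
        mean_depths = (float(dm.mean()), float(dw.mean()))
    if min(mean_depths) <= 0 or np.isnan(mean_depths).any():
        raise ValueError("mean depths must be positive")
    keep = (dm <= multiplier * mean_depths[0]) & (dw <= multiplier * mean_depths[1])
    return sites[keep]


def quality_biallelic_filter(sites: pd.DataFrame, min_qual: float = 200.0) -> pd.DataFrame:
    """Retain biallelic SNV records with qual >= min_qual.

    A record is biallelic when its alt field holds exactly one allele (no
    comma-separated alternates).
    """
    alt = sites["alt"].astype(str)
    biallelic = ~alt.str.contains(",")
    return sites[(sites["qual"] >= min_qual) & biallelic]


def impact_filter(
    variants: pd.DataFrame, table: dict[str, str] | None = None
) -> pd.DataFrame:
    """Retain variants whose consequence maps to MODERATE or HIGH impact."""
    impacts = variants["consequence"].map(lambda c: classify_impact(c, table))
    return variants[impacts.isin(["MODERATE", "HIGH"])]


def daf_criterion(variants: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Retain variants with dAF strictly greater than ``threshold``.

    Uses an existing ``daf`` column when present, otherwise computes it from
    the pooled counts.
    """
    if "daf" in variants.columns:
        daf = variants["daf"]
    else:
        daf, _ = delta_af_table(variants)
    return variants[daf > threshold]


def annotate_panel_presence(variants: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Attach panel_alt_observed: the number of panel samples carrying the
    alt allele at each variant position.

    Positions absent from the panel table count as unobserved (0) and are
    logged, not dropped.
    """
    sample_cols = [c for c in panel.columns if c not in ("chrom", "pos")]
    carriers = (panel[sample_cols].to_numpy() > 0).sum(axis=1)
    lookup = pd.DataFrame(
        {"chrom": panel["chrom"], "pos": panel["pos"], "panel_alt_observed": carriers}
    )
    out = variants.drop(columns=["panel_alt_observed"], errors="ignore").merge(
        lookup, on=["chrom", "pos"], how="left"
    )
    missing = out["panel_alt_observed"].isna()
    if missing.any():
        log.info("%d variant position(s) absent from panel; treated as unobserved", missing.sum())
    out["panel_alt_observed"] = out["panel_alt_observed"].fillna(0).astype(int)
    out.index = variants.index
    return out


def panel_absence_filter(
    variants: pd.DataFrame, panel: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Retain variants whose alt allele is seen in zero panel samples."""
    if "panel_alt_observed" not in variants.columns:
        if panel is None:
            raise ValueError("need a panel table or a panel_alt_observed column")
        variants = annotate_panel_presence(variants, panel)
    return variants[variants["panel_alt_observed"] == 0]


def region_filter(variants: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Retain variants inside any of the BED-style (0-based half-open) intervals."""
    if intervals.empty:
        return variants.iloc[0:0]
    keep = np.zeros(len(variants), dtype=bool)
    pos0 = variants["pos"].to_numpy() - 1  # to 0-based
    chrom = variants["chrom"].to_numpy()
    for _, iv in intervals.iterrows():
        keep |= (chrom == iv["chrom"]) & (pos0 >= iv["start"]) & (pos0 < iv["end"])
    return variants[keep]


@dataclass
class CascadeReport:
    """Stage-by-stage survivor counts plus the final ranked candidates."""

    stages: list[tuple[str, int]]
    candidates: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_variants"])


def prioritize(
    variants: pd.DataFrame,
    intervals: pd.DataFrame,
    panel: pd.DataFrame | None = None,
    min_qual: float = 200.0,
    daf_threshold: float = 0.5,
    depth_multiplier: float = 2.0,
    impact_table: dict[str, str] | None = None,
    mean_depths: tuple[float, float] | None = None,
) -> CascadeReport:
    """Run the full cascade and rank the survivors.

    Depth-cap means are computed over the *input* table (a genome-wide
    quantity) unless supplied. Final candidates are ranked by dAF descending,
    then position ascending.
    """
    if mean_depths is None and len(variants):
        dm, dw = _pool_depths(variants)
        mean_depths = (float(dm.mean()), float(dw.mean()))

    stages: list[tuple[str, int]] = [("input", len(variants))]
    cur = region_filter(variants, intervals)
    stages.append(("region", len(cur)))
    cur = quality_biallelic_filter(cur, min_qual)
    stages.append(("quality_biallelic", len(cur)))
    if len(cur):
        cur = depth_cap_filter(cur, mean_depths, depth_multiplier)
    stages.append(("depth_cap", len(cur)))
    cur = impact_filter(cur, impact_table) if len(cur) else cur
    stages.append(("impact", len(cur)))
    cur = daf_criterion(cur, daf_threshold) if len(cur) else cur
    stages.append(("daf", len(cur)))
    if len(cur):
        cur = panel_absence_filter(cur, panel)
    stages.append(("panel_absence", len(cur)))

    cur = cur.copy()
    if "daf" not in cur.columns:
        daf, _ = delta_af_table(cur)
        cur["daf"] = daf
    cur = cur.sort_values(["daf", "pos"], ascending=[False, True]).reset_index(drop=True)
    cur.insert(0, "rank", np.arange(1, len(cur) + 1))
    return CascadeReport(stages, cur)
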
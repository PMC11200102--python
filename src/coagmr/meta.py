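"""Fixed-effect inverse-variance meta-analysis across cohorts, and
independent-locus counting for a genome-wide result set.

The meta-analysis follows the METAL effect-size scheme: per variant,
``beta_meta = Σ β_i/se_i² / Σ 1/se_i²`` and ``se_meta = (Σ 1/se_i²)^−1/2``,
after aligning every cohort's effect allele onto the first cohort that reports
the variant. Cross-cohort heterogeneity (Cochran's Q) is reported but never
used to filter. Locus counting greedily clumps genome-wide significant
variants (P < 5e−8, LD r² < 0.01, 1 Mb windows) and annotates each retained
lead variant with the nearest gene by distance to the transcription start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import two_sided_p
from .instruments import clump
from .sumstats import GeneRegion, LDMatrix, SummaryStatSet

__all__ = ["MetaAudit", "meta_analyse", "count_loci"]


@dataclass
class MetaAudit:
    n_variants: int = 0
    n_allele_mismatch: int = 0
    mismatched_ids: list = field(default_factory=list)


def _align_to_reference(ref_row, row):
    """Return the row's beta/eaf aligned to the reference allele pair, or None."""
    if row["effect_allele"] == ref_row["effect_allele"] and row["other_allele"] == ref_row["other_allele"]:
        return row["beta"], row["eaf"]
    if row["effect_allele"] == ref_row["other_allele"] and row["other_allele"] == ref_row["effect_allele"]:
        eaf = row["eaf"]
        return -row["beta"], (1.0 - eaf if pd.notna(eaf) else eaf)
    return None


def meta_analyse(cohorts: Sequence[SummaryStatSet]) -> tuple[SummaryStatSet, MetaAudit]:
    """Fixed-effect inverse-variance meta-analysis of per-variant effects.

    Variants present in a subset of cohorts are combined over that subset
    (``n_cohorts`` records how many). The first cohort reporting a variant
    fixes the allele orientation; cohorts whose allele pair matches neither
    orientation are dropped for that variant and audited. A single cohort
    passes through unchanged.
    """
    if not cohorts:
        raise ValueError("meta_analyse requires at least one cohort")
    trait_type = cohorts[0].trait_type
    if any(c.trait_type != trait_type for c in cohorts):
        raise ValueError("all cohorts must share a trait type")
    audit = MetaAudit()

    reference: dict[str, pd.Series] = {}
    acc: dict[str, dict] = {}
    for cohort in cohorts:
        for _, row in cohort.df.iterrows():
            vid = row["variant_id"]
            if vid not in reference:
                reference[vid] = row
                acc[vid] = {
                    "row": row, "betas": [], "ses": [], "ns": [], "ncases": [], "eafs": [],
                }
            aligned = _align_to_reference(reference[vid], row)
            if aligned is None:
                audit.n_allele_mismatch += 1
                audit.mismatched_ids.append(vid)
                continue
            beta, eaf = aligned
            a = acc[vid]
            a["betas"].append(float(beta))
            a["ses"].append(float(row["se"]))
            a["ns"].append(float(row["n"]))
            if "n_cases" in row and pd.notna(row.get("n_cases", np.nan)):
                a["ncases"].append(float(row["n_cases"]))
            if pd.notna(eaf):
                a["eafs"].append((float(eaf), float(row["n"])))

    records = []
    for vid, a in acc.items():
        if not a["betas"]:
            continue
        betas = np.array(a["betas"])
        ses = np.array(a["ses"])
        w = 1.0 / ses ** 2
        if len(betas) == 1:  # exact pass-through for a lone cohort
            beta_meta, se_meta = float(betas[0]), float(ses[0])
        else:
            beta_meta = float(np.sum(w * betas) / np.sum(w))
            se_meta = float(1.0 / np.sqrt(np.sum(w)))
        q = float(np.sum(w * (betas - beta_meta) ** 2))
        dfree = len(betas) - 1
        het_p = float(stats.chi2.sf(q, dfree)) if dfree > 0 else float("nan")
        ref = a["row"]
        eaf = (
            sum(e * n for e, n in a["eafs"]) / sum(n for _, n in a["eafs"])
            if a["eafs"] else np.nan
        )
        rec = {
            "variant_id": vid,
            "chromosome": ref["chromosome"],
            "position": int(ref["position"]),
            "effect_allele": ref["effect_allele"],
            "other_allele": ref["other_allele"],
            "eaf": eaf,
            "beta": beta_meta,
            "se": se_meta,
            "pval": float(two_sided_p(beta_meta / se_meta)),
            "n": float(np.sum(a["ns"])),
            "n_cohorts": len(betas),
            "het_q": q,
            "het_p": het_p,
        }
        if trait_type == "binary":
            rec["n_cases"] = float(np.sum(a["ncases"]))
        records.append(rec)
    audit.n_variants = len(records)
    df = pd.DataFrame(records).sort_values(
        ["chromosome", "position", "variant_id"], kind="mergesort"
    )
    trait_id = "meta_" + "_".join(c.trait_id for c in cohorts[:3])
    return SummaryStatSet(trait_id, trait_type, df), audit


def count_loci(
    sumstats: SummaryStatSet,
    ld: LDMatrix,
    genes: Sequence[GeneRegion],
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
    window_bp: int = 1_000_000,
    maf_min: float | None = None,
) -> pd.DataFrame:
    """Independent risk loci of a genome-wide result set.

    Clumps at P < ``p_threshold`` (strict), LD r² < ``r2_threshold`` within
    ``window_bp``; each retained lead variant is annotated with the nearest
    gene on its chromosome (smallest |position − tss|, ties broken
    lexicographically by gene id). ``maf_min`` optionally pre-filters rows by
    minor-allele frequency.
    """
    sset = sumstats
    if maf_min is not None:
        df = sset.df
        maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
        sset = SummaryStatSet(sset.trait_id, sset.trait_type, df[maf >= maf_min].copy())
    leads = clump(sset, ld, r2_threshold, p_threshold, window_bp)
    rows = []
    for vid in leads:
        row = sset.row(vid)
        chrom = str(row["chromosome"])
        cands = sorted(
            (g for g in genes if str(g.chromosome) == chrom),
            key=lambda g: (abs(int(row["position"]) - g.tss), g.gene_id),
        )
        rows.append(
            {
                "lead_variant": vid,
                "chromosome": chrom,
                "position": int(row["position"]),
                "pval": float(row["pval"]),
                "nearest_gene": cands[0].gene_id if cands else "",
            }
        )
    return pd.DataFrame(rows, columns=["lead_variant", "chromosome", "position", "pval", "nearest_gene"])
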
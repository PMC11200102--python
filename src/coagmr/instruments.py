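"""Genetic-instrument selection and validity filters.

Three selection strategies are supported, mirroring standard drug-target MR
practice:

* ``uni_cis`` — the single variant with the smallest p-value inside the gene's
  cis window; causal effect via the Wald ratio downstream.
* ``multi_cis`` — all cis variants associated at P < 5e−8, greedily clumped to
  pairwise LD r² < 0.1 inside the window.
* ``pan`` — genome-wide significant variants clumped to r² < 0.01 in 1 Mb
  windows (cis + trans; more power, more pleiotropy risk).

Validity filters: instrument strength (F-statistic, flagged weak unless F > 10),
variance explained r² = z²/(z² + n) per trait, the Steiger directionality test
(removes instruments explaining significantly more outcome than exposure
variance — the reverse-causation signature), and removal of protein-altering
variants whose association with measured protein levels may be an
epitope-binding artefact rather than a true abundance effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from ._util import two_sided_p
from .sumstats import (
    GeneRegion,
    HarmonizedPair,
    LDMatrix,
    SelectionError,
    SummaryStatSet,
    harmonize,
)

__all__ = [
    "Instrument",
    "InstrumentSet",
    "clump",
    "select_instruments",
    "instrument_strength",
    "steiger_test",
    "steiger_filter",
    "remove_altering_variants",
    "STRATEGIES",
]

STRATEGIES = ("uni_cis", "multi_cis", "pan")
GENOME_WIDE_P = 5e-8
WEAK_F_THRESHOLD = 10.0  # F must strictly exceed this to count as strong


@dataclass
class Instrument:
    pair: HarmonizedPair
    f_stat: float
    r2_exp: float
    r2_out: float
    steiger_p: float | None = None
    annotation: str = "unknown"  # altering | non_altering | unknown

    @property
    def weak(self) -> bool:
        return not (self.f_stat > WEAK_F_THRESHOLD)

    @property
    def variant_id(self) -> str:
        return self.pair.variant_id


@dataclass
class InstrumentSet:
    strategy: str
    gene: GeneRegion | None
    instruments: list[Instrument]
    clump_r2: float | None
    p_threshold: float | None
    n_exp: int
    n_out: int

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "uni_cis" and len(self.instruments) > 1:
            raise ValueError("uni_cis carries exactly one instrument")

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def pairs(self) -> list[HarmonizedPair]:
        return [i.pair for i in self.instruments]

    @property
    def variant_ids(self) -> list[str]:
        return [i.variant_id for i in self.instruments]


def clump(
    sumstats: SummaryStatSet,
    ld: LDMatrix,
    r2_threshold: float,
    p_threshold: float,
    window_bp: int = 1_000_000,
) -> list[str]:
    """Greedy LD clumping of significant variants.

    Rows with p < ``p_threshold`` (strict) are ranked by ascending p-value
    (ties: position, then variant id). Repeatedly the best remaining variant is
    retained and every remaining variant within ``window_bp`` of it (same
    chromosome) with LD r² >= ``r2_threshold`` is discarded. Variants absent
    from the LD matrix are dropped up front. The result is pairwise r² <
    ``r2_threshold`` within windows and independent of input row order.
    """
    df = sumstats.df
    mask = df["pval"] < p_threshold
    cand = df[mask & df["variant_id"].isin(set(ld.variant_ids))]
    cand = cand.sort_values(["pval", "position", "variant_id"], kind="mergesort")
    ids = cand["variant_id"].to_list()
    pos = dict(zip(cand["variant_id"], cand["position"].astype(int)))
    chrom = dict(zip(cand["variant_id"], cand["chromosome"].astype(str)))
    kept: list[str] = []
    remaining = list(ids)
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        li = ld.index(lead)
        survivors = []
        for v in remaining:
            if chrom[v] == chrom[lead] and abs(pos[v] - pos[lead]) <= window_bp:
                r = ld.r[li, ld.index(v)]
                if r * r >= r2_threshold:
                    continue
            survivors.append(v)
        remaining = survivors
    return kept


def instrument_strength(pair: HarmonizedPair, n_exp: int, n_out: int) -> tuple[float, float, float]:
    """F-statistic and variance explained per trait.

    F = (beta_exp/se_exp)²; r² = z²/(z² + n) for each trait, a frequency-free
    approximation valid for standardized quantitative traits and applied to the
    observed log-odds scale for binary traits.
    """
    if n_exp <= 2 or n_out <= 2:
        raise ValueError("sample sizes must exceed 2")
    z_exp = pair.beta_exp / pair.se_exp
    z_out = pair.beta_out / pair.se_out
    f_stat = z_exp ** 2
    r2_exp = z_exp ** 2 / (z_exp ** 2 + n_exp)
    r2_out = z_out ** 2 / (z_out ** 2 + n_out)
    return float(f_stat), float(r2_exp), float(r2_out)


def r2_from_eaf(pair: HarmonizedPair) -> float:
    """Frequency-based alternative r² = 2 f (1-f) beta² (standardized trait)."""
    if pair.eaf is None:
        raise ValueError("eaf required for frequency-based r2")
    return float(2.0 * pair.eaf * (1.0 - pair.eaf) * pair.beta_exp ** 2)


def steiger_test(r2_exp: float, r2_out: float, n_exp: int, n_out: int) -> tuple[float, str]:
    """Two-sided test of equal variance explained in exposure vs outcome.

    The correlations sqrt(r²) from the two (independent) samples are compared on
    Fisher's z scale: statistic (z_exp − z_out) / sqrt(1/(n_exp−3) + 1/(n_out−3)).
    Returns (p, direction) with direction 'forward' when the exposure explains at
    least as much variance as the outcome.
    """
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("Steiger test requires n > 3 in both samples")
    z_e = math.atanh(min(math.sqrt(max(r2_exp, 0.0)), 1 - 1e-15))
    z_o = math.atanh(min(math.sqrt(max(r2_out, 0.0)), 1 - 1e-15))
    denom = math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    stat = (z_e - z_o) / denom
    p = float(two_sided_p(stat))
    return p, ("forward" if r2_exp >= r2_out else "reverse")


def select_instruments(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    ld: LDMatrix,
    gene: GeneRegion | None,
    strategy: str,
    p_threshold: float = GENOME_WIDE_P,
    palindromic_eaf_limit: float = 0.42,
    proxy_r2_min: float = 0.6,
) -> InstrumentSet:
    """Select, harmonize and diagnose instruments under a named strategy."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy in ("uni_cis", "multi_cis"):
        if gene is None:
            raise SelectionError(f"{strategy} requires a gene region")
        window = exposure.in_region(gene)
        if len(window) == 0:
            raise SelectionError(f"no exposure variants in the cis window of {gene.gene_id}")
    if strategy == "uni_cis":
        top = window.df.sort_values(["pval", "position", "variant_id"], kind="mergesort").iloc[0]
        selected = [top["variant_id"]]
        clump_r2 = None
        p_thr = None
    elif strategy == "multi_cis":
        clump_r2 = 0.1
        p_thr = p_threshold
        selected = clump(window, ld, clump_r2, p_thr, window_bp=2 * gene.window_bp)
    else:  # pan
        clump_r2 = 0.01
        p_thr = p_threshold
        selected = clump(exposure, ld, clump_r2, p_thr, window_bp=1_000_000)
    if not selected:
        raise SelectionError(
            f"no instrument passed selection for {exposure.trait_id} under {strategy}"
        )

    pairs, _ = harmonize(
        exposure.subset(selected), outcome, ld,
        palindromic_eaf_limit=palindromic_eaf_limit, proxy_r2_min=proxy_r2_min,
    )
    if not pairs:
        raise SelectionError(
            f"no variant of {exposure.trait_id} could be harmonized against "
            f"{outcome.trait_id} under {strategy} (no overlap or proxy)"
        )
    n_exp = int(exposure.df["n"].median())
    n_out = int(outcome.df["n"].median())
    instruments = []
    for pair in pairs:
        f_stat, r2_exp, r2_out = instrument_strength(pair, n_exp, n_out)
        p_steiger, _ = steiger_test(r2_exp, r2_out, n_exp, n_out)
        instruments.append(Instrument(pair, f_stat, r2_exp, r2_out, steiger_p=p_steiger))
    return InstrumentSet(strategy, gene, instruments, clump_r2, p_thr, n_exp, n_out)


def steiger_filter(
    instrument_set: InstrumentSet, alpha: float = 0.05
) -> tuple[InstrumentSet, list[str]]:
    """Remove instruments whose outcome variance explained significantly exceeds
    the exposure's (reverse-causation signature). Idempotent."""
    kept, removed = [], []
    for inst in instrument_set.instruments:
        p, direction = steiger_test(
            inst.r2_exp, inst.r2_out, instrument_set.n_exp, instrument_set.n_out
        )
        inst = replace(inst, steiger_p=p)
        if direction == "reverse" and inst.r2_out > inst.r2_exp and p < alpha:
            removed.append(inst.variant_id)
        else:
            kept.append(inst)
    return replace(instrument_set, instruments=kept), removed


def remove_altering_variants(
    instrument_set: InstrumentSet, annotations: Mapping[str, str]
) -> tuple[InstrumentSet, dict]:
    """Drop instruments annotated as protein-altering (epitope-artefact guard).

    ``annotations`` maps variant_id -> {'altering', 'non_altering'}; unannotated
    instruments are retained as 'unknown' and counted in the audit.
    """
    kept, removed, unknown = [], [], 0
    for inst in instrument_set.instruments:
        flag = annotations.get(inst.variant_id, "unknown")
        if flag not in ("altering", "non_altering", "unknown"):
            raise ValueError(f"unknown annotation flag {flag!r} for {inst.variant_id}")
        inst = replace(inst, annotation=flag)
        if flag == "altering":
            removed.append(inst.variant_id)
        else:
            if flag == "unknown":
                unknown += 1
            kept.append(inst)
    audit = {"removed": removed, "n_unknown": unknown}
    return replace(instrument_set, instruments=kept), audit


def read_annotations(path) -> dict[str, str]:
    """Read a two-column TSV (variant_id, flag in {altering, non_altering})."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if not {"variant_id", "flag"}.issubset(df.columns):
        raise ValueError(f"{path}: annotation file needs columns variant_id, flag")
    bad = set(df["flag"]) - {"altering", "non_altering"}
    if bad:
        raise ValueError(f"{path}: invalid annotation flags {sorted(bad)}")
    return dict(zip(df["variant_id"].astype(str), df["flag"]))
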
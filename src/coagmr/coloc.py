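"""Bayesian colocalization of two traits via per-variant approximate Bayes factors.

Under the single-causal-variant assumption, each variant's evidence of
association with a trait is summarized by the Wakefield approximate Bayes
factor: with ``V = se²`` and ``z = beta/se``,

    log ABF = 0.5 * ln(V / (V + w)) + (z²/2) * (w / (V + w)),

where ``w`` is the prior variance of the true effect. Accumulating these over
the region yields posterior probabilities of five hypotheses: H0 no
association, H1/H2 association with one trait only, H3 two distinct causal
variants, H4 one shared causal variant. Evidence for H4 argues against the MR
association being an artefact of linkage disequilibrium between distinct
causal variants.

Priors default to p1 = p2 = 1e−4 (per-variant association with each trait) and
p12 = 1e−5 (association with both); colocalization is called at PPH4 > 0.50,
i.e. when the shared-variant hypothesis is more likely than all others
combined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import GeneRegion, SummaryStatSet

__all__ = ["ColocPriors", "ColocResult", "RegionError", "wakefield_labf", "colocalize"]


class RegionError(ValueError):
    """The two traits share no variants in the requested region."""


@dataclass(frozen=True)
class ColocPriors:
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w_quant: float = 0.2 ** 2  # prior effect variance, quantitative traits (SD units)
    w_cc: float = 0.15 ** 2    # prior effect variance, case-control traits (log-odds)

    def __post_init__(self):
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.w_quant < 0 or self.w_cc < 0:
            raise ValueError("prior effect variances must be >= 0")
        if self.p12 > min(self.p1, self.p2):
            warnings.warn("p12 exceeds min(p1, p2); unusual prior configuration")

    def w_for(self, trait_type: str) -> float:
        return self.w_cc if trait_type == "binary" else self.w_quant


@dataclass
class ColocResult:
    pph: np.ndarray  # PPH0..PPH4, sums to 1
    n_snps: int
    variant_ids: list[str]
    labf1: np.ndarray
    labf2: np.ndarray

    def __post_init__(self):
        if abs(float(np.sum(self.pph)) - 1.0) > 1e-9:
            raise ValueError("posterior probabilities must sum to 1")

    @property
    def pph4(self) -> float:
        return float(self.pph[4])

    @property
    def colocalized(self) -> bool:
        return self.pph4 > 0.50

    def as_dict(self) -> dict:
        d = {f"pph{i}": float(self.pph[i]) for i in range(5)}
        d["n_snps"] = self.n_snps
        d["colocalized"] = self.colocalized
        return d


def wakefield_labf(beta: float, se: float, w: float) -> float:
    """Log approximate Bayes factor for one variant-trait association."""
    if se <= 0:
        raise ValueError("se must be positive")
    if w == 0:
        return 0.0
    v = se * se
    z = beta / se
    shrink = w / (v + w)
    return 0.5 * math.log(v / (v + w)) + 0.5 * z * z * shrink


def _labf_array(df: pd.DataFrame, w: float) -> np.ndarray:
    v = df["se"].to_numpy() ** 2
    z = df["beta"].to_numpy() / df["se"].to_numpy()
    shrink = w / (v + w)
    if w == 0:
        return np.zeros(len(df))
    return 0.5 * np.log(v / (v + w)) + 0.5 * z * z * shrink


def colocalize(
    trait1: SummaryStatSet,
    trait2: SummaryStatSet,
    region: GeneRegion | None = None,
    priors: ColocPriors | None = None,
) -> ColocResult:
    """Five-hypothesis colocalization posterior over the shared variants of a region.

    Variants are joined on id; allele pairs must match in either orientation
    (the Bayes factor depends on z², so orientation itself is immaterial).
    Accumulations run in log space; H3's sum over distinct-variant pairs uses
    the stable identity log(e^{S1+S2} − e^{S12}), clipped to −inf when rounding
    makes the argument non-positive. Single-variant regions have PPH3 = 0.
    """
    priors = priors or ColocPriors()
    d1 = trait1.in_region(region).df if region is not None else trait1.df
    d2 = trait2.in_region(region).df if region is not None else trait2.df
    merged = d1.merge(d2, on="variant_id", suffixes=("_1", "_2"))
    if len(merged):
        a1 = merged["effect_allele_1"]
        o1 = merged["other_allele_1"]
        a2 = merged["effect_allele_2"]
        o2 = merged["other_allele_2"]
        ok = ((a1 == a2) & (o1 == o2)) | ((a1 == o2) & (o1 == a2))
        merged = merged[ok]
    if merged.empty:
        raise RegionError(
            f"no shared variants between {trait1.trait_id} and {trait2.trait_id}"
            + (f" in {region.gene_id}" if region is not None else "")
        )

    labf1 = _labf_array(
        merged.rename(columns={"beta_1": "beta", "se_1": "se"}), priors.w_for(trait1.trait_type)
    )
    labf2 = _labf_array(
        merged.rename(columns={"beta_2": "beta", "se_2": "se"}), priors.w_for(trait2.trait_type)
    )

    s1 = logsumexp(labf1)
    s2 = logsumexp(labf2)
    s12 = logsumexp(labf1 + labf2)
    # H3: sum over ordered pairs j != k of ABF1_j * ABF2_k
    if len(merged) > 1 and s1 + s2 > s12:
        s3 = s1 + s2 + math.log1p(-math.exp(s12 - (s1 + s2)))
    else:
        s3 = -math.inf

    log_h = np.array(
        [
            0.0,
            math.log(priors.p1) + s1,
            math.log(priors.p2) + s2,
            (math.log(priors.p1) + math.log(priors.p2) + s3) if np.isfinite(s3) else -math.inf,
            math.log(priors.p12) + s12,
        ]
    )
    pph = np.exp(log_h - logsumexp(log_h))
    pph = pph / pph.sum()
    return ColocResult(
        pph=pph,
        n_snps=int(len(merged)),
        variant_ids=merged["variant_id"].tolist(),
        labf1=labf1,
        labf2=labf2,
    )
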
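"""Synthetic GWAS summary statistics with known ground truth.

Real pQTL/eQTL and outcome GWAS inputs are biobank-scale external downloads; this
module generates summary-level data with the same statistical anatomy so that every
downstream stage (harmonization, instrument selection, MR estimation, colocalization,
meta-analysis) can be tested against a known truth.

Generative model
----------------
A region of ``n_snps`` variants carries AR(1) linkage disequilibrium,
``r(i, j) = ld_rho^|i-j|``, which is positive definite by construction. Causal
per-allele effects ``b_causal`` are placed per scenario and the *marginal* (GWAS)
effects follow ``b_marg = R @ b_causal``. Observed effects are drawn around
``b_marg`` with the standard summary-statistic sampling error

* quantitative traits: ``se = 1 / sqrt(2 f (1-f) n)`` (phenotype in SD units),
* binary traits (log-odds): ``se = 1 / sqrt(2 f (1-f) n_cases (1 - n_cases/n))``,

where ``f`` is the effect-allele frequency. Noise is independent per SNP by
default (ratio-based MR stays analytically tractable); a multivariate option
draws noise with the LD correlation for colocalization experiments.

For Mendelian randomization scenarios the outcome's causal effects are
``theta * b_exp + alpha`` at the instrument variants, with ``alpha = 0`` for valid
instruments and ``alpha ~ Normal(mu_alpha, pleiotropy_sd^2)`` for pleiotropic
ones. The reverse-causation scenario plants outcome-causal variants whose
exposure associations are a downstream "leak", so the variance explained in the
outcome exceeds that in the exposure — the signature the Steiger test detects.

Default sample sizes mirror the study the pipeline is designed around: a
discovery protein GWAS of 35,559 individuals and a venous-thromboembolism
meta-analysis of 44,223 cases among 891,375 participants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import two_sided_p
from .sumstats import GeneRegion, HarmonizedPair, LDMatrix, SummaryStatSet, write_ld_matrix, write_sumstats

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_ld_matrix",
    "simulate_coloc_region",
    "simulate_mr_study",
    "write_study",
    "simulate_panel",
]

COLOC_SCENARIOS = ("h0", "h1", "h2", "h3", "h4")
MR_SCENARIOS = ("mr_forward", "mr_reverse")

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))  # non-palindromic


class ParameterError(ValueError):
    """A simulation parameter is outside its admissible range."""


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults are the study conditions."""

    n_snps: int = 200
    ld_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exp: int = 35_559
    n_out: int = 891_375
    n_cases: int | None = 44_223
    theta: float | None = None
    n_valid: int = 50
    n_pleiotropic: int = 0
    pleiotropy_sd: float = 0.0
    mu_alpha: float = 0.0
    scenario: str = "mr_forward"
    seed: int = 0
    # causal effect sizes (per-allele, exposure in SD units, outcome in log-odds)
    causal_beta_exp: float = 0.1
    causal_beta_out: float = 0.1
    # per-allele exposure effects of instruments: z ~ 18-37 at the default n_exp,
    # the strength range typical of discovery-cohort cis-pQTLs
    instrument_beta_range: tuple[float, float] = (0.15, 0.3)
    reverse_beta_out: float = 0.6
    reverse_leak: float = 0.125
    outcome_binary: bool = True
    multivariate_noise: bool = False
    #: when set, sampling noise uses its own stream so replicates can share
    #: structure (variants, frequencies, causal effects) while varying noise
    noise_seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.ld_rho < 1.0):
            raise ParameterError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if self.n_valid + self.n_pleiotropic > self.n_snps:
            raise ParameterError("n_valid + n_pleiotropic exceeds n_snps")
        if self.pleiotropy_sd < 0:
            raise ParameterError("pleiotropy_sd must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must lie within (0, 0.5]")


@dataclass
class Truth:
    """Ground truth attached to a synthetic study."""

    scenario: str
    theta: float | None
    causal_exp_idx: list[int]
    causal_out_idx: list[int]
    instrument_idx: list[int]
    alpha: np.ndarray  # direct (pleiotropic) outcome effects per instrument
    b_exp_marg: np.ndarray
    b_out_marg: np.ndarray


@dataclass
class SyntheticStudy:
    exposure: SummaryStatSet
    outcome: SummaryStatSet
    ld: LDMatrix
    truth: Truth
    gene: GeneRegion

    def instrument_pairs(self) -> list[HarmonizedPair]:
        """Harmonized exposure/outcome pairs at the planted instrument variants
        (alleles are shared by construction, so alignment is the identity)."""
        pairs = []
        for i in self.truth.instrument_idx:
            e = self.exposure.df.iloc[i]
            o = self.outcome.df.iloc[i]
            pairs.append(
                HarmonizedPair(
                    variant_id=e["variant_id"],
                    beta_exp=float(e["beta"]),
                    se_exp=float(e["se"]),
                    beta_out=float(o["beta"]),
                    se_out=float(o["se"]),
                    eaf=float(e["eaf"]),
                )
            )
        return pairs


def simulate_ld_matrix(n_snps: int, ld_rho: float, seed: int | None = None) -> LDMatrix:
    """AR(1) LD: r(i, j) = ld_rho^|i-j|; positive definite for 0 <= ld_rho < 1."""
    if not (0.0 <= ld_rho < 1.0):
        raise ParameterError(f"ld_rho must be in [0, 1), got {ld_rho}")
    idx = np.arange(n_snps)
    r = ld_rho ** np.abs(idx[:, None] - idx[None, :])
    ids = tuple(_variant_ids(n_snps))
    return LDMatrix(ids, r)


def _variant_ids(n_snps: int, prefix: str = "rs") -> list[str]:
    width = len(str(n_snps))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n_snps)]


def se_quantitative(f: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n)


def se_binary(f: np.ndarray, n: int, n_cases: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n_cases * (1.0 - n_cases / n))


def _variant_frame(cfg: SimulationConfig, rng, chromosome="1", start=100_000, spacing=2_000,
                   prefix="rs"):
    n = cfg.n_snps
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    ea = [_ALLELE_PAIRS[k][0] for k in pair_idx]
    oa = [_ALLELE_PAIRS[k][1] for k in pair_idx]
    return pd.DataFrame(
        {
            "variant_id": _variant_ids(n, prefix),
            "chromosome": chromosome,
            "position": start + spacing * np.arange(n),
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": maf,
        }
    )


def _sample_trait(base: pd.DataFrame, b_marg, se, noise, trait_id, trait_type,
                  n, n_cases=None) -> SummaryStatSet:
    df = base.copy()
    beta = b_marg + se * noise
    df["beta"] = beta
    df["se"] = se
    df["pval"] = two_sided_p(beta / se)
    df["n"] = n
    if trait_type == "binary":
        df["n_cases"] = n_cases
    return SummaryStatSet(trait_id, trait_type, df)


def _noise(rng, R: np.ndarray, n: int, multivariate: bool) -> np.ndarray:
    z = rng.standard_normal(n)
    if not multivariate:
        return z
    L = np.linalg.cholesky(R)
    return L @ z


def simulate_coloc_region(cfg: SimulationConfig) -> SyntheticStudy:
    """Two traits over one LD region under a named colocalization scenario.

    h4 places one shared causal variant (region midpoint); h3 two distinct causal
    variants far enough apart for near-zero LD; h1/h2 a causal variant in one
    trait only; h0 none. Trait 1 is a quantitative exposure, trait 2 a binary
    outcome by default.
    """
    if cfg.scenario not in COLOC_SCENARIOS:
        raise ParameterError(f"scenario must be one of {COLOC_SCENARIOS}, got {cfg.scenario!r}")
    if cfg.outcome_binary and cfg.n_cases is None:
        raise ParameterError("binary outcome requires n_cases")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    base = _variant_frame(cfg, rng)
    ld = simulate_ld_matrix(n, cfg.ld_rho)
    base["variant_id"] = list(ld.variant_ids)

    mid, q1, q3 = n // 2, n // 4, (3 * n) // 4
    placement = {
        "h0": ([], []),
        "h1": ([mid], []),
        "h2": ([], [mid]),
        "h3": ([q1], [q3]),
        "h4": ([mid], [mid]),
    }[cfg.scenario]
    c1, c2 = placement
    b1 = np.zeros(n)
    b2 = np.zeros(n)
    b1[c1] = cfg.causal_beta_exp
    b2[c2] = cfg.causal_beta_out
    R = ld.r
    b1_marg = R @ b1
    b2_marg = R @ b2

    f = base["eaf"].to_numpy()
    se1 = se_quantitative(f, cfg.n_exp)
    if cfg.outcome_binary:
        se2 = se_binary(f, cfg.n_out, cfg.n_cases)
    else:
        se2 = se_quantitative(f, cfg.n_out)
    nrng = rng if cfg.noise_seed is None else np.random.default_rng(cfg.noise_seed)
    z1 = _noise(nrng, R, n, cfg.multivariate_noise)
    z2 = _noise(nrng, R, n, cfg.multivariate_noise)

    exposure = _sample_trait(base, b1_marg, se1, z1, "sim_exposure", "quantitative", cfg.n_exp)
    outcome = _sample_trait(
        base, b2_marg, se2, z2, "sim_outcome",
        "binary" if cfg.outcome_binary else "quantitative",
        cfg.n_out, cfg.n_cases,
    )
    gene = GeneRegion("GENE1", "1", int(base["position"].iloc[mid]), 1_000_000)
    truth = Truth(cfg.scenario, None, list(c1), list(c2), [], np.zeros(0), b1_marg, b2_marg)
    return SyntheticStudy(exposure, outcome, ld, truth, gene)


def simulate_mr_study(cfg: SimulationConfig) -> SyntheticStudy:
    """A two-sample MR study with known causal effect and pleiotropy.

    ``mr_forward``: instrument variants get exposure effects drawn from
    ``instrument_beta_range`` with random sign; outcome causal effects are
    ``theta * b_exp + alpha``. ``mr_reverse``: variants are causal for the
    outcome and the exposure association is a fractional leak
    (``reverse_leak``), so r² in the outcome exceeds r² in the exposure.
    """
    if cfg.scenario not in MR_SCENARIOS:
        raise ParameterError(f"scenario must be one of {MR_SCENARIOS}, got {cfg.scenario!r}")
    if cfg.scenario == "mr_forward" and cfg.theta is None:
        raise ParameterError("theta must be set for MR scenarios")
    if cfg.outcome_binary and cfg.n_cases is None:
        raise ParameterError("binary outcome requires n_cases")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    m = cfg.n_valid + cfg.n_pleiotropic
    base = _variant_frame(cfg, rng)
    ld = simulate_ld_matrix(n, cfg.ld_rho)
    base["variant_id"] = list(ld.variant_ids)
    R = ld.r

    # instruments evenly spread over the region so AR(1) LD between them is negligible
    inst = np.unique(np.round(np.linspace(0, n - 1, m)).astype(int)) if m else np.array([], int)
    if len(inst) != m:
        raise ParameterError("too many instruments for n_snps (indices collide)")

    b_exp = np.zeros(n)
    b_out = np.zeros(n)
    alpha = np.zeros(m)
    if cfg.scenario == "mr_forward":
        lo, hi = cfg.instrument_beta_range
        mag = rng.uniform(lo, hi, size=m)
        sign = rng.choice([-1.0, 1.0], size=m)
        b_exp[inst] = sign * mag
        if cfg.n_pleiotropic:
            # direct effects are expressed in the oriented frame (per copy of the
            # exposure-increasing allele), so mu_alpha > 0 is directional pleiotropy
            raw = rng.normal(cfg.mu_alpha, cfg.pleiotropy_sd, size=cfg.n_pleiotropic)
            alpha[cfg.n_valid:] = np.sign(b_exp[inst][cfg.n_valid:]) * raw
        b_out[inst] = cfg.theta * b_exp[inst] + alpha
        theta = cfg.theta
    else:  # mr_reverse
        sign = rng.choice([-1.0, 1.0], size=m)
        b_out[inst] = sign * cfg.reverse_beta_out
        b_exp[inst] = cfg.reverse_leak * b_out[inst]
        theta = cfg.theta

    b_exp_marg = R @ b_exp
    b_out_marg = R @ b_out
    f = base["eaf"].to_numpy()
    se1 = se_quantitative(f, cfg.n_exp)
    if cfg.outcome_binary:
        se2 = se_binary(f, cfg.n_out, cfg.n_cases)
    else:
        se2 = se_quantitative(f, cfg.n_out)
    nrng = rng if cfg.noise_seed is None else np.random.default_rng(cfg.noise_seed)
    z1 = _noise(nrng, R, n, cfg.multivariate_noise)
    z2 = _noise(nrng, R, n, cfg.multivariate_noise)

    exposure = _sample_trait(base, b_exp_marg, se1, z1, "sim_exposure", "quantitative", cfg.n_exp)
    outcome = _sample_trait(
        base, b_out_marg, se2, z2, "sim_outcome",
        "binary" if cfg.outcome_binary else "quantitative",
        cfg.n_out, cfg.n_cases,
    )
    gene = GeneRegion("GENE1", "1", int(base["position"].iloc[n // 2]), 1_000_000)
    truth = Truth(cfg.scenario, theta, [], [], [int(i) for i in inst], alpha, b_exp_marg, b_out_marg)
    return SyntheticStudy(exposure, outcome, ld, truth, gene)


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Write a study to a directory in the pipeline's TSV formats; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": outdir / "exposure.tsv",
        "outcome": outdir / "outcome.tsv",
        "ld": outdir / "ld.tsv",
        "genes": outdir / "genes.tsv",
        "truth": outdir / "truth.json",
    }
    write_sumstats(study.exposure, paths["exposure"])
    write_sumstats(study.outcome, paths["outcome"])
    write_ld_matrix(study.ld, paths["ld"])
    pd.DataFrame(
        [{"gene_id": study.gene.gene_id, "chromosome": study.gene.chromosome, "tss": study.gene.tss}]
    ).to_csv(paths["genes"], sep="\t", index=False)
    t = study.truth
    paths["truth"].write_text(
        json.dumps(
            {
                "scenario": t.scenario,
                "theta": t.theta,
                "causal_exp_idx": t.causal_exp_idx,
                "causal_out_idx": t.causal_out_idx,
                "instrument_idx": t.instrument_idx,
                "alpha": list(map(float, t.alpha)),
            },
            indent=2,
        )
    )
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# the packaged demonstration panel
# ---------------------------------------------------------------------------

#: fixed seed of the packaged panel — part of the fixture's definition, so the
#: demonstration dataset is identical wherever it is generated
PANEL_SEED = 20240527

#: true log-odds effects per 1 SD higher exposure for the packaged panel:
#: TARGET1 mirrors a favourable anticoagulant target (protects against the
#: efficacy outcomes, null on bleeding); TARGET2 is a harmful control.
PANEL_TRUTH = {
    "TARGET1": {"vte": -0.5, "stroke": -0.3, "bleeding": 0.0},
    "TARGET2": {"vte": 0.3, "stroke": 0.2, "bleeding": 0.3},
}


def simulate_panel(outdir, seed: int = PANEL_SEED, n_snps_region: int = 151) -> dict:
    """Generate the packaged 2-exposure x 3-outcome synthetic panel.

    Each exposure is a protein with three independent cis-acting causal variants
    in its own LD block (separate chromosomes); the three outcomes share those
    blocks, with outcome effects ``theta * b_exp_marg`` per :data:`PANEL_TRUTH`
    plus sampling noise. TARGET1's causal configuration is shared with the
    efficacy outcomes (a colocalization-H4 arrangement). Writes all TSV inputs
    plus a ready-to-run pipeline config and returns the path map.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = n_snps_region
    # one dominant cis-acting causal variant at the TSS (the shared-variant,
    # colocalization-H4 arrangement) plus two weaker independent signals so the
    # multi-cis strategy has several instruments to clump
    causal_idx = [n // 5, n // 2, (4 * n) // 5]
    causal_beta = np.array([0.06, 0.12, 0.055])
    n_exp, n_out, n_cases = 35_559, 891_375, 44_223

    regions = {
        "TARGET1": {"chromosome": "4", "start": 5_000_000},
        "TARGET2": {"chromosome": "11", "start": 8_000_000},
    }
    exposures = {}
    ld_blocks = {}
    chols = {}
    frames = {}
    b_exp_margs = {}
    genes = []
    for g, (gene_id, spec) in enumerate(regions.items()):
        cfg = SimulationConfig(n_snps=n, ld_rho=0.9, seed=seed + g, n_exp=n_exp,
                               n_out=n_out, n_cases=n_cases, theta=0.0, n_valid=0)
        base = _variant_frame(cfg, rng, chromosome=spec["chromosome"],
                              start=spec["start"], prefix=f"rs{g + 1}_")
        ld = simulate_ld_matrix(n, 0.9)
        base["variant_id"] = [f"{gene_id}_{v}" for v in ld.variant_ids]
        ld = LDMatrix(tuple(base["variant_id"]), ld.r)
        b_causal = np.zeros(n)
        b_causal[causal_idx] = causal_beta
        b_marg = ld.r @ b_causal
        f = base["eaf"].to_numpy()
        se1 = se_quantitative(f, n_exp)
        chol = np.linalg.cholesky(ld.r)  # LD-correlated noise: smooth association fields
        chols[gene_id] = chol
        exposures[gene_id] = _sample_trait(
            base, b_marg, se1, chol @ rng.standard_normal(n), f"{gene_id}_protein",
            "quantitative", n_exp
        )
        ld_blocks[gene_id] = ld
        frames[gene_id] = base
        b_exp_margs[gene_id] = b_marg
        tss = int(base["position"].iloc[n // 2])
        genes.append({"gene_id": gene_id, "chromosome": spec["chromosome"], "tss": tss})

    outcomes = {}
    for out_name in ("vte", "stroke", "bleeding"):
        parts = []
        for gene_id in regions:
            base = frames[gene_id]
            theta = PANEL_TRUTH[gene_id][out_name]
            b_marg = theta * b_exp_margs[gene_id]
            f = base["eaf"].to_numpy()
            se2 = se_binary(f, n_out, n_cases)
            part = base.copy()
            beta = b_marg + se2 * (chols[gene_id] @ rng.standard_normal(n))
            part["beta"] = beta
            part["se"] = se2
            part["pval"] = two_sided_p(beta / se2)
            part["n"] = n_out
            part["n_cases"] = n_cases
            parts.append(part)
        outcomes[out_name] = SummaryStatSet(f"{out_name}_gwas", "binary",
                                            pd.concat(parts, ignore_index=True))

    # block-diagonal LD over both regions
    all_ids = [v for g in regions for v in ld_blocks[g].variant_ids]
    big = np.zeros((2 * n, 2 * n))
    for g_i, gene_id in enumerate(regions):
        sl = slice(g_i * n, (g_i + 1) * n)
        big[sl, sl] = ld_blocks[gene_id].r
    combined_ld = LDMatrix(tuple(all_ids), big)

    paths = {}
    for gene_id, sset in exposures.items():
        p = outdir / f"exposure_{gene_id.lower()}.tsv"
        write_sumstats(sset, p)
        paths[f"exposure_{gene_id}"] = p
    for name, sset in outcomes.items():
        p = outdir / f"outcome_{name}.tsv"
        write_sumstats(sset, p)
        paths[f"outcome_{name}"] = p
    write_ld_matrix(combined_ld, outdir / "ld.tsv")
    paths["ld"] = outdir / "ld.tsv"
    pd.DataFrame(genes).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    paths["genes"] = outdir / "genes.tsv"

    config = {
        "exposures": [
            {
                "file": f"exposure_{gid.lower()}.tsv",
                "dataset": "synthdata",
                "label": f"{gid}_protein",
                "trait_type": "quantitative",
                "gene": {
                    "gene_id": gid,
                    "chromosome": regions[gid]["chromosome"],
                    "tss": next(g["tss"] for g in genes if g["gene_id"] == gid),
                    "window_bp": 1_000_000,
                },
            }
            for gid in regions
        ],
        "outcomes": [
            {"file": "outcome_vte.tsv", "label": "VTE", "class": "efficacy", "trait_type": "binary"},
            {"file": "outcome_stroke.tsv", "label": "cardioembolic_stroke", "class": "efficacy", "trait_type": "binary"},
            {"file": "outcome_bleeding.tsv", "label": "bleeding", "class": "safety", "trait_type": "binary"},
        ],
        "ld": "ld.tsv",
        "strategies": ["uni_cis", "multi_cis"],
        "estimators": ["ivw_mre", "egger", "weighted_median", "contamination_mixture"],
        "coloc": {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5},
        "seed": int(seed),
    }
    cfg_path = outdir / "panel_config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    paths["config"] = cfg_path
    return {k: str(v) for k, v in paths.items()}
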
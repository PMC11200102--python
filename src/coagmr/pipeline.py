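"""Panel orchestration: many exposures x outcomes x strategies x estimators,
with per-pair colocalization and a triangulation summary.

The report mirrors the balloon-plot content of a target-prioritization study
as a flat table: one row per (exposure x outcome x strategy x method) with the
causal estimate, its inhibition-framed odds ratio, the colocalization PPH4 and
audit flags. The triangulation summary then asks, per target: are the causal
directions concordant across strategies, is the efficacy/safety profile
favourable (efficacy outcomes significant and protective while safety outcomes
are null), and does any colocalization support a shared causal variant?
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import sha256_file
from . import __version__ as _pkg_version
from .coloc import ColocPriors, RegionError, colocalize
from .estimators import (
    EstimatorError,
    PressoConfig,
    contamination_mixture,
    egger,
    ivw_mre,
    mr_presso,
    ratio_estimates,
    wald_ratio,
    weighted_median,
)
from .instruments import remove_altering_variants, select_instruments, steiger_filter
from .sumstats import (
    GeneRegion,
    SelectionError,
    read_ld_matrix,
    read_sumstats,
)

__all__ = ["AnalysisConfig", "ConfigError", "run_panel", "summarize_triangulation"]

SIGNIFICANCE_P = 0.05  # raw p-value threshold used in the triangulation summary

REPORT_COLUMNS = [
    "exposure", "dataset", "outcome", "outcome_class", "strategy", "method",
    "n_snps", "theta", "se", "ci_low", "ci_high", "pval", "or_per_sd_lower",
    "q_stat", "q_pval", "egger_intercept", "egger_intercept_p", "outliers",
    "pph4", "colocalized", "flags", "status",
]


class ConfigError(ValueError):
    """The analysis configuration is malformed or references missing files."""


@dataclass
class ExposureSpec:
    file: Path
    dataset: str
    label: str
    gene: GeneRegion
    trait_type: str = "quantitative"


@dataclass
class OutcomeSpec:
    file: Path
    label: str
    outcome_class: str  # efficacy | safety | lifespan
    trait_type: str = "binary"


@dataclass
class AnalysisConfig:
    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    ld_file: Path
    strategies: list[str]
    estimators: list[str]
    coloc_priors: ColocPriors
    seed: int = 0
    annotations: dict[str, str] = field(default_factory=dict)
    steiger_alpha: float = 0.05

    def __post_init__(self):
        if not self.exposures or not self.outcomes:
            raise ConfigError("config needs at least one exposure and one outcome")
        if not self.strategies:
            raise ConfigError("config needs a non-empty strategy list")
        for spec in [*self.exposures, *self.outcomes]:
            if not Path(spec.file).exists():
                raise ConfigError(f"input file not found: {spec.file}")
        if not Path(self.ld_file).exists():
            raise ConfigError(f"LD matrix file not found: {self.ld_file}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as e:
            raise ConfigError(f"{path}: invalid YAML ({e})") from e
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        base = path.parent
        try:
            exposures = [
                ExposureSpec(
                    file=base / e["file"],
                    dataset=e.get("dataset", "default"),
                    label=e.get("label", e["file"]),
                    gene=GeneRegion(
                        e["gene"]["gene_id"],
                        str(e["gene"]["chromosome"]),
                        int(e["gene"]["tss"]),
                        int(e["gene"].get("window_bp", 1_000_000)),
                    ),
                    trait_type=e.get("trait_type", "quantitative"),
                )
                for e in raw["exposures"]
            ]
            outcomes = [
                OutcomeSpec(
                    file=base / o["file"],
                    label=o.get("label", o["file"]),
                    outcome_class=o.get("class", "efficacy"),
                    trait_type=o.get("trait_type", "binary"),
                )
                for o in raw["outcomes"]
            ]
            coloc_raw = raw.get("coloc", {})
            priors = ColocPriors(
                p1=float(coloc_raw.get("p1", 1e-4)),
                p2=float(coloc_raw.get("p2", 1e-4)),
                p12=float(coloc_raw.get("p12", 1e-5)),
            )
            return cls(
                exposures=exposures,
                outcomes=outcomes,
                ld_file=base / raw["ld"],
                strategies=list(raw.get("strategies", ["uni_cis"])),
                estimators=list(raw.get("estimators", ["ivw_mre"])),
                coloc_priors=priors,
                seed=int(raw.get("seed", 0)),
            )
        except (KeyError, TypeError) as e:
            raise ConfigError(f"{path}: missing or malformed config field ({e})") from e


_ESTIMATOR_MIN_N = {
    "ivw_mre": 2,
    "egger": 3,
    "weighted_median": 3,
    "contamination_mixture": 1,
    "presso": 4,
}


def _run_estimator(name: str, pairs, seed: int):
    ratios = ratio_estimates(pairs)
    if name == "ivw_mre":
        return ivw_mre(ratios) if len(ratios) >= 2 else wald_ratio(pairs[0])
    if name == "egger":
        return egger(pairs)
    if name == "weighted_median":
        return weighted_median(ratios, seed=seed)
    if name == "contamination_mixture":
        return contamination_mixture(ratios)
    if name == "presso":
        return mr_presso(pairs, PressoConfig(seed=seed))
    raise ConfigError(f"unknown estimator {name!r}")


def run_panel(config: AnalysisConfig, out_dir) -> pd.DataFrame:
    """Run every exposure x outcome x strategy, write the report and provenance.

    A failure in one pair (no overlap, too few instruments, degenerate design)
    does not abort the rest: the affected row is emitted with ``status``
    naming the failure. Identical config + seed reproduce a byte-identical
    report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ld = read_ld_matrix(config.ld_file)
    priors = config.coloc_priors

    exposure_sets = {}
    for spec in config.exposures:
        sset, _ = read_sumstats(spec.file, spec.trait_type)
        sset.trait_id = spec.label
        exposure_sets[spec.label] = (spec, sset)
    outcome_sets = {}
    for spec in config.outcomes:
        sset, _ = read_sumstats(spec.file, spec.trait_type)
        sset.trait_id = spec.label
        outcome_sets[spec.label] = (spec, sset)

    rows = []
    for exp_label, (exp_spec, exp_set) in exposure_sets.items():
        for out_label, (out_spec, out_set) in outcome_sets.items():
            # colocalization over the cis region, once per pair
            pph4 = np.nan
            colocalized = None
            try:
                cres = colocalize(exp_set, out_set, exp_spec.gene, priors)
                pph4 = cres.pph4
                colocalized = cres.colocalized
            except RegionError:
                pass

            for strategy in config.strategies:
                base_row = {
                    "exposure": exp_label,
                    "dataset": exp_spec.dataset,
                    "outcome": out_label,
                    "outcome_class": out_spec.outcome_class,
                    "strategy": strategy,
                    "pph4": pph4,
                    "colocalized": colocalized,
                }
                try:
                    inst = select_instruments(
                        exp_set, out_set, ld, exp_spec.gene, strategy
                    )
                    flags = []
                    inst, alter_audit = remove_altering_variants(inst, config.annotations)
                    if alter_audit["removed"]:
                        flags.append(f"altering_removed:{len(alter_audit['removed'])}")
                    inst, steiger_removed = steiger_filter(inst, config.steiger_alpha)
                    if steiger_removed:
                        flags.append(f"steiger_removed:{len(steiger_removed)}")
                    if not inst.instruments:
                        raise SelectionError(
                            f"{exp_label} non-instrumentable under {strategy} after filters"
                        )
                    n_weak = sum(i.weak for i in inst.instruments)
                    if n_weak:
                        flags.append(f"weak_instruments:{n_weak}")
                except (SelectionError, EstimatorError) as e:
                    methods = ["wald"] if strategy == "uni_cis" else config.estimators
                    for method in methods:
                        rows.append({**base_row, "method": method, "status": f"failed: {e}"})
                    continue

                pairs = inst.pairs
                methods = ["wald"] if strategy == "uni_cis" else config.estimators
                for method in methods:
                    row = dict(base_row)
                    row["method"] = method
                    row["flags"] = ";".join(flags)
                    try:
                        if method == "wald":
                            est = wald_ratio(pairs[0])
                        else:
                            est = _run_estimator(method, pairs, config.seed)
                        if est.multimodal:
                            row["flags"] = ";".join(filter(None, [row["flags"], "multimodal_cm"]))
                        row.update(
                            n_snps=est.n_snps,
                            theta=est.theta,
                            se=est.se,
                            ci_low=est.ci_low,
                            ci_high=est.ci_high,
                            pval=est.pval,
                            or_per_sd_lower=est.or_per_sd_lower,
                            q_stat=est.q_stat,
                            q_pval=est.q_pval,
                            egger_intercept=est.egger_intercept,
                            egger_intercept_p=est.egger_intercept_p,
                            outliers=",".join(est.outliers or []),
                            status="ok",
                        )
                    except EstimatorError as e:
                        row["status"] = f"failed: {e}"
                    rows.append(row)

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    report.to_csv(out_dir / "report.tsv", sep="\t", index=False, float_format="%.10g")

    provenance = {
        "version": _pkg_version,
        "seed": config.seed,
        "inputs": {
            str(spec.file): sha256_file(spec.file)
            for spec in [*config.exposures, *config.outcomes]
        },
        "ld": sha256_file(config.ld_file),
        "strategies": config.strategies,
        "estimators": config.estimators,
    }
    (out_dir / "run_info.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    summary = summarize_triangulation(report)
    summary.to_csv(out_dir / "triangulation.tsv", sep="\t", index=False, float_format="%.10g")
    return report


def _primary_rows(report: pd.DataFrame) -> pd.DataFrame:
    """One estimate per exposure x outcome x strategy: the Wald ratio for
    uni_cis and IVW-MRE (or the first available method) otherwise."""
    ok = report[report["status"] == "ok"]
    frames = []
    for (_, _, _), grp in ok.groupby(["exposure", "outcome", "strategy"], sort=False):
        for preferred in ("wald", "ivw_mre"):
            hit = grp[grp["method"] == preferred]
            if len(hit):
                frames.append(hit.iloc[[0]])
                break
        else:
            frames.append(grp.iloc[[0]])
    if not frames:
        return ok
    return pd.concat(frames, ignore_index=True)


def summarize_triangulation(report: pd.DataFrame) -> pd.DataFrame:
    """Per exposure x outcome concordance, per-exposure profile and coloc support.

    * concordance: 'concordant' when every primary CI across strategies/datasets
      lies on the same side of 0, 'discordant' otherwise.
    * profile: 'favourable' when all efficacy outcomes are significant
      (p < 0.05) and protective (CI < 0) while all safety outcomes are null
      (p >= 0.05); 'not assessable' when either class is absent; otherwise
      'unfavourable'.
    * coloc_support: any PPH4 > 0.50 for the pair.
    """
    if report.empty:
        raise ValueError("empty report")
    primary = _primary_rows(report)

    pair_rows = []
    for (exposure, outcome), grp in primary.groupby(["exposure", "outcome"], sort=False):
        all_neg = bool((grp["ci_high"] < 0).all())
        all_pos = bool((grp["ci_low"] > 0).all())
        concordance = "concordant" if (all_neg or all_pos) and len(grp) else "discordant"
        significant = bool((grp["pval"] < SIGNIFICANCE_P).all())
        protective = all_neg
        pph4 = grp["pph4"].max()
        pair_rows.append(
            {
                "exposure": exposure,
                "outcome": outcome,
                "outcome_class": grp["outcome_class"].iloc[0],
                "n_estimates": len(grp),
                "concordance": concordance,
                "significant": significant,
                "protective": protective,
                "coloc_support": bool(pph4 > 0.50) if pd.notna(pph4) else False,
                "pph4": pph4,
            }
        )
    pairs = pd.DataFrame(pair_rows)

    profiles = {}
    for exposure, grp in pairs.groupby("exposure", sort=False):
        eff = grp[grp["outcome_class"] == "efficacy"]
        saf = grp[grp["outcome_class"] == "safety"]
        if eff.empty or saf.empty:
            profiles[exposure] = "not assessable"
        elif (
            bool((eff["significant"] & eff["protective"]).all())
            and bool((~saf["significant"]).all())
        ):
            profiles[exposure] = "favourable"
        else:
            profiles[exposure] = "unfavourable"
    pairs["profile"] = pairs["exposure"].map(profiles)
    return pairs
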
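"""GWAS summary statistics: data model, TSV readers/writers, allele harmonization
and proxy-SNP substitution.

The universal currency of the pipeline is the :class:`SummaryStatSet` — one trait's
per-variant marginal association statistics (beta on the SD scale for quantitative
traits, log-odds for binary traits). Two-sample Mendelian randomization needs the
exposure and outcome effects expressed per copy of the *same* effect allele, so
:func:`harmonize` aligns an outcome set onto an exposure set, flipping signs where
the allele pair is reported in the opposite orientation, resolving strand-ambiguous
(palindromic) variants by allele frequency, and substituting an LD proxy
(r² > 0.6 by default) when a variant is missing from the outcome study.

Coordinates are 1-based; genomic windows are inclusive on both ends. Signed LD
correlations are carried throughout so that a proxy's effect can be oriented onto
the target's effect allele.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "VariantLookupError",
    "SelectionError",
    "SummaryStatSet",
    "LDMatrix",
    "GeneRegion",
    "HarmonizedPair",
    "ProxyHit",
    "ReadAudit",
    "HarmonizeAudit",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_gene_regions",
    "harmonize",
    "find_proxy",
    "is_palindromic",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class VariantLookupError(KeyError):
    """A requested variant is absent from the structure being queried."""


class SelectionError(RuntimeError):
    """Instrument selection could not produce a valid result (e.g. empty cis window)."""


VALID_ALLELES = frozenset("ACGT")

#: canonical column name -> header name in the on-disk TSV dialect
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "variant_id",
    "chromosome": "chromosome",
    "position": "position",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "standard_error",
    "pval": "p_value",
    "n": "n",
    "n_cases": "n_cases",
}

_CORE_COLUMNS = [
    "variant_id", "chromosome", "position", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_palindromic(a1: str, a2: str) -> bool:
    """True for strand-ambiguous allele pairs (A/T or C/G)."""
    return _COMPLEMENT.get(a1) == a2


@dataclass
class ReadAudit:
    """Row-level accounting from :func:`read_sumstats`."""

    n_total: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    dropped_reasons: Counter = field(default_factory=Counter)
    n_duplicates_removed: int = 0
    n_missing_eaf: int = 0


@dataclass
class SummaryStatSet:
    """One trait's GWAS summary statistics.

    ``df`` holds canonical columns ``variant_id, chromosome, position,
    effect_allele, other_allele, eaf, beta, se, pval, n`` (+ ``n_cases`` for
    binary traits). ``variant_id`` is unique within the set.
    """

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    df: pd.DataFrame

    def __post_init__(self):
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.df["variant_id"].duplicated().any():
            raise ValueError(f"duplicate variant_id in {self.trait_id}")
        if self.trait_type == "binary":
            if "n_cases" not in self.df.columns or self.df["n_cases"].isna().any():
                raise ValueError(f"binary trait {self.trait_id} requires n_cases on all rows")
        self.df = self.df.reset_index(drop=True)
        self._index = {v: i for i, v in enumerate(self.df["variant_id"])}

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def row(self, variant_id: str) -> pd.Series:
        try:
            return self.df.iloc[self._index[variant_id]]
        except KeyError:
            raise VariantLookupError(f"{variant_id} not in {self.trait_id}") from None

    def subset(self, variant_ids: Sequence[str]) -> "SummaryStatSet":
        idx = [self._index[v] for v in variant_ids if v in self._index]
        return SummaryStatSet(self.trait_id, self.trait_type, self.df.iloc[idx].copy())

    def in_region(self, region: "GeneRegion") -> "SummaryStatSet":
        m = (self.df["chromosome"].astype(str) == str(region.chromosome)) & (
            (self.df["position"] - region.tss).abs() <= region.window_bp
        )
        return SummaryStatSet(self.trait_id, self.trait_type, self.df[m].copy())


@dataclass(frozen=True)
class LDMatrix:
    """Signed pairwise correlation ``r`` among variants of a region."""

    variant_ids: tuple
    r: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        n = len(self.variant_ids)
        if r.shape != (n, n):
            raise FormatError(f"LD matrix shape {r.shape} does not match {n} variant ids")
        if not np.allclose(r, r.T, atol=1e-12, rtol=0):
            raise FormatError("LD matrix not symmetric within 1e-12")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise FormatError("LD matrix diagonal must be 1")
        object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "_index", {v: i for i, v in enumerate(self.variant_ids)})

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise VariantLookupError(f"{variant_id} not in LD matrix") from None

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)])

    def subset(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = [self.index(v) for v in variant_ids]
        return LDMatrix(tuple(variant_ids), self.r[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        ids = list(self.variant_ids)
        return pd.DataFrame(self.r, index=ids, columns=ids)


@dataclass(frozen=True)
class GeneRegion:
    """A cis window around a gene's transcription start site.

    ``window_bp`` is the half-width: the window is [tss − window_bp, tss + window_bp],
    inclusive. The default ±1 Mb matches the primary cis definition; a ±500 kb dialect
    is used by cohorts that only release cis summary statistics.
    """

    gene_id: str
    chromosome: str
    tss: int
    window_bp: int = 1_000_000

    def __post_init__(self):
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")

    def contains(self, chromosome: str, position: int) -> bool:
        return str(chromosome) == str(self.chromosome) and abs(position - self.tss) <= self.window_bp


@dataclass
class HarmonizedPair:
    """Exposure/outcome effects for one variant, aligned to the exposure's effect allele."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf: float | None = None
    is_proxy: bool = False
    proxy_id: str | None = None
    proxy_r: float | None = None

    def __post_init__(self):
        if self.se_exp <= 0 or self.se_out <= 0:
            raise ValueError("standard errors must be positive")
        if self.is_proxy and self.proxy_r is not None and self.proxy_r ** 2 < 0.6 - 1e-12:
            raise ValueError("proxy r^2 below the admissible threshold")


@dataclass
class ProxyHit:
    """Outcome-side fragment produced by :func:`find_proxy` for a missing variant."""

    proxy_id: str
    proxy_r: float
    beta_out: float  # already oriented per copy of the target's effect allele
    se_out: float
    eaf_out: float | None


@dataclass
class HarmonizeAudit:
    n_exposure: int = 0
    n_matched: int = 0
    n_flipped: int = 0
    n_proxied: int = 0
    n_palindromic_dropped: int = 0
    n_allele_mismatch: int = 0
    n_missing: int = 0
    mismatched_ids: list = field(default_factory=list)
    missing_ids: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sumstats(
    path,
    trait_type: str,
    column_map: Mapping[str, str] | None = None,
) -> tuple[SummaryStatSet, ReadAudit]:
    """Read a trait's summary statistics from a (possibly gzipped) TSV.

    Rows violating the per-row invariants (invalid alleles, se ≤ 0, eaf outside
    [0, 1], p outside (0, 1], position < 1, n_cases > n) are dropped and counted
    in the returned :class:`ReadAudit`; a missing eaf is retained but audited.
    Duplicate variant ids keep the row with the smaller p-value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, sep="\t", dtype={cmap["chromosome"]: str}, compression="infer")
    if df.empty:
        raise FormatError(f"{path}: empty summary-statistics file")

    required = list(_CORE_COLUMNS)
    if trait_type == "binary":
        required.append("n_cases")
    for canon in required:
        if cmap[canon] not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {cmap[canon]!r}")

    present = {canon: hdr for canon, hdr in cmap.items() if hdr in df.columns}
    df = df[[hdr for hdr in present.values()]].rename(columns={h: c for c, h in present.items()})

    audit = ReadAudit(n_total=len(df))
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("position", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "n_cases" in df.columns:
        df["n_cases"] = pd.to_numeric(df["n_cases"], errors="coerce")

    def _flag(mask: pd.Series, reason: str):
        k = int(mask.sum())
        if k:
            audit.dropped_reasons[reason] += k
        return mask

    bad = _flag(~df["effect_allele"].isin(VALID_ALLELES) | ~df["other_allele"].isin(VALID_ALLELES), "invalid_allele")
    bad |= _flag(df["effect_allele"] == df["other_allele"], "identical_alleles")
    bad |= _flag(~(df["se"] > 0), "nonpositive_se")
    bad |= _flag(df["eaf"].notna() & ~df["eaf"].between(0.0, 1.0), "eaf_out_of_range")
    bad |= _flag(~(df["pval"] > 0) | ~(df["pval"] <= 1), "pval_out_of_range")
    bad |= _flag(~(df["position"] >= 1) | (df["position"] % 1 != 0), "bad_position")
    bad |= _flag(~(df["n"] > 0) | df["beta"].isna(), "missing_core_value")
    if trait_type == "binary":
        bad |= _flag(df["n_cases"].isna() | (df["n_cases"] > df["n"]), "bad_n_cases")

    df = df[~bad].copy()
    audit.n_dropped = audit.n_total - len(df)
    audit.n_missing_eaf = int(df["eaf"].isna().sum())

    # duplicate ids: keep the smallest p-value (ties: position, then id order)
    before = len(df)
    df = df.sort_values(["pval", "position", "variant_id"], kind="mergesort")
    df = df.drop_duplicates(subset="variant_id", keep="first")
    audit.n_duplicates_removed = before - len(df)
    df = df.sort_values(["chromosome", "position", "variant_id"], kind="mergesort").reset_index(drop=True)
    df["position"] = df["position"].astype(np.int64)

    if df.empty:
        raise FormatError(f"{path}: no valid rows after filtering")
    audit.n_kept = len(df)
    trait_id = path.name
    for suffix in (".gz", ".tsv", ".txt"):
        if trait_id.endswith(suffix):
            trait_id = trait_id[: -len(suffix)]
    return SummaryStatSet(trait_id, trait_type, df), audit


def write_sumstats(sset: SummaryStatSet, path, column_map: Mapping[str, str] | None = None) -> None:
    """Write a set back to TSV (12 significant digits, lossless round-trip)."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = sset.df.copy()
    cols = [c for c in DEFAULT_COLUMN_MAP if c in df.columns]
    df = df[cols].rename(columns={c: cmap[c] for c in cols})
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_ld_matrix(path) -> LDMatrix:
    """Read a square signed-correlation matrix whose first row/column are variant ids.

    Small asymmetries are removed by averaging ``r`` with its transpose and the
    diagonal is reset to 1; entries with |r| > 1 + 1e−6 are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    r = df.to_numpy(dtype=float)
    if r.shape[0] != r.shape[1]:
        raise FormatError(f"{path}: LD matrix is not square ({r.shape[0]}x{r.shape[1]})")
    if np.any(np.abs(r) > 1 + 1e-6):
        raise FormatError(f"{path}: LD correlation outside [-1, 1]")
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(tuple(str(v) for v in df.index), r)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    ld.to_dataframe().to_csv(path, sep="\t", float_format="%.12g")


def read_gene_regions(path, window_bp: int = 1_000_000) -> list[GeneRegion]:
    """Read a gene table (gene_id, chromosome, tss) into cis regions."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    for col in ("gene_id", "chromosome", "tss"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    return [
        GeneRegion(str(row.gene_id), str(row.chromosome), int(row.tss), window_bp)
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _orient(exp_row: pd.Series, out_row: pd.Series, palindromic_eaf_limit: float):
    """Return (beta_out, se_out, eaf) aligned to the exposure's effect allele,
    'palindromic' if strand-ambiguous and unresolvable, or None on allele mismatch."""
    ea_e, oa_e = exp_row["effect_allele"], exp_row["other_allele"]
    ea_o, oa_o = out_row["effect_allele"], out_row["other_allele"]
    if {ea_e, oa_e} != {ea_o, oa_o}:
        return None
    if is_palindromic(ea_e, oa_e):
        eaf_e, eaf_o = exp_row["eaf"], out_row["eaf"]
        if pd.isna(eaf_e) or pd.isna(eaf_o):
            return "palindromic"
        if min(eaf_e, 1 - eaf_e) > palindromic_eaf_limit:
            return "palindromic"
        # align by frequency: the minor allele must agree between studies
        flip = (eaf_e < 0.5) != (eaf_o < 0.5)
        beta = -out_row["beta"] if flip else out_row["beta"]
        return float(beta), float(out_row["se"]), float(eaf_e)
    if ea_o == ea_e and oa_o == oa_e:
        return float(out_row["beta"]), float(out_row["se"]), _maybe(exp_row["eaf"])
    if ea_o == oa_e and oa_o == ea_e:
        return float(-out_row["beta"]), float(out_row["se"]), _maybe(exp_row["eaf"])
    return None


def _maybe(x):
    return None if pd.isna(x) else float(x)


def harmonize(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    ld: LDMatrix | None = None,
    palindromic_eaf_limit: float = 0.42,
    proxy_r2_min: float = 0.6,
) -> tuple[list[HarmonizedPair], HarmonizeAudit]:
    """Align outcome effects onto the exposure's effect alleles.

    For each exposure variant found in the outcome with a matching allele pair the
    outcome beta is sign-flipped when reported on the other allele. Palindromic
    variants are aligned by allele frequency when unambiguous and dropped when the
    minor-allele frequency exceeds ``palindromic_eaf_limit``. Variants absent from
    the outcome are substituted by their best LD proxy (outcome side only) when an
    LD matrix is supplied.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValueError("harmonize requires non-empty exposure and outcome sets")
    audit = HarmonizeAudit(n_exposure=len(exposure))
    pairs: list[HarmonizedPair] = []
    for _, exp_row in exposure.df.iterrows():
        vid = exp_row["variant_id"]
        if vid in outcome:
            oriented = _orient(exp_row, outcome.row(vid), palindromic_eaf_limit)
            if oriented is None:
                audit.n_allele_mismatch += 1
                audit.mismatched_ids.append(vid)
                continue
            if oriented == "palindromic":
                audit.n_palindromic_dropped += 1
                continue
            beta_out, se_out, eaf = oriented
            if beta_out != outcome.row(vid)["beta"]:
                audit.n_flipped += 1
            audit.n_matched += 1
            pairs.append(
                HarmonizedPair(
                    variant_id=vid,
                    beta_exp=float(exp_row["beta"]),
                    se_exp=float(exp_row["se"]),
                    beta_out=beta_out,
                    se_out=se_out,
                    eaf=eaf,
                )
            )
            continue
        hit = None
        if ld is not None and vid in ld:
            hit = find_proxy(vid, outcome, ld, r2_min=proxy_r2_min)
        if hit is None:
            audit.n_missing += 1
            audit.missing_ids.append(vid)
            continue
        audit.n_proxied += 1
        pairs.append(
            HarmonizedPair(
                variant_id=vid,
                beta_exp=float(exp_row["beta"]),
                se_exp=float(exp_row["se"]),
                beta_out=hit.beta_out,
                se_out=hit.se_out,
                eaf=_maybe(exp_row["eaf"]),
                is_proxy=True,
                proxy_id=hit.proxy_id,
                proxy_r=hit.proxy_r,
            )
        )
    return pairs, audit


def find_proxy(
    target: str,
    outcome: SummaryStatSet,
    ld: LDMatrix,
    r2_min: float = 0.6,
) -> ProxyHit | None:
    """Best-LD proxy for ``target`` among outcome variants present in the LD matrix.

    Selects the candidate maximizing r² with the target subject to r² > ``r2_min``
    (strict, mirroring the r² > 0.6 rule); ties are broken by smaller genomic
    position. The proxy's outcome beta is multiplied by sign(r) so it is expressed
    per copy of the target's effect allele. Returns None when nothing qualifies.
    """
    i = ld.index(target)  # raises VariantLookupError if absent
    best = None  # (r2, position, variant_id, r)
    for vid in ld.variant_ids:
        if vid == target or vid not in outcome:
            continue
        r = float(ld.r[i, ld.index(vid)])
        r2 = r * r
        if r2 <= r2_min:
            continue
        pos = int(outcome.row(vid)["position"])
        key = (-r2, pos, vid)
        if best is None or key < best[0]:
            best = (key, vid, r)
    if best is None:
        return None
    _, vid, r = best
    row = outcome.row(vid)
    sign = 1.0 if r >= 0 else -1.0
    eaf = row["eaf"]
    if pd.isna(eaf):
        eaf_out = None
    else:
        eaf_out = float(eaf) if sign > 0 else float(1.0 - eaf)
    return ProxyHit(
        proxy_id=vid,
        proxy_r=r,
        beta_out=float(sign * row["beta"]),
        se_out=float(row["se"]),
        eaf_out=eaf_out,
    )
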
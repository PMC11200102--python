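import numpy as np
import pandas as pd
import pytest

from coagmr.sumstats import LDMatrix, SummaryStatSet


ROW_DEFAULTS = {
    "chromosome": "1",
    "effect_allele": "A",
    "other_allele": "G",
    "eaf": 0.3,
    "n": 10_000,
}


def make_sumstats(rows, trait_id="trait", trait_type="quantitative"):
    """Build a SummaryStatSet from partial row dicts, filling sensible defaults."""
    full = []
    for i, row in enumerate(rows):
        r = dict(ROW_DEFAULTS)
        r.setdefault("variant_id", f"snp{i + 1}")
        r.setdefault("position", 1000 * (i + 1))
        r.update(row)
        r.setdefault("se", 0.1)
        r.setdefault("beta", 0.0)
        r.setdefault("pval", 0.5)
        if trait_type == "binary":
            r.setdefault("n_cases", r["n"] // 10)
        full.append(r)
    return SummaryStatSet(trait_id, trait_type, pd.DataFrame(full))


def make_ld(ids, r=None):
    n = len(ids)
    if r is None:
        r = np.eye(n)
    return LDMatrix(tuple(ids), np.asarray(r, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sumstats_factory():
    return make_sumstats


@pytest.fixture
def ld_factory():
    return make_ld
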
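import dataclasses

import numpy as np
import pandas as pd
import pytest

from genectx.simulate import SimConfig


@pytest.fixture
def small_config() -> SimConfig:
    """Scaled-down study conditions for fast structural tests."""
    return dataclasses.replace(
        SimConfig(),
        chromosomes=(("chrI", 200_000), ("chrII", 200_000)),
        n_genes=60,
        n_antisense=20,
        n_tf2=5,
        n_ltrs=12,
        n_tandem_short=10,
        n_tandem_long=40,
        n_g4=10,
        domain_end_span=15_000,
        interior_domain=None,
    )


def make_expression(rows: list[dict], n_rep: int = 2) -> pd.DataFrame:
    """Assemble a minimal expression table from per-gene dicts with keys
    gene_id, biotype, cond1 (list), cond2 (list), fold_change, p_value, fdr."""
    out = []
    for r in rows:
        row = {
            "gene_id": r["gene_id"],
            "biotype": r.get("biotype", "protein_coding"),
        }
        for j, v in enumerate(r.get("cond1", [1.0] * n_rep)):
            row[f"cond1_r{j + 1}"] = v
        for j, v in enumerate(r.get("cond2", [1.0] * n_rep)):
            row[f"cond2_r{j + 1}"] = v
        row["fold_change"] = r.get("fold_change", 1.0)
        row["p_value"] = r.get("p_value", 1.0)
        row["fdr"] = r.get("fdr", 1.0)
        row["de_call"] = "none"
        out.append(row)
    return pd.DataFrame(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
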
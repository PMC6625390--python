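"""The 11-feature representation of a candidate protein pair.

Feature order is fixed and documented: four structural slots followed by
seven genomic slots.  A feature table is a pandas DataFrame indexed by the
canonical (protein_a, protein_b) pair with one column per feature; NaN
encodes *missing* (no evidence source covered the pair).

The classifier consumes a *design matrix*: the 11 features after
imputation plus 11 companion ``<feature>_missing`` indicator columns, so
the forest can exploit missingness itself rather than having it hidden by
the imputed defaults.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .genomic import GENOMIC_FEATURES
from .pairs import Pair
from .structural import RMSD_DOMAIN_MAX, STRUCTURAL_FEATURES, StructuralFeatureSet

FEATURE_NAMES: tuple[str, ...] = STRUCTURAL_FEATURES + GENOMIC_FEATURES
assert len(FEATURE_NAMES) == 11

MISSING_SUFFIX = "_missing"

#: value substituted for a missing feature before training/prediction
IMPUTE_DEFAULTS: dict[str, float] = {
    "tm_score": 0.0,
    "rmsd": RMSD_DOMAIN_MAX,
    "preserved_interface_size": 0.0,
    "preserved_fraction": 0.0,
    "coexpression_pcc": 0.0,
    "go_bp_sim": 0.0,
    "go_mf_sim": 0.0,
    "go_cc_sim": 0.0,
    "phylo_profile_sim": 0.0,
    "interolog_support": 0.0,
    "gene_fusion": 0.0,
}

FEATURE_BOUNDS: dict[str, tuple[float, float]] = {
    "tm_score": (0.0, 1.0),
    "rmsd": (0.0, np.inf),
    "preserved_interface_size": (0.0, np.inf),
    "preserved_fraction": (0.0, 1.0),
    "coexpression_pcc": (-1.0, 1.0),
    "go_bp_sim": (0.0, 1.0),
    "go_mf_sim": (0.0, 1.0),
    "go_cc_sim": (0.0, 1.0),
    "phylo_profile_sim": (-1.0, 1.0),
    "interolog_support": (0.0, 6.0),
    "gene_fusion": (0.0, 1.0),
}


def empty_feature_table(pairs: Iterable[Pair]) -> pd.DataFrame:
    index = pd.MultiIndex.from_tuples(list(pairs), names=["protein_a", "protein_b"])
    return pd.DataFrame(np.nan, index=index, columns=list(FEATURE_NAMES))


def set_structural_features(
    table: pd.DataFrame, pair: Pair, features: StructuralFeatureSet | None
) -> None:
    if features is None:
        return
    table.loc[pair, "tm_score"] = features.tm_score
    table.loc[pair, "rmsd"] = features.rmsd
    table.loc[pair, "preserved_interface_size"] = features.preserved_interface_size
    table.loc[pair, "preserved_fraction"] = features.preserved_fraction


def validate_feature_table(table: pd.DataFrame) -> None:
    """Raise if columns deviate from the schema or present values leave bounds."""
    missing_cols = set(FEATURE_NAMES) - set(table.columns)
    if missing_cols:
        raise ValueError(f"feature table missing columns: {sorted(missing_cols)}")
    for name, (lo, hi) in FEATURE_BOUNDS.items():
        values = table[name].dropna()
        if ((values < lo - 1e-9) | (values > hi + 1e-9)).any():
            raise ValueError(f"feature {name!r} outside [{lo}, {hi}]")


def missing_flags(table: pd.DataFrame) -> pd.DataFrame:
    flags = table[list(FEATURE_NAMES)].isna().astype(float)
    flags.columns = [c + MISSING_SUFFIX for c in flags.columns]
    return flags


def impute(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing features with their documented defaults."""
    out = table[list(FEATURE_NAMES)].copy()
    for name, default in IMPUTE_DEFAULTS.items():
        out[name] = out[name].fillna(default)
    return out


def design_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Imputed features + missingness indicators, fixed column order."""
    return pd.concat([impute(table), missing_flags(table)], axis=1)


def feature_coverage(table: pd.DataFrame) -> pd.Series:
    """Fraction of pairs with a non-missing value, per feature.

    Mirrors the standard coverage report: pairs with available information
    in a feature divided by all candidate pairs.
    """
    return 1.0 - table[list(FEATURE_NAMES)].isna().mean()
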
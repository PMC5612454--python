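"""Phone-to-articulatory-feature mapping and feature-fit aggregation.

Each phone is characterised by binary articulatory features (place and
manner of articulation, vowel quality).  The mapping is a binary indicator
matrix chi, with chi_f(phone) = 1 when the phone exhibits feature f.  Phone
GLM coefficients beta_phone are aggregated into per-feature fits by

    fit_f = sum over phones of chi_f(phone) * beta_phone

with the GLM intercept never included.  The package ships a default
British English matrix (40 phones, six feature categories) as an editable
CSV data file; the loader treats the matrix as configuration, not code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six feature-category groups of the default matrix.
FEATURE_CATEGORIES = (
    "broad",
    "place",
    "manner",
    "frontness",
    "closeness",
    "roundedness",
)


@dataclass(frozen=True)
class FeatureMatrix:
    """Binary phone x articulatory-feature indicator matrix.

    ``indicator`` is stored feature-major: shape (n_features, n_phones),
    entry [f, p] = chi_f(phone p).  Every feature must cover at least one
    phone and every phone must carry at least one feature.
    """

    features: tuple[str, ...]
    categories: tuple[str, ...]  # one per feature
    phones: tuple[str, ...]
    indicator: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator)
        if not np.isin(ind, (0, 1)).all():
            raise ValueError("indicator entries must be 0 or 1")
        ind = ind.astype(np.int8)
        if ind.shape != (len(self.features), len(self.phones)):
            raise ValueError(
                f"indicator shape {ind.shape} does not match "
                f"{len(self.features)} features x {len(self.phones)} phones"
            )
        if len(self.categories) != len(self.features):
            raise ValueError("need one category per feature")
        if len(set(self.features)) != len(self.features):
            raise ValueError("feature names must be unique")
        if len(set(self.phones)) != len(self.phones):
            raise ValueError("phone symbols must be unique")
        empty_feats = [
            f for f, row in zip(self.features, ind) if row.sum() == 0
        ]
        if empty_feats:
            raise ValueError(
                f"feature(s) with no phones: {', '.join(empty_feats)}"
            )
        empty_phones = [
            p for p, col in zip(self.phones, ind.T) if col.sum() == 0
        ]
        if empty_phones:
            raise ValueError(
                f"phone(s) with no features: {', '.join(empty_phones)}"
            )
        object.__setattr__(self, "indicator", ind)
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "phones", tuple(self.phones))

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_phones(self) -> int:
        return len(self.phones)

    def chi(self, feature: str, phone: str) -> int:
        """Indicator chi_f(phone): 1 if the phone exhibits the feature."""
        return int(
            self.indicator[
                self.features.index(feature), self.phones.index(phone)
            ]
        )

    def phones_with(self, feature: str) -> tuple[str, ...]:
        row = self.indicator[self.features.index(feature)]
        return tuple(p for p, v in zip(self.phones, row) if v)

    def category_of(self, feature: str) -> str:
        return self.categories[self.features.index(feature)]

    def to_frame(self) -> pd.DataFrame:
        """CSV-layout DataFrame: feature, category, then one column per phone."""
        df = pd.DataFrame(self.indicator, columns=list(self.phones))
        df.insert(0, "category", list(self.categories))
        df.insert(0, "feature", list(self.features))
        return df


def load_feature_matrix(path: str | Path) -> FeatureMatrix:
    """Load a feature matrix CSV.

    Layout: first column feature name, second column category, remaining
    columns one per phone with 0/1 cells.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "feature" or df.columns[1] != "category":
        raise ValueError(
            "feature matrix CSV must start with 'feature' and 'category' "
            "columns"
        )
    phones = tuple(df.columns[2:])
    cells = df.iloc[:, 2:].to_numpy()
    if not np.isin(cells, (0, 1)).all():
        bad = df["feature"][(~np.isin(cells, (0, 1))).any(axis=1)].tolist()
        raise ValueError(f"non-binary cells in feature row(s): {bad}")
    return FeatureMatrix(
        features=tuple(df["feature"]),
        categories=tuple(df["category"]),
        phones=phones,
        indicator=cells,
    )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    fm.to_frame().to_csv(path, index=False)


def default_feature_matrix() -> FeatureMatrix:
    """The packaged default British English articulatory matrix (40 phones)."""
    with resources.as_file(
        resources.files("ssrsa.data").joinpath("articulatory_features.csv")
    ) as p:
        return load_feature_matrix(p)


def check_against_inventory(
    fm: FeatureMatrix, inventory: tuple[str, ...] | list[str]
) -> dict[str, list[str]]:
    """Report phone-by-phone mismatches between a matrix and an inventory."""
    inv = set(inventory)
    mat = set(fm.phones)
    report = {
        "missing_from_matrix": sorted(inv - mat),
        "missing_from_inventory": sorted(mat - inv),
    }
    for kind, phones in report.items():
        for p in phones:
            logger.warning("feature matrix mismatch (%s): %s", kind, p)
    return report


def feature_fit(
    betas: Mapping[str, float], feature: str, fm: FeatureMatrix
) -> float:
    """fit_f: sum of GLM phone coefficients over phones exhibiting feature f.

    Phones in the matrix without a fitted coefficient contribute 0 (logged):
    they correspond to phones dropped for lack of triphone models.  The GLM
    intercept must not be present in `betas`.
    """
    if feature not in fm.features:
        raise KeyError(f"unknown feature '{feature}'")
    missing = [p for p in fm.phones_with(feature) if p not in betas]
    if missing:
        logger.info(
            "feature '%s': no fitted beta for %s; contributing 0",
            feature,
            ", ".join(missing),
        )
    return float(
        sum(betas.get(p, 0.0) for p in fm.phones_with(feature))
    )


def all_feature_fits(
    betas: Mapping[str, float], fm: FeatureMatrix
) -> dict[str, float]:
    """fit_f for every feature in the matrix (consistent with feature_fit)."""
    beta_vec = np.array([betas.get(p, 0.0) for p in fm.phones])
    fits = fm.indicator @ beta_vec
    return dict(zip(fm.features, fits.astype(float)))
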
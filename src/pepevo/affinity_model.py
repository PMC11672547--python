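"""Random-forest regression of inhibition constants from peptide sequences.

Sequences are featurized as a one-hot block over the scaffold's variable
positions plus whole-sequence physicochemical descriptors (hydropathy, net
charge at pH 7.4, molecular weight, residue-class counts) computed from a
versioned per-residue constant table shipped with the package. The
regression target is log10(Ki / 1 nM): family Ki values span two to three
orders of magnitude, so an untransformed target would be dominated by the
weakest binders.

The tree ensemble itself is scikit-learn's ``RandomForestRegressor``
(prediction = mean of per-tree outputs); the bespoke surface here is the
featurization, the log transform, the cross-validation report, and the
percentile selection rule used to filter generated sequences.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .seq_core import AffinityRecord, Alphabet, Scaffold

logger = logging.getLogger("pepevo")

WATER_MASS = 18.02  # Da, added once per peptide chain

DESCRIPTOR_NAMES = ("mean_hydropathy", "net_charge_pH7.4", "molecular_weight",
                    "aromatic_count", "aliphatic_count", "polar_count",
                    "positive_count", "negative_count", "proline_count")


@lru_cache(maxsize=1)
def residue_descriptor_table() -> pd.DataFrame:
    """Per-residue constants (Kyte-Doolittle hydropathy, residue mass,
    charge model with D/E = -1, K/R = +1, H = 0, and class flags)."""
    with importlib.resources.files("pepevo.data").joinpath(
            "residue_descriptors.csv").open() as fh:
        return pd.read_csv(fh, index_col="residue")


@dataclass(frozen=True)
class FeatureSpec:
    """Which features enter the regressor, in a deterministic order:
    one-hot over variable positions (if enabled), then descriptors."""

    use_onehot: bool = True
    descriptors: tuple[str, ...] = DESCRIPTOR_NAMES

    def __post_init__(self) -> None:
        unknown = set(self.descriptors) - set(DESCRIPTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown descriptor name(s): {sorted(unknown)}")

    def n_features(self, scaffold: Scaffold, alphabet: Alphabet) -> int:
        n = len(self.descriptors)
        if self.use_onehot:
            n += scaffold.n_variable * alphabet.q
        return n


def _descriptor_vector(sequence: str, names: tuple[str, ...]) -> np.ndarray:
    tab = residue_descriptor_table()
    rows = tab.loc[list(sequence)]
    values = {
        "mean_hydropathy": rows["hydropathy"].mean(),
        "net_charge_pH7.4": rows["charge_ph7.4"].sum(),
        "molecular_weight": rows["residue_mass"].sum() + WATER_MASS,
        "aromatic_count": rows["aromatic"].sum(),
        "aliphatic_count": rows["aliphatic"].sum(),
        "polar_count": rows["polar"].sum(),
        "positive_count": rows["positive"].sum(),
        "negative_count": rows["negative"].sum(),
        "proline_count": sequence.count("P"),
    }
    return np.array([values[n] for n in names], dtype=float)


def featurize(sequence: str, scaffold: Scaffold,
              spec: FeatureSpec | None = None,
              alphabet: Alphabet | None = None) -> np.ndarray:
    """Deterministic feature vector for one scaffold-conformant sequence."""
    spec = spec or FeatureSpec()
    alphabet = alphabet or Alphabet()
    scaffold.check(sequence)
    parts = []
    if spec.use_onehot:
        onehot = np.zeros((scaffold.n_variable, alphabet.q))
        for k, pos in enumerate(scaffold.variable_positions):
            onehot[k, alphabet.index(sequence[pos - 1])] = 1.0
        parts.append(onehot.ravel())
    if spec.descriptors:
        parts.append(_descriptor_vector(sequence, spec.descriptors))
    return np.concatenate(parts)


def featurize_many(sequences, scaffold: Scaffold,
                   spec: FeatureSpec | None = None,
                   alphabet: Alphabet | None = None) -> np.ndarray:
    spec = spec or FeatureSpec()
    alphabet = alphabet or Alphabet()
    return np.stack([featurize(s, scaffold, spec, alphabet) for s in sequences])


@dataclass
class RegressorConfig:
    """Random-forest hyperparameters; the target transform is fixed as
    log10(Ki / 1 nM)."""

    n_trees: int = 100
    max_depth: int | None = None
    min_samples_leaf: int = 1
    max_features: float | str = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("need at least one tree")

    def to_dict(self) -> dict:
        return {"n_trees": self.n_trees, "max_depth": self.max_depth,
                "min_samples_leaf": self.min_samples_leaf,
                "max_features": self.max_features, "seed": self.seed}


@dataclass
class FitReport:
    """Cross-validated vs in-sample error, both in log10(Ki/nM) units."""

    cv_rmse: float
    train_rmse: float
    folds: int

    @property
    def overfit_gap(self) -> float:
        return self.cv_rmse - self.train_rmse

    def to_dict(self) -> dict:
        return {"cv_rmse": self.cv_rmse, "train_rmse": self.train_rmse,
                "overfit_gap": self.overfit_gap, "folds": self.folds}


def _to_log_nm(ki_molar: np.ndarray) -> np.ndarray:
    return np.log10(np.asarray(ki_molar) / 1e-9)


class KiForest:
    """Random-forest Ki regressor over a peptide affinity table."""

    def __init__(self, records: list[AffinityRecord], scaffold: Scaffold,
                 spec: FeatureSpec | None = None,
                 config: RegressorConfig | None = None,
                 alphabet: Alphabet | None = None):
        if len(records) < 5:
            raise ValueError("need at least 5 records to fit a regressor")
        self.records = list(records)
        self.scaffold = scaffold
        self.spec = spec or FeatureSpec()
        self.config = config or RegressorConfig()
        self.alphabet = alphabet or Alphabet()
        self.X = featurize_many([r.sequence for r in records], scaffold,
                                self.spec, self.alphabet)
        self.y = _to_log_nm(np.array([r.ki for r in records]))

    def _make_forest(self) -> RandomForestRegressor:
        c = self.config
        return RandomForestRegressor(
            n_estimators=c.n_trees, max_depth=c.max_depth,
            min_samples_leaf=c.min_samples_leaf, max_features=c.max_features,
            random_state=c.seed, n_jobs=1)

    def fit(self) -> "KiForestResults":
        """Train the forest and report k-fold CV error (k = min(5, n)).

        Folds are shuffled with the configured seed, so the report is
        deterministic. A constant target triggers a warning (the forest is
        still returned: it predicts the constant).
        """
        if np.allclose(self.y, self.y[0]):
            warnings.warn("constant Ki target; regressor will predict a constant")
        n = len(self.y)
        k = min(5, n)
        cv_sq = np.empty(n)
        splitter = KFold(n_splits=k, shuffle=True,
                         random_state=self.config.seed)
        for train_idx, test_idx in splitter.split(self.X):
            forest = self._make_forest()
            forest.fit(self.X[train_idx], self.y[train_idx])
            pred = forest.predict(self.X[test_idx])
            cv_sq[test_idx] = (pred - self.y[test_idx]) ** 2
        forest = self._make_forest()
        forest.fit(self.X, self.y)
        train_rmse = float(np.sqrt(np.mean((forest.predict(self.X) - self.y) ** 2)))
        report = FitReport(cv_rmse=float(np.sqrt(cv_sq.mean())),
                           train_rmse=train_rmse, folds=k)
        logger.info("KiForest fit: n=%d, cv_rmse=%.3f, train_rmse=%.3f (log10 nM)",
                    n, report.cv_rmse, report.train_rmse)
        return KiForestResults(self, forest, report)


class KiForestResults:
    """Trained forest + CV report; predictions are returned in molar."""

    def __init__(self, model_spec: KiForest, forest: RandomForestRegressor,
                 report: FitReport):
        self.spec = model_spec
        self.forest = forest
        self.report = report

    def predict_ki(self, sequences) -> np.ndarray:
        """Predicted Ki in molar: 10^yhat nM back-transformed (always > 0)."""
        X = featurize_many(sequences, self.spec.scaffold, self.spec.spec,
                           self.spec.alphabet)
        if X.shape[1] != self.spec.X.shape[1]:
            raise ValueError(
                f"feature length mismatch: got {X.shape[1]}, "
                f"model trained with {self.spec.X.shape[1]}")
        yhat = self.forest.predict(X)
        return 10.0 ** yhat * 1e-9

    def summary(self) -> str:
        r = self.report
        return "\n".join([
            "Random-forest Ki regression",
            "=" * 36,
            f"records            {len(self.spec.records):>8}",
            f"features           {self.spec.X.shape[1]:>8}",
            f"trees              {self.spec.config.n_trees:>8}",
            f"CV folds           {r.folds:>8}",
            f"cv RMSE  (log10)   {r.cv_rmse:>8.3f}",
            f"train RMSE (log10) {r.train_rmse:>8.3f}",
            f"overfit gap        {r.overfit_gap:>8.3f}",
        ])


def fit_regressor(records, scaffold, spec=None, config=None, alphabet=None
                  ) -> tuple[KiForestResults, FitReport]:
    """Functional wrapper returning (results, report)."""
    results = KiForest(records, scaffold, spec=spec, config=config,
                       alphabet=alphabet).fit()
    return results, results.report


def predict_ki(results: KiForestResults, sequences, scaffold=None,
               spec=None) -> np.ndarray:
    return results.predict_ki(sequences)


def percentile_threshold(values, pct: float = 50.0) -> float:
    """Linear-interpolation percentile of a reference set; pct=50 is the median."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty set")
    if not 0 < pct <= 100:
        raise ValueError("percentile must be in (0, 100]")
    return float(np.percentile(values, pct))


def filter_by_threshold(sequences, predictions, threshold: float
                        ) -> tuple[list, float]:
    """Keep entries with prediction strictly below the threshold.

    The published selection rule ("predicted lower than the 50th-percentile
    value") is a strict inequality; order is preserved. Returns the selected
    (sequence, prediction) pairs and the retained fraction.
    """
    sequences = list(sequences)
    predictions = np.asarray(list(predictions), dtype=float)
    if len(sequences) != len(predictions):
        raise ValueError("sequences and predictions must be parallel lists")
    selected = [(s, float(p)) for s, p in zip(sequences, predictions)
                if p < threshold]
    fraction = len(selected) / len(sequences) if sequences else 0.0
    return selected, fraction
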
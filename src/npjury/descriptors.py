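"""Physicochemical descriptor panel and min-max normalization.

Molecules are featurized with a fixed, versioned panel of RDKit 2D
descriptors (the full list minus the ``fr_`` substructure counts and the
numerically unbounded ``Ipc``), then min-max scaled to [0, 1] per column.
The scaling parameters are learned on the training matrix and applied
unchanged to screening candidates, with out-of-range values clipped so
that the jury never sees inputs outside its trained domain.

Both steps are exposed as sklearn-style transformers (``DescriptorCalculator``
and ``MinMaxNormalizer``) so they compose with pipelines; the module-level
functions are thin wrappers kept for scripting convenience.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import rdBase
from rdkit.Chem import Descriptors
from rdkit.ML.Descriptors.MoleculeDescriptors import MolecularDescriptorCalculator
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_is_fitted

from .chem import mol_from_smiles
from .errors import ConfigurationError, InputError

_EXCLUDED = {"Ipc"}  # grows combinatorially with size; AvgIpc is kept

#: Default descriptor panel: every RDKit 2D descriptor except the
#: fragment-count (``fr_``) family and ``Ipc``. Order is the toolkit's.
DEFAULT_PANEL: tuple[str, ...] = tuple(
    name
    for name, _ in Descriptors.descList
    if not name.startswith("fr_") and name not in _EXCLUDED
)


def panel_version(panel: tuple[str, ...] | list[str]) -> str:
    """Stable identifier of (toolkit version, resolved descriptor names)."""
    digest = hashlib.sha1("\n".join(panel).encode()).hexdigest()[:12]
    return f"rdkit-{rdBase.rdkitVersion}/{len(panel)}d-{digest}"


class DescriptorCalculator(TransformerMixin, BaseEstimator):
    """Compute the descriptor panel for a list of SMILES.

    Parameters
    ----------
    panel : sequence of str, optional
        Descriptor names; defaults to :data:`DEFAULT_PANEL`. Unknown names
        raise :class:`ConfigurationError`.
    max_missing_fraction : float
        A molecule whose row has more than this fraction of failed
        descriptors is dropped (and recorded in ``dropped_``).
    impute_missing : bool
        Impute the remaining sparse failures with the column median of the
        transformed matrix. With imputation on, the output has no NaNs.
    """

    def __init__(
        self,
        panel: tuple[str, ...] | list[str] | None = None,
        max_missing_fraction: float = 0.05,
        impute_missing: bool = True,
    ):
        self.panel = panel
        self.max_missing_fraction = max_missing_fraction
        self.impute_missing = impute_missing

    def _resolved_panel(self) -> tuple[str, ...]:
        panel = tuple(self.panel) if self.panel is not None else DEFAULT_PANEL
        known = {name for name, _ in Descriptors.descList}
        unknown = [p for p in panel if p not in known]
        if unknown:
            raise ConfigurationError(f"unknown descriptor names: {unknown}")
        if not panel:
            raise ConfigurationError("empty descriptor panel")
        return panel

    def fit(self, X, y=None):
        self.panel_ = self._resolved_panel()
        self.panel_version_ = panel_version(self.panel_)
        self._calc = MolecularDescriptorCalculator(list(self.panel_))
        return self

    def transform(self, X) -> pd.DataFrame:
        """Featurize SMILES strings into a (molecules x descriptors) frame.

        The index is the input SMILES (not canonicalized here — callers pass
        canonical SMILES from curation). Rows dropped for excessive
        descriptor failures are listed in ``dropped_``.
        """
        check_is_fitted(self, "panel_")
        smiles_list = list(X)
        rows = np.full((len(smiles_list), len(self.panel_)), np.nan)
        for i, smi in enumerate(smiles_list):
            mol = mol_from_smiles(smi, context=f"row {i}")
            vals = self._calc.CalcDescriptors(mol)
            rows[i] = [v if np.isfinite(v) else np.nan for v in vals]
        frame = pd.DataFrame(rows, index=smiles_list, columns=list(self.panel_))

        missing_frac = frame.isna().mean(axis=1)
        keep = missing_frac <= self.max_missing_fraction
        self.dropped_ = list(frame.index[~keep])
        frame = frame.loc[keep]
        if self.impute_missing and len(frame):
            frame = frame.fillna(frame.median())
            # a column that failed for every molecule has no median
            frame = frame.fillna(0.0)
        return frame

    def fit_transform(self, X, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


class MinMaxNormalizer(TransformerMixin, BaseEstimator):
    """Per-column min-max scaling to [0, 1], clipping out-of-range values.

    Constant columns map to 0. Backed by sklearn's ``MinMaxScaler`` with
    ``clip=True``; this wrapper pins the panel (column names must match at
    transform time) and exposes the learned (min, max) pairs for the model
    archive.
    """

    def __init__(self):
        pass

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        if X.shape[0] == 0:
            raise InputError("cannot fit a normalizer on an empty matrix")
        self.columns_ = list(X.columns)
        self._scaler = MinMaxScaler(clip=True).fit(X.to_numpy(dtype=float))
        self.data_min_ = self._scaler.data_min_.copy()
        self.data_max_ = self._scaler.data_max_.copy()
        return self

    def _check_columns(self, X: pd.DataFrame):
        if list(X.columns) != self.columns_:
            extra = sorted(set(X.columns) - set(self.columns_))
            missing = sorted(set(self.columns_) - set(X.columns))
            raise ConfigurationError(
                f"descriptor panel mismatch (missing {missing}, unexpected {extra})"
            )

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "columns_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X), columns=self.columns_)
        self._check_columns(X)
        scaled = self._scaler.transform(X.to_numpy(dtype=float))
        constant = self.data_min_ == self.data_max_
        scaled[:, constant] = 0.0
        return pd.DataFrame(scaled, index=X.index, columns=self.columns_)

    def to_dict(self) -> dict:
        check_is_fitted(self, "columns_")
        return {
            "columns": self.columns_,
            "min": [float(v) for v in self.data_min_],
            "max": [float(v) for v in self.data_max_],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MinMaxNormalizer":
        model = cls()
        frame = pd.DataFrame(
            [payload["min"], payload["max"]], columns=payload["columns"]
        )
        model.fit(frame)
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "MinMaxNormalizer":
        return cls.from_dict(json.loads(Path(path).read_text()))


def compute_descriptors(
    smiles_list, panel: tuple[str, ...] | list[str] | None = None
) -> pd.DataFrame:
    """One row of descriptor values per molecule (see DescriptorCalculator)."""
    return DescriptorCalculator(panel=panel).fit_transform(smiles_list)


def fit_normalizer(matrix: pd.DataFrame) -> MinMaxNormalizer:
    return MinMaxNormalizer().fit(matrix)


def apply_normalizer(model: MinMaxNormalizer, matrix: pd.DataFrame) -> pd.DataFrame:
    return model.transform(matrix)
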
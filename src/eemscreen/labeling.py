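"""Potency-to-label conversion and dataset assembly.

Activity labels follow the strict-threshold convention used when curating
ChEMBL-style bioactivity data: a compound is active when Ki < 100 nM
(IC50 < 200 nM) and inactive when Ki > 1000 nM (IC50 > 2000 nM).  Values
between the thresholds — including the thresholds themselves, since both
inequalities are strict — are ambiguous and never enter a dataset.

Four dataset variants are assembled against a shared set of actives:
``true_inactives`` (experimentally inactive compounds), ``dud1`` and
``dud2`` (property-matched decoys at 1:1 and 1:2 actives:decoys ratios),
and ``mixed`` (true inactives merged with the smaller, 1:1, decoy set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDatasetError, InputError
from .synthlib import ROLE_ACTIVE, ROLE_INACTIVE, SyntheticLibrary

ACTIVE = "active"
INACTIVE = "inactive"
AMBIGUOUS = "ambiguous"

PROV_ACTIVE = "active"
PROV_TRUE_INACTIVE = "true_inactive"
PROV_DECOY = "decoy"

DATASET_MODES = ("true_inactives", "dud1", "dud2", "mixed")

#: (active threshold, inactive threshold) in nM per potency measure; both
#: inequalities are strict, so the thresholds themselves are ambiguous.
THRESHOLDS_NM = {"Ki": (100.0, 1000.0), "IC50": (200.0, 2000.0)}


def assign_activity(measure: str, value_nm: float) -> str:
    """Map one potency measurement to active / inactive / ambiguous."""
    if measure not in THRESHOLDS_NM:
        raise InputError(f"unknown potency measure {measure!r}")
    value = float(value_nm)
    if not math.isfinite(value) or value <= 0.0:
        raise InputError(f"potency must be a positive finite value in nM, got {value_nm!r}")
    active_below, inactive_above = THRESHOLDS_NM[measure]
    if value < active_below:
        return ACTIVE
    if value > inactive_above:
        return INACTIVE
    return AMBIGUOUS


def label_compounds(potencies: pd.DataFrame) -> pd.Series:
    """Per-compound label from a table of potency records.

    When a compound has both Ki and IC50 records, Ki takes precedence.
    Multiple records of the preferred measure that disagree make the
    compound ambiguous.
    """
    labels: dict[str, str] = {}
    for cid, group in potencies.groupby("compound_id", sort=True):
        ki = group[group["measure"] == "Ki"]
        chosen = ki if len(ki) else group
        per_record = {
            assign_activity(row.measure, row.value_nM)
            for row in chosen.itertuples()
        }
        labels[cid] = per_record.pop() if len(per_record) == 1 else AMBIGUOUS
    return pd.Series(labels, name="label", dtype=object)


@dataclass
class LabeledDataset:
    """Fingerprint matrix with binary activity labels and provenance tags."""

    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray
    ids: np.ndarray
    scheme: str
    target: str = "synthetic"

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.y) == len(self.provenance) == len(self.ids) == n):
            raise DegenerateDatasetError("X, y, provenance and ids must align")
        if np.any((self.provenance == PROV_ACTIVE) != (self.y == ACTIVE)):
            raise DegenerateDatasetError("rows tagged active must be labeled active")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def n_actives(self) -> int:
        return int(np.sum(self.y == ACTIVE))

    @property
    def n_inactives(self) -> int:
        return int(np.sum(self.y == INACTIVE))


def active_ids(library: SyntheticLibrary) -> pd.Index:
    """Ids of active-candidate compounds whose potency labels them active."""
    labels = label_compounds(library.potencies)
    mask = (library.roles == ROLE_ACTIVE) & (
        labels.reindex(library.ids) == ACTIVE
    )
    return library.ids[mask.to_numpy()]


def assemble_dataset(
    library: SyntheticLibrary,
    scheme: str,
    mode: str,
    decoys=None,
    target: str = "synthetic",
) -> LabeledDataset:
    """Assemble one of the four dataset variants for one fingerprint scheme.

    ``decoys`` is a :class:`~eemscreen.decoys.DecoySelection`; required for
    modes ``dud1`` (ratio 1), ``dud2`` (ratio 2) and ``mixed`` (which merges
    the true inactives with the 1:1 decoy set).
    """
    if mode not in DATASET_MODES:
        raise ConfigurationError(f"unknown dataset mode {mode!r}")
    if scheme not in library.fingerprints:
        raise ConfigurationError(f"scheme {scheme!r} not in library")

    labels = label_compounds(library.potencies).reindex(library.ids)
    act_mask = (library.roles == ROLE_ACTIVE).to_numpy() & (labels == ACTIVE).to_numpy()
    true_inact_mask = (library.roles == ROLE_INACTIVE).to_numpy() & (
        labels == INACTIVE
    ).to_numpy()
    act_ids = list(library.ids[act_mask])
    true_inact_ids = list(library.ids[true_inact_mask])

    if mode == "true_inactives":
        neg = [(cid, PROV_TRUE_INACTIVE) for cid in true_inact_ids]
    else:
        required_ratio = 2.0 if mode == "dud2" else 1.0
        if decoys is None:
            raise ConfigurationError(f"mode {mode!r} requires a decoy selection")
        if decoys.criteria.ratio != required_ratio:
            raise ConfigurationError(
                f"mode {mode!r} requires a decoy selection with ratio "
                f"{required_ratio:g}, got {decoys.criteria.ratio:g}"
            )
        decoy_neg = [(cid, PROV_DECOY) for cid in decoys.selected_ids]
        if mode == "mixed":
            neg = [(cid, PROV_TRUE_INACTIVE) for cid in true_inact_ids] + decoy_neg
        else:
            neg = decoy_neg

    if not act_ids or not neg:
        raise DegenerateDatasetError(
            f"mode {mode!r}: need at least one compound in each class "
            f"({len(act_ids)} actives, {len(neg)} negatives)"
        )

    ordered = [(cid, PROV_ACTIVE) for cid in act_ids] + neg
    row_of = {cid: i for i, cid in enumerate(library.ids)}
    rows = [row_of[cid] for cid, _ in ordered]
    X = library.fingerprints[scheme][rows]
    y = np.array([ACTIVE] * len(act_ids) + [INACTIVE] * len(neg), dtype=object)
    provenance = np.array([tag for _, tag in ordered], dtype=object)
    ids = np.array([cid for cid, _ in ordered], dtype=object)
    return LabeledDataset(X=X, y=y, provenance=provenance, ids=ids,
                          scheme=scheme, target=target)
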
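"""DUD-style decoy selection: property-matched, structurally dissimilar.

A decoy is a presumed-inactive pool compound that looks like an active
physicochemically but not structurally.  Selection proceeds in three
stages, mirroring the classic DUD protocol:

1. descriptor windows — keep pool compounds that, for at least one active,
   have identical HBA, HBD and rotB counts and logP and MW within a
   relative tolerance (default 10%);
2. structural dissimilarity — compute each survivor's maximum Tanimoto
   coefficient to the actives and reject values above a cutoff (default
   0.7; the rejection is strict, so exactly 0.7 is retained);
3. ranking — request round(ratio * n_actives) decoys and take the
   candidates with the smallest maximum Tanimoto, ties broken by
   ascending compound id.  A shortfall is allowed with a warning (the
   ratios are approximate by design).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eem import tanimoto_kernel
from .errors import InputError, SchemaError
from .labeling import ACTIVE, label_compounds
from .synthlib import (
    DESCRIPTOR_COLUMNS,
    ROLE_ACTIVE,
    ROLE_POOL,
    SyntheticLibrary,
)

logger = logging.getLogger(__name__)

EXACT_FIELDS = ("HBA", "HBD", "rotB")
WINDOW_FIELDS = ("logP", "MW")


@dataclass(frozen=True)
class DecoyCriteria:
    """Window and dissimilarity thresholds of the selection."""

    relative_tolerance: float = 0.10
    tanimoto_max: float = 0.7
    ratio: float = 1.0
    exact_fields: tuple = EXACT_FIELDS

    def __post_init__(self) -> None:
        if not 0.0 < self.relative_tolerance < 1.0:
            raise InputError("relative_tolerance must lie in (0, 1)")
        if not 0.0 < self.tanimoto_max <= 1.0:
            raise InputError("tanimoto_max must lie in (0, 1]")
        if self.ratio <= 0.0:
            raise InputError("ratio must be positive")


@dataclass
class DecoySelection:
    """Chosen decoys, ordered by non-decreasing maximum Tanimoto to actives."""

    selected_ids: list
    max_tanimoto: np.ndarray
    requested: int
    achieved: int
    criteria: DecoyCriteria = field(default_factory=DecoyCriteria)

    def __post_init__(self) -> None:
        if self.achieved != len(self.selected_ids):
            raise InputError("achieved must equal the number of selected ids")
        if self.achieved > self.requested:
            raise InputError("achieved cannot exceed requested")
        if len(self.max_tanimoto) and np.any(np.diff(self.max_tanimoto) < 0):
            raise InputError("max_tanimoto must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"compound_id": self.selected_ids, "max_tanimoto": self.max_tanimoto}
        )


def _require_columns(table: pd.DataFrame, name: str) -> None:
    missing = [c for c in DESCRIPTOR_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns {missing}")


def descriptor_window_match(
    pool: pd.DataFrame, actives: pd.DataFrame, criteria: DecoyCriteria
) -> np.ndarray:
    """Boolean mask: pool rows matching at least one active's windows.

    A pool compound matches an active when HBA, HBD and rotB are identical
    and |MW - MW_a| <= tol * MW_a and |logP - logP_a| <= tol * |logP_a|
    (for logP_a = 0 the condition degenerates to logP = 0).
    """
    _require_columns(pool, "pool")
    _require_columns(actives, "actives")
    tol = criteria.relative_tolerance
    mask = np.zeros(len(pool), dtype=bool)
    pool_exact = {c: pool[c].to_numpy() for c in criteria.exact_fields}
    pool_mw = pool["MW"].to_numpy(dtype=float)
    pool_logp = pool["logP"].to_numpy(dtype=float)
    for a in actives.itertuples():
        m = np.ones(len(pool), dtype=bool)
        for c in criteria.exact_fields:
            m &= pool_exact[c] == getattr(a, c)
        m &= np.abs(pool_mw - a.MW) <= tol * a.MW
        if a.logP == 0.0:
            m &= pool_logp == 0.0
        else:
            m &= np.abs(pool_logp - a.logP) <= tol * abs(a.logP)
        mask |= m
    return mask


def max_tanimoto_to_actives(
    pool_fp: np.ndarray, active_fp: np.ndarray, chunk: int = 2048
) -> np.ndarray:
    """Per-pool-row maximum Tanimoto coefficient over all actives."""
    pool_fp = np.asarray(pool_fp)
    out = np.empty(pool_fp.shape[0], dtype=np.float64)
    for start in range(0, pool_fp.shape[0], chunk):
        block = pool_fp[start : start + chunk]
        out[start : start + len(block)] = tanimoto_kernel(block, active_fp).max(axis=1)
    return out


def select_decoys(
    library: SyntheticLibrary,
    scheme: str,
    criteria: DecoyCriteria = DecoyCriteria(),
) -> DecoySelection:
    """Select decoys from the library pool for one fingerprint scheme.

    The Tanimoto cutoff is evaluated on ``scheme`` (by default the same
    fingerprint under which the resulting dataset will be modeled).
    An empty candidate set yields an empty selection with a warning, not
    an exception.
    """
    labels = label_compounds(library.potencies).reindex(library.ids)
    act_mask = library.role_mask(ROLE_ACTIVE) & (labels == ACTIVE).to_numpy()
    pool_mask = library.role_mask(ROLE_POOL)
    n_actives = int(act_mask.sum())
    if n_actives == 0 or not pool_mask.any():
        raise InputError("decoy selection needs >= 1 active and >= 1 pool compound")

    fp = library.fingerprints[scheme]
    active_desc = library.descriptors.loc[act_mask]
    pool_desc = library.descriptors.loc[pool_mask]
    pool_ids = np.asarray(library.ids[pool_mask])

    window = descriptor_window_match(pool_desc, active_desc, criteria)
    logger.info(
        "decoys[%s]: pool=%d window_pass=%d", scheme, len(pool_ids), window.sum()
    )

    cand_ids = pool_ids[window]
    cand_fp = fp[pool_mask][window]
    requested = int(round(criteria.ratio * n_actives))
    if len(cand_ids) == 0:
        logger.warning("decoys[%s]: no window-matched candidates", scheme)
        return DecoySelection([], np.empty(0), requested, 0, criteria)

    mt = max_tanimoto_to_actives(cand_fp, fp[act_mask])
    keep = mt <= criteria.tanimoto_max  # strictly reject only > cutoff
    logger.info(
        "decoys[%s]: tanimoto_pass=%d (cutoff %.2f)",
        scheme, keep.sum(), criteria.tanimoto_max,
    )
    cand_ids, mt = cand_ids[keep], mt[keep]

    order = np.lexsort((cand_ids, mt))  # ascending similarity, then id
    take = order[:requested]
    achieved = len(take)
    if achieved < requested:
        logger.warning(
            "decoys[%s]: requested %d decoys, only %d candidates available",
            scheme, requested, achieved,
        )
    return DecoySelection(
        selected_ids=list(cand_ids[take]),
        max_tanimoto=mt[take],
        requested=requested,
        achieved=achieved,
        criteria=criteria,
    )
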
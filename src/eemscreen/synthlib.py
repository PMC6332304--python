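"""Synthetic compound libraries for ligand-based virtual-screening benchmarks.

Real screening benchmarks pair bioactivity records (Ki / IC50 against a
protein target) with binary substructure fingerprints and physicochemical
descriptors.  This module generates libraries with the statistical structure
such benchmarks exhibit:

* actives are bit-flip perturbations of a small number of scaffold
  prototype fingerprints, so they cluster in Tanimoto space;
* true inactives perturb a disjoint set of prototypes;
* the screening pool is structurally dispersed (independent Bernoulli bits)
  but a configurable fraction of it is property-matched to the actives
  (identical H-bond donor/acceptor and rotatable-bond counts, logP and
  molecular weight within +/-10%), guaranteeing that DUD-style decoy
  selection has candidates to draw from;
* potencies straddle the activity thresholds: actives below the active
  cutoff, inactives above the inactive cutoff, and an ambiguous fraction
  strictly between the two (those compounds are later discarded by the
  labeling rules).

Everything is deterministic given the seed in the configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

ROLE_ACTIVE = "active_candidate"
ROLE_INACTIVE = "inactive_candidate"
ROLE_POOL = "pool"
ROLES = (ROLE_ACTIVE, ROLE_INACTIVE, ROLE_POOL)

DESCRIPTOR_COLUMNS = ("logP", "MW", "HBA", "HBD", "rotB")

#: Default fingerprint schemes: widths of the three smallest PaDEL-style
#: fingerprints commonly used for this kind of study (E-state, MACCS,
#: substructure keys).
DEFAULT_SCHEMES = {"estate": 79, "maccs": 166, "sub": 308}

# Potency bands in nM.  Actives are drawn below the active threshold,
# inactives above the inactive threshold, ambiguous compounds strictly
# between the two; thresholds themselves are never generated.
_ACTIVE_BAND = {"Ki": (1.0, 100.0), "IC50": (2.0, 200.0)}
_INACTIVE_BAND = {"Ki": (1000.0, 100000.0), "IC50": (2000.0, 200000.0)}
_AMBIGUOUS_BAND = {"Ki": (100.0, 1000.0), "IC50": (200.0, 2000.0)}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic library.

    Counts are numbers of compounds per role; probabilities are per-bit
    (densities, flip rates) or per-compound (matching and ambiguity
    fractions).  ``n_bits`` maps fingerprint scheme names to bit widths;
    a bare integer is accepted as shorthand for a single scheme ``"fp"``.
    """

    n_actives: int = 120
    n_true_inactives: int = 100
    n_pool: int = 600
    n_bits: dict[str, int] | int = field(
        default_factory=lambda: dict(DEFAULT_SCHEMES)
    )
    n_scaffolds: int = 5
    prototype_density: float = 0.15
    flip_rate_active: float = 0.03
    flip_rate_inactive: float = 0.05
    pool_density: float = 0.15
    descriptor_match_fraction: float = 0.5
    ambiguous_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_bits, int):
            object.__setattr__(self, "n_bits", {"fp": self.n_bits})
        for name in ("n_actives", "n_true_inactives", "n_scaffolds"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_pool < 0:
            raise ConfigurationError("n_pool must be >= 0")
        for scheme, d in self.n_bits.items():
            if d < 1:
                raise ConfigurationError(f"n_bits[{scheme!r}] must be >= 1")
        if self.n_scaffolds > self.n_actives:
            raise ConfigurationError("n_scaffolds must not exceed n_actives")
        for name in (
            "prototype_density",
            "flip_rate_active",
            "flip_rate_inactive",
            "pool_density",
            "descriptor_match_fraction",
            "ambiguous_fraction",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticLibrary:
    """A generated compound library.

    ``fingerprints`` maps scheme name to an (n_compounds, n_bits) uint8
    0/1 matrix; ``descriptors`` is indexed by compound id with columns
    logP, MW, HBA, HBD, rotB; ``potencies`` has one row per measurement
    (compound_id, measure in {Ki, IC50}, value_nM); ``roles`` is a
    compound-id-indexed Series of role tags.
    """

    fingerprints: dict[str, np.ndarray]
    descriptors: pd.DataFrame
    potencies: pd.DataFrame
    roles: pd.Series
    config: SyntheticConfig | None = None

    @property
    def ids(self) -> pd.Index:
        return self.descriptors.index

    @property
    def n_compounds(self) -> int:
        return len(self.descriptors)

    def role_mask(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise ConfigurationError(f"unknown role {role!r}")
        return (self.roles == role).to_numpy()

    @property
    def schemes(self) -> list[str]:
        return sorted(self.fingerprints)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float,
                 closed: str) -> float:
    """Log-uniform draw on (lo, hi) with one closed end or fully open.

    ``closed`` is "low" for [lo, hi), "high" for (lo, hi], "none" for the
    open interval.  Band boundaries are never returned for "none".
    """
    r = rng.random()
    if closed == "low":
        return lo * (hi / lo) ** r
    if closed == "high":
        return hi * (lo / hi) ** r
    while r == 0.0:  # boundary hit has probability ~2**-53
        r = rng.random()
    return lo * (hi / lo) ** r


def generate_library(config: SyntheticConfig) -> SyntheticLibrary:
    """Generate a fully deterministic synthetic library from ``config``."""
    rng = np.random.default_rng(config.seed)
    na, ni, npool = config.n_actives, config.n_true_inactives, config.n_pool
    n_total = na + ni + npool
    ids = pd.Index([f"C{i:06d}" for i in range(n_total)], name="compound_id")
    roles = pd.Series(
        [ROLE_ACTIVE] * na + [ROLE_INACTIVE] * ni + [ROLE_POOL] * npool,
        index=ids,
        name="role",
    )

    # one scaffold assignment shared by all fingerprint schemes
    active_scaffold = rng.integers(0, config.n_scaffolds, size=na)
    inactive_scaffold = rng.integers(0, config.n_scaffolds, size=ni)

    fingerprints: dict[str, np.ndarray] = {}
    for scheme in sorted(config.n_bits):
        d = config.n_bits[scheme]
        proto_active = rng.random((config.n_scaffolds, d)) < config.prototype_density
        proto_inactive = rng.random((config.n_scaffolds, d)) < config.prototype_density
        act = proto_active[active_scaffold] ^ (
            rng.random((na, d)) < config.flip_rate_active
        )
        inact = proto_inactive[inactive_scaffold] ^ (
            rng.random((ni, d)) < config.flip_rate_inactive
        )
        pool = rng.random((npool, d)) < config.pool_density
        fingerprints[scheme] = np.vstack([act, inact, pool]).astype(np.uint8)

    # descriptors: drug-like marginals (logP ~ N(2.5, 1.2), MW ~ N(350, 80) Da,
    # Poisson H-bond acceptor/donor and rotatable-bond counts)
    descriptors = pd.DataFrame(
        {
            "logP": rng.normal(2.5, 1.2, n_total),
            "MW": np.clip(rng.normal(350.0, 80.0, n_total), 100.0, None),
            "HBA": rng.poisson(4.0, n_total),
            "HBD": rng.poisson(2.0, n_total),
            "rotB": rng.poisson(5.0, n_total),
        },
        index=ids,
    )

    # property-match a fraction of the pool to random actives so that the
    # decoy descriptor windows are guaranteed to have candidates
    n_match = int(round(config.descriptor_match_fraction * npool))
    if n_match > 0:
        matched_pool = rng.choice(npool, size=n_match, replace=False) + na + ni
        source_active = rng.integers(0, na, size=n_match)
        for col in ("HBA", "HBD", "rotB"):
            vals = descriptors[col].to_numpy().copy()
            vals[matched_pool] = vals[source_active]
            descriptors[col] = vals
        mw = descriptors["MW"].to_numpy().copy()
        mw[matched_pool] = mw[source_active] * rng.uniform(0.9, 1.1, n_match)
        descriptors["MW"] = mw
        logp = descriptors["logP"].to_numpy().copy()
        logp_a = logp[source_active]
        logp[matched_pool] = logp_a + rng.uniform(-1.0, 1.0, n_match) * 0.1 * np.abs(logp_a)
        descriptors["logP"] = logp

    # potencies for the candidate compounds only; the pool is unassayed
    n_candidates = na + ni
    n_ambiguous = int(round(config.ambiguous_fraction * n_candidates))
    ambiguous = np.zeros(n_candidates, dtype=bool)
    if n_ambiguous > 0:
        ambiguous[rng.choice(n_candidates, size=n_ambiguous, replace=False)] = True

    records = []
    for j in range(n_candidates):
        measure = "Ki" if rng.random() < 0.5 else "IC50"
        if ambiguous[j]:
            lo, hi = _AMBIGUOUS_BAND[measure]
            value = _log_uniform(rng, lo, hi, closed="none")
        elif j < na:
            lo, hi = _ACTIVE_BAND[measure]
            value = _log_uniform(rng, lo, hi, closed="low")
        else:
            lo, hi = _INACTIVE_BAND[measure]
            value = _log_uniform(rng, lo, hi, closed="high")
        records.append((ids[j], measure, value))
    potencies = pd.DataFrame(records, columns=["compound_id", "measure", "value_nM"])

    return SyntheticLibrary(
        fingerprints=fingerprints,
        descriptors=descriptors,
        potencies=potencies,
        roles=roles,
        config=config,
    )


# ---------------------------------------------------------------------------
# on-disk format: headered CSV tables plus a JSON manifest


def _bit_columns(d: int) -> list[str]:
    width = max(4, len(str(d)))
    return [f"bit_{i + 1:0{width}d}" for i in range(d)]


def write_library(library: SyntheticLibrary, outdir: str | Path) -> Path:
    """Write a library as CSV tables with a sidecar manifest; returns outdir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    compounds = library.descriptors.copy()
    compounds.insert(0, "role", library.roles)
    compounds.to_csv(out / "compounds.csv")
    library.potencies.to_csv(out / "potencies.csv", index=False)
    for scheme, fp in library.fingerprints.items():
        df = pd.DataFrame(fp, index=library.ids, columns=_bit_columns(fp.shape[1]))
        df.to_csv(out / f"fingerprints_{scheme}.csv")

    manifest = {
        "schemes": {s: int(fp.shape[1]) for s, fp in library.fingerprints.items()},
        "n_compounds": int(library.n_compounds),
        "config": library.config.to_dict() if library.config else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def read_library(indir: str | Path) -> SyntheticLibrary:
    """Read a library written by :func:`write_library`."""
    path = Path(indir)
    manifest = json.loads((path / "manifest.json").read_text())
    compounds = pd.read_csv(path / "compounds.csv", index_col="compound_id")
    roles = compounds["role"]
    descriptors = compounds[list(DESCRIPTOR_COLUMNS)]
    potencies = pd.read_csv(path / "potencies.csv")
    fingerprints = {}
    for scheme in manifest["schemes"]:
        df = pd.read_csv(path / f"fingerprints_{scheme}.csv", index_col="compound_id")
        fingerprints[scheme] = df.to_numpy(dtype=np.uint8)
    config = manifest.get("config")
    return SyntheticLibrary(
        fingerprints=fingerprints,
        descriptors=descriptors,
        potencies=potencies,
        roles=roles,
        config=SyntheticConfig(**config) if config else None,
    )
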
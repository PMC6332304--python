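"""End-to-end benchmark pipeline: simulate -> label -> decoys -> grid search
-> reports.

Every run is driven by a single :class:`PipelineConfig` and a master seed;
all stage seeds (library generation, splits) are derived from it, and a
manifest recording the configuration, derived seeds and a config hash is
written next to the results so a rerun reproduces byte-identical TSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baselines, decoys, evaluation, labeling, synthlib
from .errors import ConfigurationError, EemScreenError, PipelineError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = np.round(np.arange(0.50, 1.0001, 0.01), 2)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one benchmark run bit-for-bit."""

    synthetic: synthlib.SyntheticConfig = field(
        default_factory=synthlib.SyntheticConfig
    )
    target: str = "T1"
    schemes: list | None = None  # default: every scheme in the library
    modes: tuple = labeling.DATASET_MODES
    methods: tuple = baselines.METHODS
    split_proportion: float = 0.5
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for mode in self.modes:
            if mode not in labeling.DATASET_MODES:
                raise ConfigurationError(f"unknown dataset mode {mode!r}")
        for method in self.methods:
            if method not in baselines.METHODS:
                raise ConfigurationError(f"unknown method {method!r}")
        if not 0.0 < self.split_proportion < 1.0:
            raise ConfigurationError("split_proportion must lie in (0, 1)")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        mapping = dict(mapping)
        synth = mapping.pop("synthetic", {})
        if isinstance(synth, dict):
            synth = synthlib.SyntheticConfig(**synth)
        modes = tuple(mapping.pop("modes", labeling.DATASET_MODES))
        methods = tuple(mapping.pop("methods", baselines.METHODS))
        return cls(synthetic=synth, modes=modes, methods=methods, **mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()) or {})

    def to_manifest(self) -> dict:
        manifest = dataclasses.asdict(self)
        manifest.pop("out_dir")  # location-independent, so reruns in another
        manifest["modes"] = list(self.modes)  # directory stay byte-identical
        manifest["methods"] = list(self.methods)
        canonical = json.dumps(manifest, sort_keys=True)
        manifest["config_sha256"] = hashlib.sha256(canonical.encode()).hexdigest()
        return manifest


def _derive_seeds(master: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31 from the master seed."""
    state = np.random.SeedSequence(master).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns records, report frames and output paths.

    Stage failures abort with :class:`PipelineError` naming the stage;
    partial outputs already written are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(config.seed, 2)
    synth_seed, split_seed_base = seeds

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except EemScreenError as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    # -- simulate ----------------------------------------------------------
    synth_config = dataclasses.replace(config.synthetic, seed=synth_seed)
    library = stage("simulate", synthlib.generate_library, synth_config)
    stage("simulate", synthlib.write_library, library, out / "library")
    schemes = list(config.schemes) if config.schemes else library.schemes
    for scheme in schemes:
        if scheme not in library.fingerprints:
            raise PipelineError(f"stage 'simulate' failed: scheme {scheme!r} "
                                "not present in the generated library")

    # -- label -------------------------------------------------------------
    labels = stage("label", labeling.label_compounds, library.potencies)
    label_table = pd.DataFrame(
        {
            "compound_id": library.ids,
            "role": library.roles.to_numpy(),
            "label": labels.reindex(library.ids).fillna("unassayed").to_numpy(),
        }
    )
    label_table.to_csv(out / "labels.tsv", sep="\t", index=False)

    # -- decoys ------------------------------------------------------------
    decoy_modes = [m for m in config.modes if m in ("dud1", "dud2", "mixed")]
    needed_ratios = sorted(
        {2.0 if m == "dud2" else 1.0 for m in decoy_modes}
    )
    selections: dict[tuple[str, float], decoys.DecoySelection] = {}
    if decoy_modes:
        if not library.role_mask(synthlib.ROLE_POOL).any():
            raise PipelineError(
                "stage 'decoys' failed: modes "
                f"{decoy_modes} require a compound pool but the library has none"
            )
        for scheme in schemes:
            for ratio in needed_ratios:
                sel = stage(
                    "decoys",
                    decoys.select_decoys,
                    library,
                    scheme,
                    decoys.DecoyCriteria(ratio=ratio),
                )
                selections[(scheme, ratio)] = sel
                sel.to_frame().to_csv(
                    out / f"decoys_{scheme}_ratio{ratio:g}.tsv", sep="\t", index=False
                )

    # -- train / evaluate: grid search per scheme x mode x method ----------
    records: list[evaluation.EvalRecord] = []
    grid_rows = []
    grid_results: dict[tuple[str, str, str], evaluation.GridResult] = {}
    for si, scheme in enumerate(schemes):
        for mi, mode in enumerate(config.modes):
            sel = None
            if mode in ("dud1", "dud2", "mixed"):
                sel = selections[(scheme, 2.0 if mode == "dud2" else 1.0)]
            dataset = stage(
                "label", labeling.assemble_dataset, library, scheme, mode,
                decoys=sel, target=config.target,
            )
            split_seed = (split_seed_base + 7919 * si + 104729 * mi) % (2**31)
            for method in config.methods:
                grid = baselines.make_grid(method)
                result = stage(
                    "train", evaluation.grid_search, method, dataset, grid,
                    split_seed=split_seed, proportion=config.split_proportion,
                )
                grid_results[(scheme, mode, method)] = result
                records.append(
                    evaluation.EvalRecord(
                        target=f"{config.target}/{mode}",
                        scheme=scheme,
                        method=method,
                        params=result.best_params,
                        split_seed=split_seed,
                        bac=result.best_bac,
                    )
                )
                for params, bac, err in zip(result.points, result.bacs, result.errors):
                    grid_rows.append(
                        {
                            "target": config.target,
                            "scheme": scheme,
                            "mode": mode,
                            "method": method,
                            "params": json.dumps(params, sort_keys=True),
                            "split_seed": split_seed,
                            "bac": bac,
                            "error": err or "",
                        }
                    )

    pd.DataFrame(grid_rows).to_csv(out / "grid_points.tsv", sep="\t", index=False)
    results = pd.DataFrame(
        [
            {
                "target": r.target,
                "scheme": r.scheme,
                "method": r.method,
                "params": json.dumps(r.params, sort_keys=True),
                "split_seed": r.split_seed,
                "bac": r.bac,
            }
            for r in records
        ]
    )
    results.to_csv(out / "results.tsv", sep="\t", index=False)

    # -- report ------------------------------------------------------------
    best_fp = stage("report", evaluation.best_fingerprint, records)
    best_fp.to_csv(out / "best_fingerprint.tsv", sep="\t", index=False)

    experiments = []
    for scheme in schemes:
        for mode in config.modes:
            exp = {
                method: grid_results[(scheme, mode, method)].best_bac
                for method in config.methods
            }
            experiments.append(exp)
    ranking = stage(
        "report", evaluation.ranking_profile, experiments, tuple(config.methods)
    )
    ranking.to_frame().to_csv(out / "ranking.tsv", sep="\t")

    stability_rows = []
    for (scheme, mode, method), result in sorted(grid_results.items()):
        curve = evaluation.stability_curve(result.valid_bacs, DEFAULT_THRESHOLDS)
        for t, p in zip(curve.thresholds, curve.probability):
            stability_rows.append(
                {
                    "scheme": scheme,
                    "mode": mode,
                    "method": method,
                    "threshold": t,
                    "probability": p,
                }
            )
    pd.DataFrame(stability_rows).to_csv(out / "stability.tsv", sep="\t", index=False)

    manifest = config.to_manifest()
    manifest["derived_seeds"] = {"synthetic": synth_seed, "split_base": split_seed_base}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "library": library,
        "records": records,
        "grid_results": grid_results,
        "best_fingerprint": best_fp,
        "ranking": ranking,
        "out_dir": out,
    }
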
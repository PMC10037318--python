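"""End-to-end pipeline: contacts -> scores -> clustering -> matching -> WHAM.

A :class:`PipelineConfig` (usually loaded from YAML) names the inputs and
parameters; :func:`run_pipeline` executes whichever stages have inputs, in
dependency order, writing TSV/JSON artifacts whose ``#`` headers record the
package version, a hash of the resolved configuration, and the seed, so a
rerun with the same config and seed is byte-identical for the deterministic
stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
from dataclasses import dataclass, field

import yaml

from . import __version__
from .clustering import (
    cross_cluster_match,
    daura_cluster,
    extract_backbone,
    DEFAULT_BACKBONE_ATOMS,
)
from .contacts import (
    compute_contact_fractions,
    default_reference_table,
    load_reference_table,
    DEFAULT_LAYER_TOLERANCE,
)
from .errors import ConfigurationError
from .scoring import FreeEnergyTable, default_free_energy_table, residue_binding_scores
from .trajectory import load_trajectory
from .wham import load_windows, wham_with_errors

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("pepsurf")


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; any stage without inputs is skipped."""

    output_dir: str = "pepsurf-out"
    seed: int = 0

    # contact / scoring stage
    trajectory: str | None = None
    trajectory_frames: list[str] = field(default_factory=list)
    length_unit: str = "angstrom"
    reference_table: str | None = None  # YAML/TSV; default table when absent
    free_energy_table: str | None = None  # TSV/YAML; representative defaults
    contact_method: str = "vertical"
    layer_tolerance: float = DEFAULT_LAYER_TOLERANCE
    score: bool = True

    # clustering / matching stage
    cluster: bool = True
    cluster_cutoff: float = 2.0  # Angstrom
    backbone_atoms: tuple[str, ...] = DEFAULT_BACKBONE_ATOMS
    fit: bool = True
    match_trajectory: str | None = None  # second variant to cross-match against
    top_k: int = 5

    # WHAM stage
    umbrella_metadata: str | None = None
    wham_bins: int = 200
    temperature: float = 300.0
    wham_tolerance: float = 1e-6
    n_boot: int = 200

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(
                f"{path}: unknown config keys: {', '.join(sorted(unknown))}"
            )
        if "backbone_atoms" in raw:
            raw["backbone_atoms"] = tuple(raw["backbone_atoms"])
        return cls(**raw)

    def validate(self) -> None:
        """Fail fast, before any computation."""
        for label, path in (
            ("trajectory", self.trajectory),
            ("match_trajectory", self.match_trajectory),
            ("reference_table", self.reference_table),
            ("free_energy_table", self.free_energy_table),
            ("umbrella_metadata", self.umbrella_metadata),
        ):
            if path is not None and not os.path.exists(path):
                raise ConfigurationError(f"{label}: no such file: {path}")
        for fp in self.trajectory_frames:
            if not os.path.exists(fp):
                raise ConfigurationError(f"trajectory frame file missing: {fp}")
        if self.trajectory is None and self.umbrella_metadata is None:
            raise ConfigurationError(
                "nothing to do: provide a trajectory and/or umbrella metadata"
            )
        if self.cluster_cutoff <= 0:
            raise ConfigurationError("cluster_cutoff must be > 0")
        if self.wham_bins < 2:
            raise ConfigurationError("wham_bins must be >= 2")
        if self.n_boot < 2:
            raise ConfigurationError("n_boot must be >= 2")
        if not (0 < self.temperature):
            raise ConfigurationError("temperature must be > 0 K")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(config: PipelineConfig) -> list[str]:
    return [
        f"pepsurf {__version__}",
        f"config_hash = {config.config_hash()}",
        f"seed = {config.seed}",
    ]


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run all configured stages; returns artifact name -> path.

    Artifacts (as applicable): ``contacts.tsv``, ``scores.tsv``,
    ``scores.json``, ``clusters.tsv``, ``match.tsv``, ``pmf.tsv`` and
    ``run.log``.
    """
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    header = _header(config)
    artifacts: dict[str, str] = {}

    log_path = os.path.join(config.output_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts["run.log"] = log_path

    def _out(name: str) -> str:
        path = os.path.join(config.output_dir, name)
        artifacts[name] = path
        return path

    try:
        logger.info("pepsurf %s starting (config %s, seed %d)",
                    __version__, config.config_hash(), config.seed)

        traj = None
        if config.trajectory is not None:
            traj = load_trajectory(
                config.trajectory, config.trajectory_frames, config.length_unit
            )
            logger.info("loaded trajectory: %d atoms, %d frames",
                        traj.n_atoms, traj.n_frames)

            ref_table = (
                load_reference_table(config.reference_table)
                if config.reference_table
                else default_reference_table()
            )
            profile = compute_contact_fractions(
                traj,
                ref_table,
                method=config.contact_method,
                layer_tolerance=config.layer_tolerance,
            )
            profile.to_tsv(_out("contacts.tsv"), header)
            logger.info("contact fractions: %s",
                        dict(zip(profile.labels, profile.fractions.round(3))))

            if config.score:
                dg = (
                    FreeEnergyTable.load(config.free_energy_table)
                    if config.free_energy_table
                    else default_free_energy_table()
                )
                report = residue_binding_scores(profile, dg)
                report.to_tsv(_out("scores.tsv"), header)
                report.to_json(_out("scores.json"))
                logger.info("cumulative scores: %s; position-9: %s (%s)",
                            report.cumulative, report.position9_score,
                            report.position9_class)

            if config.cluster:
                ensemble = extract_backbone(traj, config.backbone_atoms)
                result = daura_cluster(ensemble, config.cluster_cutoff, fit=config.fit)
                result.to_tsv(_out("clusters.tsv"), header)
                logger.info("clustering: %d clusters, populations %s",
                            len(result.clusters), result.populations()[:5])

                if config.match_trajectory is not None:
                    other = load_trajectory(
                        config.match_trajectory, [], config.length_unit
                    )
                    other_result = daura_cluster(
                        extract_backbone(other, config.backbone_atoms),
                        config.cluster_cutoff,
                        fit=config.fit,
                    )
                    match = cross_cluster_match(
                        result, other_result, top_k=config.top_k, fit=config.fit
                    )
                    match.to_tsv(_out("match.tsv"), header)
                    logger.info("cross-variant match: %s", match.counts())

        if config.umbrella_metadata is not None:
            windows = load_windows(config.umbrella_metadata)
            profile = wham_with_errors(
                windows,
                n_boot=config.n_boot,
                seed=config.seed,
                bins=config.wham_bins,
                temperature=config.temperature,
                tolerance=config.wham_tolerance,
            )
            profile.to_tsv(_out("pmf.tsv"), header)
            logger.info("WHAM: %d windows, %d iterations, PMF span %.2f kJ/mol",
                        len(windows), profile.n_iterations,
                        float(np.nanmax(profile.free_energy)))

        logger.info("done; artifacts: %s", sorted(artifacts))
        return artifacts
    finally:
        logger.removeHandler(handler)
        handler.close()
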
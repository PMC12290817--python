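"""End-to-end pipeline: simulate -> project -> distances -> statistics ->
geometry, with provenance.

The pipeline is configured by a single :class:`PipelineConfig` (constructible
from YAML/JSON via :func:`load_config`), validated before any computation,
and produces a :class:`RunManifest` with per-stage timings and SHA-256
checksums of every written file, so a re-run with identical configuration
and seeds is verifiable as identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .analysis import study_distances
from .community import sensitivity_report
from .dlda import fit_dlda
from .geometry import mds_embed, object_distance_matrix, permutation_average
from .graphs import automorphism_group
from .identity import classify_accuracy, identity_report_table, min_statistic_test, permutation_engine
from .simulate import ParcelSpec, simulate_study

logger = logging.getLogger("commrsa.pipeline")

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (all stages)."""

    out_dir: str
    condition: str = "structured"
    n_observers: int = 2
    runs: int = 2
    parcel_specs: list = field(default_factory=lambda: [ParcelSpec(parcel_id=0)])
    seed: int = 0
    alpha: float = 0.05
    tau_max: int = 30
    fdr_q: float = 0.05
    n_permutations: int = 0      # identity permutation test; 0 = skip
    n_candidates: int = 200      # counterbalancing candidates per run
    run_identity: bool = True
    run_geometry: bool = True

    def specs(self) -> list[ParcelSpec]:
        return [
            s if isinstance(s, ParcelSpec) else ParcelSpec(**s)
            for s in self.parcel_specs
        ]


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)   # stage -> seconds
    checksums: dict = field(default_factory=dict)  # file -> sha256
    status: str = "running"

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2)


def load_config(path) -> PipelineConfig:
    """Load a YAML (or JSON) configuration document."""
    with open(path) as f:
        doc = yaml.safe_load(f)
    return PipelineConfig(**doc)


def validate_config(config: PipelineConfig) -> list[str]:
    """Structural validation; returns a list of errors (empty = valid).

    Never touches data: parcel specs are instantiated only to trigger their
    own range checks.
    """
    errors: list[str] = []
    if config.condition not in ("structured", "unstructured"):
        errors.append(f"unknown condition {config.condition!r}")
    if config.n_observers < 1:
        errors.append("n_observers must be >= 1")
    if config.runs < 1:
        errors.append("runs must be >= 1")
    if not (0 < config.alpha < 1):
        errors.append("alpha must be in (0, 1)")
    if not (0 < config.fdr_q < 1):
        errors.append("fdr_q must be in (0, 1)")
    if config.tau_max < 1:
        errors.append("tau_max must be >= 1")
    if not config.out_dir:
        errors.append("out_dir is required")
    else:
        parent = Path(config.out_dir).resolve().parent
        if not parent.exists():
            errors.append(f"parent of out_dir does not exist: {parent}")
    try:
        specs = config.specs()
        ids = [s.parcel_id for s in specs]
        if len(set(ids)) != len(ids):
            errors.append("parcel_id values must be unique")
    except (TypeError, ValueError) as e:
        errors.append(f"invalid parcel spec: {e}")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in dependency order, writing outputs + manifest.

    Stages: simulate, subspace fitting + projection, pairwise distances with
    residual correction, community-sensitivity report, identity report
    (optional), geometry (optional).  A failing stage aborts the run but the
    manifest (status="failed: <stage>") and the outputs of completed stages
    are preserved.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "reports").mkdir(exist_ok=True)

    cfg_doc = json.dumps(
        {**asdict(config), "parcel_specs": [asdict(s) for s in config.specs()]},
        sort_keys=True, default=str,
    )
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_doc.encode()).hexdigest(),
        version=_version(),
    )
    (out / "config.yaml").write_text(yaml.safe_dump(yaml.safe_load(cfg_doc)))

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        logger.info("stage %s", stage)
        bundle = simulate_study(
            config.n_observers,
            config.specs(),
            condition=config.condition,
            runs=config.runs,
            seed=config.seed,
            n_candidates=config.n_candidates,
        )
        all_seqs = [s for seqs in bundle.sequences.values() for s in seqs]
        cio.write_sequences(all_seqs, out / "sequences.tsv")
        cio.write_graph(bundle.graph, out / "graph_edges.tsv", out / "graph_nodes.tsv")
        h5 = out / "responses.h5"
        if h5.exists():
            h5.unlink()
        cio.write_responses(list(bundle.responses.values()), h5)
        manifest.stages[stage] = time.perf_counter() - t0

        stage = "project"
        t0 = time.perf_counter()
        logger.info("stage %s", stage)
        obs_data: dict = {}  # parcel -> {observer: (X, labels, runs)}
        for (u, w), rs in bundle.responses.items():
            rec = rs.recurring_mask()
            labels = rs.trial_meta["object_id"].to_numpy()
            runs = rs.trial_meta["run_id"].to_numpy()
            sub = fit_dlda(
                rs.responses[rec], labels[rec], fitted_on=f"obs{u}/parcel{w}/all-runs"
            )
            cio.write_subspace(sub, h5, f"obs{u}_parcel{w}")
            obs_data.setdefault(w, {})[u] = (rs.responses[rec], labels[rec], runs[rec])
        manifest.stages[stage] = time.perf_counter() - t0

        stage = "distances"
        t0 = time.perf_counter()
        logger.info("stage %s", stage)
        dsets = study_distances(bundle)
        pd.concat(dsets.values(), ignore_index=True).to_csv(
            out / "distances.tsv", sep="\t", index=False
        )
        manifest.stages[stage] = time.perf_counter() - t0

        stage = "community"
        t0 = time.perf_counter()
        logger.info("stage %s", stage)
        rep = sensitivity_report(
            dsets, bundle.graph, alpha=config.fdr_q, tau_max=config.tau_max
        )
        rep.to_tsv(out / "reports" / "community_sensitivity.tsv")
        manifest.stages[stage] = time.perf_counter() - t0

        if config.run_identity:
            stage = "identity"
            t0 = time.perf_counter()
            logger.info("stage %s", stage)
            reports = []
            for w, data in sorted(obs_data.items()):
                accs = {
                    u: classify_accuracy(X, lab, rn) for u, (X, lab, rn) in data.items()
                }
                if config.n_permutations >= 100 and len(data) >= 2:
                    rep_w = min_statistic_test(
                        accs,
                        permutation_engine(data),
                        n_permutations=config.n_permutations,
                        seed=config.seed + 1,
                        parcel_id=w,
                        alpha=config.alpha,
                    )
                    rep_w.accuracies = accs
                    reports.append(rep_w)
                else:
                    from .identity import IdentityReport

                    reports.append(
                        IdentityReport(w, accs, min(accs.values()), float("nan"), 0)
                    )
            identity_report_table(reports).to_csv(
                out / "reports" / "identity.tsv", sep="\t", index=False
            )
            manifest.stages[stage] = time.perf_counter() - t0

        if config.run_geometry and bundle.graph.name == "modular":
            stage = "geometry"
            t0 = time.perf_counter()
            logger.info("stage %s", stage)
            perms = automorphism_group(bundle.graph)
            for w, dset in dsets.items():
                per_obs = []
                for u, sub_d in dset.groupby("observer_id"):
                    M = object_distance_matrix(sub_d)
                    per_obs.append(permutation_average(M, perms=perms))
                avg = np.mean(np.stack(per_obs), axis=0)
                np.savetxt(out / "reports" / f"distmatrix_parcel{w}.tsv", avg,
                           delimiter="\t")
                emb = mds_embed(avg, seed=config.seed, graph=bundle.graph)
                emb.to_frame().to_csv(
                    out / "reports" / f"embedding_parcel{w}.tsv", sep="\t", index=False
                )
            manifest.stages[stage] = time.perf_counter() - t0

        manifest.status = "ok"
    except Exception:
        manifest.status = f"failed: {stage}"
        raise
    finally:
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                manifest.checksums[str(p.relative_to(out))] = _sha256(p)
        manifest.save(out / "manifest.json")

    return manifest


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("commrsa")
    except Exception:
        return "unknown"
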
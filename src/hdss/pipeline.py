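"""End-to-end pipeline: simulate/ingest -> score -> space -> geometry.

Runs every stage in order, writes all artifacts under one output
directory, and records a JSON manifest (seeds, stage parameters, file
hashes) that fully determines reproduction: rerunning with the same
configuration yields byte-identical numeric CSVs.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .categories import (
    assignment_from_status,
    summarize_within_between,
    within_between_matrix,
)
from .centroid import (
    average_person_vector,
    distance_from_centroid,
    distance_severity_correlation,
    person_severity_index,
    rose_data,
    severity_regression,
)
from .embedding import fit_clinical_boundary, mds_embed
from .io import (
    FLOAT_FMT,
    read_cohort,
    write_cohort,
    write_distance_matrix,
    write_json,
    write_observation_frame,
    write_observation_series,
    write_space,
)
from .scoring import ScaleMap, score_cohort
from .simulate import generate_cohort, preset
from .space import build_scale_space, build_space, pairwise_distances
from .trajectories import (
    build_trajectories,
    detect_transitions,
    events_frame,
    trajectories_frame,
)

log = logging.getLogger("hdss")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out: str = "hdss_out"
    preset: str | None = "paper_like"  # simulate this preset ...
    input: str | None = None  # ... or ingest this cohort CSV
    scales: str | None = None  # scale-map YAML (required with --input)
    demographics: str = "onehot"
    threshold: float = 65.0
    seed: int = 42
    mds_method: str = "smacof"
    mds_n_init: int = 1  # classical warm start only; see docs/methods.md
    mds_max_iter: int = 300
    rose_disorders: tuple[str, ...] = ("oppositional_defiant", "somatic_problems")
    rose_n_sample: int = 30
    write_distances_max_n: int = 2000  # skip the O(n^2) CSV above this size
    plot: bool = False
    complete_case: bool = True


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the report bundle (as a dict).

    Stage order: simulate/ingest, score, build-space, distances, centroid,
    embed, boundary, categories, trajectories, report.  Any stage failure
    propagates with the artifacts written so far preserved on disk.
    """
    t_start = time.perf_counter()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _config_dict(config), "version": __version__}
    artifacts: list[Path] = []

    def _stage(name: str):
        log.info("stage %s", name)
        return time.perf_counter()

    # -- simulate or ingest -------------------------------------------------
    t = _stage("simulate" if config.preset else "ingest")
    truth = None
    if config.preset is not None:
        sim = preset(config.preset, seed=config.seed)
        cohort, truth, scale_map = generate_cohort(sim)
        write_cohort(cohort, out / "cohort.csv")
        scale_map.to_yaml(out / "scales.yaml")
        truth.true_severity.to_frame().reset_index().to_csv(
            out / "true_severity.csv", index=False, float_format=FLOAT_FMT
        )
        artifacts += [out / "cohort.csv", out / "scales.yaml", out / "true_severity.csv"]
    else:
        if config.input is None or config.scales is None:
            raise ValueError("either a preset or (input, scales) must be given")
        cohort = read_cohort(config.input, complete_case=config.complete_case)
        scale_map = ScaleMap.from_yaml(config.scales)
    report["n_persons"] = int(cohort["person_id"].nunique())
    report["n_observations"] = int(len(cohort))
    log.info("cohort ready in %.1fs", time.perf_counter() - t)

    # -- score --------------------------------------------------------------
    t = _stage("score")
    tscores, status = score_cohort(cohort, scale_map, threshold=config.threshold)
    write_observation_frame(tscores.raw, out / "raw_scores.csv")
    write_observation_frame(tscores.t, out / "tscores.csv")
    status_frame = status.elevated.astype(int).copy()
    status_frame["n_diagnoses"] = status.n_diagnoses
    status_frame["any_clinical"] = status.any_clinical.astype(int)
    status_frame["total_clinical"] = status.total_clinical.astype(int)
    write_observation_frame(status_frame, out / "status.csv")
    artifacts += [out / "raw_scores.csv", out / "tscores.csv", out / "status.csv"]
    log.info("scoring done in %.1fs", time.perf_counter() - t)

    # -- build-space and distances -----------------------------------------
    t = _stage("build-space")
    space = build_space(cohort, demographics=config.demographics)
    write_space(space, out / "space")
    artifacts += [out / "space" / "space.csv", out / "space" / "standardization.json"]
    report["n_features"] = space.n_features
    dist = pairwise_distances(space)
    if dist.n <= config.write_distances_max_n:
        write_distance_matrix(dist, out / "distances.csv")
        artifacts.append(out / "distances.csv")
    else:
        log.info("distances kept in memory (n=%d rows; CSV skipped)", dist.n)
    log.info("space + distances in %.1fs", time.perf_counter() - t)

    # -- centroid analysis --------------------------------------------------
    t = _stage("centroid")
    centroid = average_person_vector(space)
    cdist = distance_from_centroid(space, centroid)
    write_observation_series(cdist, out / "centroid_distances.csv", "centroid_distance")
    artifacts.append(out / "centroid_distances.csv")
    reg = severity_regression(cdist, status.n_diagnoses)
    report["severity_regression"] = asdict(reg)
    write_json(asdict(reg), out / "severity_regression.json")
    artifacts.append(out / "severity_regression.json")

    # per-observation distance vs total symptom score (item-space analogue)
    total_corr = distance_severity_correlation(cdist, tscores.raw["total_problems"])
    report["distance_total_correlation"] = asdict(total_corr)

    if truth is not None:
        sev_idx = person_severity_index(space)
        aligned = sev_idx.reindex(truth.true_severity.index)
        report["severity_recovery_r"] = float(
            np.corrcoef(aligned.to_numpy(), truth.true_severity.to_numpy())[0, 1]
        )

    # the 5-dimensional broad-scale space and its severity correlation
    scale_space = build_scale_space(tscores.t)
    scale_centroid = average_person_vector(scale_space)
    scale_cdist = distance_from_centroid(scale_space, scale_centroid)
    corr = distance_severity_correlation(scale_cdist, tscores.raw["total_problems"])
    report["scale_space_correlation"] = asdict(corr)
    write_json(asdict(corr), out / "scale_space_correlation.json")
    artifacts.append(out / "scale_space_correlation.json")

    for disorder in config.rose_disorders:
        if disorder not in scale_map.scales:
            continue
        rose = rose_data(
            cdist,
            status,
            disorder,
            n_sample=config.rose_n_sample,
            seed=config.seed,
        )
        rose_path = out / f"rose_{disorder}.csv"
        rose.to_csv(rose_path, index=False, float_format=FLOAT_FMT)
        artifacts.append(rose_path)
    log.info("centroid stage in %.1fs", time.perf_counter() - t)

    # -- embed + boundary ---------------------------------------------------
    t = _stage("embed")
    embedding = mds_embed(
        dist,
        seed=config.seed,
        method=config.mds_method,
        n_init=config.mds_n_init,
        max_iter=config.mds_max_iter,
    )
    emb_frame = embedding.coords.copy()
    write_observation_frame(emb_frame, out / "embedding.csv")
    artifacts.append(out / "embedding.csv")
    report["mds"] = {
        "stress": embedding.stress,
        "n_iter": embedding.n_iter,
        "converged": embedding.converged,
    }
    boundary = fit_clinical_boundary(embedding, status.total_clinical)
    report["boundary"] = {
        "intercept": boundary.intercept,
        "coefficients": [float(c) for c in boundary.coefficients],
        "threshold": boundary.threshold,
        "training_accuracy": boundary.training_accuracy,
    }
    write_json(report["boundary"], out / "boundary.json")
    artifacts.append(out / "boundary.json")
    log.info("embedding + boundary in %.1fs", time.perf_counter() - t)

    # -- categories ---------------------------------------------------------
    t = _stage("categories")
    report["categories"] = {}
    for family in ("dsm_proxy", "hitop"):
        assign = assignment_from_status(status, scale_map, family, timepoint=1)
        base_labels = assign.membership.index
        sub = _subset_distance(dist, base_labels)
        summary = within_between_matrix(sub, assign)
        summary.matrix.to_csv(out / f"categories_{family}.csv", float_format=FLOAT_FMT)
        summary.counts.to_csv(out / f"categories_{family}_counts.csv")
        artifacts += [out / f"categories_{family}.csv", out / f"categories_{family}_counts.csv"]
        mw, sw, mb, sb = summarize_within_between(summary)
        report["categories"][family] = {
            "within_mean": mw,
            "within_sd": sw,
            "between_mean": mb,
            "between_sd": sb,
        }
    write_json(report["categories"], out / "categories_summary.json")
    artifacts.append(out / "categories_summary.json")
    log.info("categories in %.1fs", time.perf_counter() - t)

    # -- trajectories -------------------------------------------------------
    t = _stage("trajectories")
    trajectories = build_trajectories(embedding, status.total_clinical, cdist, status.n_diagnoses)
    write_frame = trajectories_frame(trajectories)
    write_frame.to_csv(out / "trajectories.csv", index=False, float_format=FLOAT_FMT)
    events = detect_transitions(trajectories, boundary)
    events_frame(events).to_csv(out / "events.csv", index=False)
    artifacts += [out / "trajectories.csv", out / "events.csv"]
    n_improved = sum(e.direction == "improved" for e in events)
    n_worsened = sum(e.direction == "worsened" for e in events)
    report["transitions"] = {"improved": n_improved, "worsened": n_worsened}
    log.info("trajectories in %.1fs", time.perf_counter() - t)

    if config.plot:
        from . import plots

        plots.render_all(out, embedding, boundary, status)

    # -- manifest -----------------------------------------------------------
    report["runtime_seconds"] = time.perf_counter() - t_start
    manifest_config = {k: v for k, v in _config_dict(config).items() if k != "out"}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": manifest_config,
        "hashes": {p.name: _sha256(p) for p in artifacts if p.exists()},
    }
    write_json(manifest, out / "manifest.json")
    write_json(_json_safe(report), out / "report.json")
    return report


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["rose_disorders"] = list(d["rose_disorders"])
    return d


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _subset_distance(dist, labels):
    from .space import DistanceMatrix

    pos = dist.index.get_indexer(labels)
    if (pos < 0).any():
        raise ValueError("labels not present in the distance matrix")
    return DistanceMatrix(values=dist.values[np.ix_(pos, pos)], index=pd.MultiIndex.from_tuples(list(labels), names=["person_id", "timepoint"]))
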
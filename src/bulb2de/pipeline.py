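"""End-to-end pipeline: simulate → detect/ingest → match → normalize →
SVQ calling → aggregation → summary, as one reproducible, configured run.

Every stage writes plain CSV/JSON so any stage can be re-run standalone
on user data; the run's full configuration (including the mandatory seed)
is copied into the output directory together with a config hash, and a
run is a pure function of its config.
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
from scipy.spatial import cKDTree

from . import __version__
from .catalog import generate_catalog, write_catalog
from .cohort import (CohortTruth, EffectDesign, generate_cohort,
                     plant_effects, render_gel)
from .diffexp import (DEFAULT_HIGH, DEFAULT_LOW, DEFAULT_MIN_GELS,
                      DIFFERENTIAL_STATUSES, DifferentialCall,
                      aggregate_by_accession, call_cluster, compute_svq,
                      summarize, tallies, validate_thresholds)
from .gel_analysis import (detect_spots, match_spots,
                           normalize_volumes, select_reference,
                           write_clusters_csv)
from .pmf import PMFParams

__all__ = ["DetectorParams", "RunConfig", "RunReport", "run_pipeline",
           "compare_to_truth", "ConfigError"]

log = logging.getLogger("bulb2de")


class ConfigError(ValueError):
    """Run configuration failed validation."""


@dataclass
class DetectorParams:
    min_volume: float = 50.0
    min_separation: int = 3
    k_sigma: float = 5.0
    background_radius: int = 15


@dataclass
class RunConfig:
    """Full configuration of a pipeline run (seed is mandatory)."""

    seed: int
    design: EffectDesign = field(default_factory=EffectDesign)
    catalog_size: int = 850
    detector: DetectorParams = field(default_factory=DetectorParams)
    match_radius: float = 3.0
    svq_low: float = DEFAULT_LOW
    svq_high: float = DEFAULT_HIGH
    min_gels: int = DEFAULT_MIN_GELS
    pmf: PMFParams = field(default_factory=PMFParams)
    use_images: bool = False
    outdir: str | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory (no silent clock seeding)")
        try:
            validate_thresholds(self.svq_low, self.svq_high)
            self.design.validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        if self.catalog_size < 1:
            raise ConfigError("catalog_size must be >= 1")
        if self.match_radius <= 0:
            raise ConfigError("match_radius must be positive")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            raw = yaml.safe_load(Path(source).read_text())
        else:
            raw = yaml.safe_load(source)
        raw = dict(raw)
        if "design" in raw:
            raw["design"] = EffectDesign(**raw["design"])
        if "detector" in raw:
            raw["detector"] = DetectorParams(**raw["detector"])
        if "pmf" in raw:
            raw["pmf"] = PMFParams(**raw["pmf"])
        return cls(**raw)

    def sha256(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


@dataclass
class RunReport:
    """Result of one pipeline run, with provenance."""

    tallies: dict[str, int]
    summary: pd.DataFrame
    protein_calls: dict[str, DifferentialCall]
    cluster_calls: dict[str, DifferentialCall]
    cluster_to_accession: dict[str, str]
    truth: CohortTruth
    config: RunConfig
    provenance: dict

    def __post_init__(self):
        row = self.tallies
        assert row["total"] == (row["up"] + row["down"]
                                + row["absent_cmp"] + row["absent_p90"]), \
            "tallies inconsistent: total != sum of differential classes"


def _majority_accession(cluster, gels_by_id) -> str | None:
    """Accession carried by most member spot_ids (synthetic ``acc.k`` ids)."""
    votes: dict[str, int] = {}
    for gel_id, sid in cluster.members.items():
        acc = sid.rsplit(".", 1)[0] if "." in sid else None
        if acc:
            votes[acc] = votes.get(acc, 0) + 1
    if not votes:
        return None
    return max(sorted(votes), key=votes.get)


def assign_clusters_to_truth(clusters, truth: CohortTruth,
                             radius: float) -> dict[str, str]:
    """Map clusters to truth accessions by nearest truth-spot position.

    Used on the image path, where detection discards synthetic spot ids.
    The reference gel carries its own affine distortion relative to the
    undistorted truth grid, so truth positions are first registered to
    the reference frame like any other gel.
    """
    from .gel_analysis import _estimate_affine

    pos = truth.spot_positions
    truth_xy = pos[["x", "y"]].to_numpy(dtype=float)
    ref_xy = np.array([[c.x_ref, c.y_ref] for c in clusters])
    model = _estimate_affine(truth_xy, ref_xy, "truth")
    mapped = model(truth_xy)
    tree = cKDTree(mapped)
    mapping = {}
    for c, xy in zip(clusters, ref_xy):
        d, i = tree.query(xy)
        if d <= radius:
            mapping[c.cluster_id] = str(pos["accession"].iloc[int(i)])
    return mapping


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full synthetic pipeline under ``config``.

    Stages: catalog generation, effect planting, cohort simulation,
    optionally image rendering + spot detection (``use_images``),
    normalization, reference selection, matching, per-cluster SVQ calling,
    protein aggregation and category summary.  Deterministic given the
    config seed; intermediates are written to ``config.outdir`` when set.
    """
    config.validate()
    design = dataclasses.replace(config.design, seed=config.seed)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "run_config.yaml")

    log.info("stage catalog: %d proteins", config.catalog_size)
    catalog = generate_catalog(config.catalog_size, seed=config.seed)
    truth = plant_effects(catalog, design)
    log.info("stage simulate: %d gels per group", design.gels_per_group)
    cmp_gels, ref_gels = generate_cohort(truth, design)

    if config.use_images:
        log.info("stage render+detect")
        rng = np.random.default_rng([config.seed, 2])
        det = config.detector

        def redetect(gel):
            img = render_gel(gel, rng=rng)
            return detect_spots(
                img, min_volume=det.min_volume,
                min_separation=det.min_separation, k_sigma=det.k_sigma,
                background_radius=det.background_radius, gel_id=gel.gel_id)

        cmp_gels = [redetect(g) for g in cmp_gels]
        ref_gels = [redetect(g) for g in ref_gels]

    cmp_gels = [normalize_volumes(g) for g in cmp_gels]
    ref_gels = [normalize_volumes(g) for g in ref_gels]
    all_gels = cmp_gels + ref_gels

    reference = select_reference(all_gels)
    log.info("stage match: reference %s", reference)
    clusters = match_spots(all_gels, reference, radius=config.match_radius)

    log.info("stage diffexp: %d clusters", len(clusters))
    cluster_calls = {}
    for c in clusters:
        res = compute_svq(c, ref_gels, cmp_gels)
        cluster_calls[c.cluster_id] = call_cluster(
            res, low=config.svq_low, high=config.svq_high,
            min_gels=config.min_gels)

    if config.use_images:
        c2a = assign_clusters_to_truth(clusters, truth, config.match_radius)
    else:
        c2a = {c.cluster_id: acc for c in clusters
               if (acc := _majority_accession(c, None)) is not None}

    protein_calls = aggregate_by_accession(
        cluster_calls, c2a, low=config.svq_low, high=config.svq_high)
    categories = {r.accession: r.category for r in catalog}
    summary = summarize(protein_calls, categories)
    t = tallies(summary)
    provenance = {"config_sha256": config.sha256(), "seed": config.seed,
                  "version": __version__, "reference_gel": reference,
                  "n_clusters": len(clusters)}

    if outdir:
        write_catalog(catalog, outdir / "catalog.fasta",
                      outdir / "catalog_meta.csv")
        for g in all_gels:
            g.to_csv(outdir / f"spots_{g.gel_id}.csv")
        write_clusters_csv(clusters, outdir / "clusters.csv")
        calls_df = pd.DataFrame([
            {"accession": acc, "status": c.status, "mean_svq": c.mean_svq,
             "n_spots": len(c.svq_values)}
            for acc, c in protein_calls.items()])
        calls_df.to_csv(outdir / "protein_calls.csv", index=False)
        summary.to_csv(outdir / "summary_by_category.csv")
        (outdir / "report.json").write_text(json.dumps(
            {"tallies": t, "provenance": provenance}, indent=2))

    return RunReport(tallies=t, summary=summary,
                     protein_calls=protein_calls,
                     cluster_calls=cluster_calls,
                     cluster_to_accession=c2a, truth=truth, config=config,
                     provenance=provenance)


def compare_to_truth(report: RunReport,
                     truth: CohortTruth | None = None) -> dict:
    """Recovery metrics of a run against its planted truth.

    Per planted class: sensitivity = fraction of planted proteins
    recovered with exactly that status.  Specificity = fraction of
    unchanged proteins *not* called differential.
    """
    truth = truth or report.truth
    if truth.comparison != report.config.design.comparison:
        raise ValueError(
            f"report is for {report.config.design.comparison!r}, truth for "
            f"{truth.comparison!r}")
    metrics: dict[str, float] = {}
    for cls in DIFFERENTIAL_STATUSES:
        planted = [a for a, c in truth.classes.items() if c == cls]
        if not planted:
            continue
        hit = sum(1 for a in planted
                  if a in report.protein_calls
                  and report.protein_calls[a].status == cls)
        metrics[f"sensitivity_{cls}"] = hit / len(planted)
    unchanged = [a for a, c in truth.classes.items() if c == "unchanged"]
    if unchanged:
        false = sum(1 for a in unchanged
                    if a in report.protein_calls
                    and report.protein_calls[a].status
                    in DIFFERENTIAL_STATUSES)
        metrics["specificity"] = 1.0 - false / len(unchanged)
        metrics["false_call_rate"] = false / len(unchanged)
    return metrics
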
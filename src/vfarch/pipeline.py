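"""End-to-end pipeline: simulate -> fit -> select-k -> calibrate -> decompose
-> analyze -> match, with provenance.

A single global seed is fanned out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so stages are independently
reproducible.  Every artifact is listed in a manifest with its SHA-256
content hash; re-running with the same configuration and seed reproduces
identical hashes for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as vf_io
from .archetypes import ArchetypeModel, FitOptions, decompose_matrix, fit_archetypes
from .cohort import EyeSeries, dominant_at, meaningful_at_count
from .grids import GRID_24_2
from .matching import (
    MatchOutcome,
    classify_match,
    default_match_table,
    load_match_table,
    matching_summary,
)
from .model_selection import cv_rss_curve, select_num_archetypes
from .synthetic import (
    CohortConfig,
    default_normative_map,
    make_pattern_library,
    simulate_controls,
    simulate_on_cohort,
)
from .threshold import control_change_stats, meaningful_threshold
from .vf_core import (
    CONTROL_RELIABILITY_POLICY,
    ON_RELIABILITY_POLICY,
    VFRecord,
    normalize_record,
    reliability_pass,
)

log = logging.getLogger("vfarch.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "render_decomposition_report", "td_matrix"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-serializable)."""

    out_dir: str = "vfarch_out"
    seed: int = 0
    n_eyes: int = 456
    n_controls: int = 61
    control_visits: int = 9
    k: Optional[int] = 16  # fixed model order; None selects k by CV
    k_min: int = 2
    k_max: int = 20
    folds: int = 10
    epsilon: float = 0.05
    n_restarts: int = 5
    threshold_override: Optional[int] = None
    match_table_path: Optional[str] = None
    on_input: Optional[str] = None  # CSV paths; None simulates
    control_input: Optional[str] = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (2 <= self.k_min < self.k_max):
            raise ValueError("k_min/k_max: need 2 <= k_min < k_max")
        if self.k is not None and self.k < 2:
            raise ValueError("k: model order must be >= 2")
        if self.folds < 2:
            raise ValueError("folds: need >= 2")
        for path_field in ("on_input", "control_input", "match_table_path"):
            p = getattr(self, path_field)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{path_field}: path {p!r} does not exist")


def td_matrix(records: Sequence[VFRecord]) -> np.ndarray:
    """Stack normalized (right-eye 24-2) TD vectors into a data matrix."""
    return np.vstack([normalize_record(r).td for r in records])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str, t0: float, **counts) -> None:
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage=%s elapsed=%.1fs %s", name, time.time() - t0, extra)


def render_decomposition_report(
    eye: EyeSeries, model: ArchetypeModel, threshold: float
) -> pd.DataFrame:
    """Per-visit table of MD and the AT weights at or above the threshold.

    Weights below the threshold at every visit are dropped from the table
    (they are indistinguishable from test-retest fluctuation); the retained
    columns therefore sum to at most 100 per row.
    """
    if eye.weights.shape[0] == 0:
        raise ValueError("eye series is empty")
    keep = np.flatnonzero((eye.weights >= threshold).any(axis=0))
    cols = {f"AT{j + 1}": eye.weights[:, j] for j in keep}
    out = pd.DataFrame({"visit_day": eye.visit_days, "md": eye.md, **cols})
    return out


def _eye_series(records: Sequence[VFRecord], W: np.ndarray) -> List[EyeSeries]:
    by_eye: Dict[str, List[int]] = {}
    for i, r in enumerate(records):
        by_eye.setdefault(r.eye_id, []).append(i)
    series = []
    for eye_id, idx in by_eye.items():
        idx = sorted(idx, key=lambda i: records[i].visit_day)
        series.append(
            EyeSeries(
                eye_id=eye_id,
                visit_days=np.array([records[i].visit_day for i in idx]),
                weights=W[idx],
                md=np.array([records[i].md for i in idx], dtype=float),
                psd=np.array(
                    [np.nan if records[i].psd is None else records[i].psd for i in idx]
                ),
            )
        )
    return series


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the artifact manifest (also written to disk)."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    manifest: Dict[str, str] = {}
    artifacts: List[Path] = []
    current = "simulate"
    try:
        # --- inputs -------------------------------------------------------
        t0 = time.time()
        lib = make_pattern_library(GRID_24_2)
        if cfg.on_input:
            on_records = vf_io.read_vf_table(cfg.on_input)
        else:
            on_cfg = CohortConfig(n_eyes=cfg.n_eyes, seed=stage_seed[0])
            on_records, _ = simulate_on_cohort(lib, on_cfg)
            vf_io.write_vf_table(on_records, out / "on_cohort.csv")
            artifacts.append(out / "on_cohort.csv")
        if cfg.control_input:
            control_records = vf_io.read_vf_table(cfg.control_input)
        else:
            control_records, _ = simulate_controls(
                lib, n_eyes=cfg.n_controls, n_visits=cfg.control_visits,
                seed=stage_seed[1],
            )
            vf_io.write_vf_table(control_records, out / "controls.csv")
            artifacts.append(out / "controls.csv")
        on_records = [
            r for r in on_records if reliability_pass(r, ON_RELIABILITY_POLICY)
        ]
        control_records = [
            r for r in control_records if reliability_pass(r, CONTROL_RELIABILITY_POLICY)
        ]
        _stage("simulate", t0, on=len(on_records), controls=len(control_records))

        # --- model order --------------------------------------------------
        current = "select-k"
        t0 = time.time()
        X = td_matrix(on_records)
        opts = FitOptions(n_restarts=cfg.n_restarts, seed=stage_seed[2])
        if cfg.k is None:
            curve = cv_rss_curve(
                X,
                range(cfg.k_min, cfg.k_max + 1),
                folds=cfg.folds,
                seed=stage_seed[2],
                opts=FitOptions(n_restarts=1, max_iter=100, rel_tol=1e-5,
                                seed=stage_seed[2]),
            )
            curve.to_frame().to_csv(out / "curve.csv", index=False)
            artifacts.append(out / "curve.csv")
            k = select_num_archetypes(curve, cfg.epsilon)
        else:
            k = cfg.k
        _stage("select-k", t0, k=k)

        # --- fit ----------------------------------------------------------
        current = "fit"
        t0 = time.time()
        model = fit_archetypes(X, k, opts)
        model.to_json(out / "model.json")
        artifacts.append(out / "model.json")
        _stage("fit", t0, n=X.shape[0], k=k, rss=round(model.fit_rss, 2))

        # --- calibrate ----------------------------------------------------
        current = "calibrate"
        t0 = time.time()
        ctrl_by_eye: Dict[str, List[VFRecord]] = {}
        for r in control_records:
            ctrl_by_eye.setdefault(r.eye_id, []).append(r)
        trajectories = []
        for eye_id, recs in ctrl_by_eye.items():
            recs = sorted(recs, key=lambda r: r.visit_day)
            if len(recs) < 2:
                continue
            trajectories.append(decompose_matrix(td_matrix(recs), model))
        normal_at = int(np.argmax(model.avg_td))
        stats = control_change_stats(trajectories, normal_at=normal_at)
        result = meaningful_threshold(stats, model.k)
        threshold = (
            cfg.threshold_override if cfg.threshold_override is not None
            else result.threshold
        )
        stats.to_frame().to_csv(out / "control_change_stats.csv", index=False)
        artifacts.append(out / "control_change_stats.csv")
        with open(out / "threshold.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "ci_upper_max": result.ci_upper_max,
                    "floor_1_over_k": result.floor_1_over_k,
                    "threshold": result.threshold,
                    "threshold_used": threshold,
                    "normal_at": normal_at + 1,
                },
                fh,
                indent=1,
            )
        artifacts.append(out / "threshold.json")
        _stage("calibrate", t0, threshold=threshold)

        # --- decompose ----------------------------------------------------
        current = "decompose"
        t0 = time.time()
        W = decompose_matrix(X, model)
        wdf = pd.DataFrame(W, columns=[f"AT{j + 1}" for j in range(model.k)])
        wdf.insert(0, "eye_id", [r.eye_id for r in on_records])
        wdf.insert(1, "visit_day", [r.visit_day for r in on_records])
        wdf.to_csv(out / "weights.csv", index=False)
        artifacts.append(out / "weights.csv")
        _stage("decompose", t0, rows=W.shape[0])

        # --- analyze ------------------------------------------------------
        current = "analyze"
        t0 = time.time()
        report_dir = out / "report"
        report_dir.mkdir(exist_ok=True)
        seen = set()
        baseline_idx = []
        for i, r in enumerate(on_records):
            if r.visit_day == 0 and r.eye_id not in seen:
                seen.add(r.eye_id)
                baseline_idx.append(i)
        Wb = W[baseline_idx]
        counts = [meaningful_at_count(w, threshold) for w in Wb]
        pd.DataFrame(
            {
                "n_meaningful_ats": np.arange(0, max(counts) + 1),
                "n_eyes": [counts.count(c) for c in range(0, max(counts) + 1)],
            }
        ).to_csv(report_dir / "meaningful_at_histogram.csv", index=False)
        freq = (Wb >= threshold).sum(axis=0)
        pd.DataFrame(
            {"at": np.arange(1, model.k + 1), "n_eyes_meaningful": freq}
        ).to_csv(report_dir / "meaningful_at_frequency.csv", index=False)
        md_b = np.array([on_records[i].md for i in baseline_idx], dtype=float)
        from .cohort import spearman_with_bonferroni

        pairs = [
            (f"AT{j + 1}~MD", Wb[:, j], md_b) for j in range(model.k)
        ]
        spearman_with_bonferroni(pairs).to_csv(
            report_dir / "correlations_md.csv", index=False
        )
        artifacts.extend(
            [
                report_dir / "meaningful_at_histogram.csv",
                report_dir / "meaningful_at_frequency.csv",
                report_dir / "correlations_md.csv",
            ]
        )
        # archetype heat-map exports: one CSV grid per AT
        xy = np.asarray(GRID_24_2.analysis_locations)
        for j in range(model.k):
            grid_df = pd.DataFrame(
                {"x": xy[:, 0], "y": xy[:, 1], "td": model.archetype_td[j]}
            )
            grid_df.to_csv(report_dir / f"archetype_AT{j + 1}.csv", index=False)
        _stage("analyze", t0, baseline=len(baseline_idx))

        # --- match --------------------------------------------------------
        current = "match"
        t0 = time.time()
        table = (
            load_match_table(cfg.match_table_path)
            if cfg.match_table_path
            else default_match_table()
        )
        rows = []
        for i in baseline_idx:
            r = on_records[i]
            if r.expert_label is None:
                continue
            dom = dominant_at(W[i])
            dom_at = None if dom is None else dom + 1
            if dom_at is not None and dom_at not in table.full:
                continue  # model larger than the table; skip unmapped ATs
            outcome = classify_match(dom_at, r.expert_label, table)
            rows.append(
                {
                    "eye_id": r.eye_id,
                    "dominant_at": dom_at,
                    "expert_label": r.expert_label,
                    "outcome": outcome.value,
                }
            )
        match_df = pd.DataFrame(rows)
        match_df.to_csv(out / "match_report.csv", index=False)
        artifacts.append(out / "match_report.csv")
        summary = (
            matching_summary([MatchOutcome(o) for o in match_df["outcome"]])
            if len(match_df)
            else {"n": 0}
        )
        with open(out / "match_summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1)
        artifacts.append(out / "match_summary.json")
        _stage("match", t0, labeled=len(rows))
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {current!r} failed: {exc} "
            f"(partial outputs preserved in {out})"
        ) from exc

    manifest = {str(p.relative_to(out)): _sha256(p) for p in artifacts}
    manifest_doc = {"seed": cfg.seed, "artifacts": manifest}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest_doc, fh, indent=1)
    return manifest_doc
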
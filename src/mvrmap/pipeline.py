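"""End-to-end orchestration: simulate -> localize -> quantal -> sitemap -> mvrstats.

:func:`run_pipeline` executes the whole analysis on either a synthetic
experiment (the generator's study conditions), a pre-localized event
table, or ground-truth passthrough (true positions analyzed directly,
bypassing rendering and fitting — useful for separating imaging error from
analysis behavior). The per-bouton minimum-events filter is applied before
any quantal or site-level analysis, and the run's accounting identity
(total = analyzed + excluded + fit failures) is asserted on every report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, localize, mvrstats, quantal, sitemap, synthkit
from .errors import BoutonExcluded, ConfigurationError, ParameterError

__all__ = ["PipelineConfig", "Report", "run_pipeline", "load_config",
           "simulate_experiment"]

logger = logging.getLogger("mvrmap")


@dataclass(frozen=True)
class PipelineConfig:
    """All analysis constants and simulation conditions of one run."""

    acquisition: synthkit.AcquisitionParams = field(
        default_factory=synthkit.AcquisitionParams
    )
    cluster_diameter_nm: float = 50.0
    proximity_radius_nm: float = 25.0
    band_halfwidth_nm: float = 25.0
    min_events_per_bouton: int = 5
    mvr_amp_sd_multiplier: float = 2.0
    alpha: float = 0.05
    snr_threshold: float = 5.0
    seed: int = 0
    condition: str = "control"
    # synthetic-experiment conditions
    n_boutons: int = 12
    az_radius_nm: float = 180.0
    n_sites: int = 8
    pr_center: float = 0.04
    pr_edge: float = 0.008
    mvr_fraction: float = 0.05
    desync_sd_ms: float = 2.0
    quantal_cv: float = 0.2

    def __post_init__(self) -> None:
        for name in ("cluster_diameter_nm", "proximity_radius_nm",
                     "band_halfwidth_nm", "mvr_amp_sd_multiplier", "alpha",
                     "snr_threshold"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.min_events_per_bouton < 1:
            raise ParameterError("min_events_per_bouton must be >= 1")
        if self.condition not in synthkit.CONDITIONS:
            raise ParameterError(f"condition must be one of {synthkit.CONDITIONS}")

    def analysis_dict(self) -> dict:
        """Analysis-relevant parameters (drives the config hash)."""
        d = asdict(self)
        d["acquisition"] = asdict(self.acquisition)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.analysis_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML mapping (missing keys -> defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    acq = synthkit.AcquisitionParams(**raw.pop("acquisition", {}))
    return PipelineConfig(acquisition=acq, **raw)


@dataclass
class Report:
    """Machine-readable result bundle of one pipeline run."""

    counts: dict
    boutons: list
    sites: pd.DataFrame
    pairs: pd.DataFrame
    events: pd.DataFrame
    quantal: list
    tests: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "schema_version": io.REPORT_SCHEMA_VERSION,
            "provenance": self.provenance,
            "counts": self.counts,
            "boutons": self.boutons,
            "sites": self.sites.to_dict(orient="records"),
            "pairs": self.pairs.to_dict(orient="records"),
            "quantal": self.quantal,
            "tests": self.tests,
        }


# ---------------------------------------------------------------------------
# simulation front end

def simulate_experiment(config: PipelineConfig, seed: int | None = None):
    """Generate boutons and their ground-truth event sequences."""
    seed = config.seed if seed is None else seed
    boutons, truths = [], []
    for b in range(config.n_boutons):
        bouton = synthkit.make_bouton_model(
            az_radius_nm=config.az_radius_nm,
            n_sites=config.n_sites,
            pr_center=config.pr_center,
            pr_edge=config.pr_edge,
            condition=config.condition,
            seed=seed * 100_003 + b,
            bouton_id=f"b{b:03d}",
        )
        events = synthkit.sample_release_sequence(
            bouton, config.acquisition,
            mvr_fraction=config.mvr_fraction,
            desync_sd_ms=config.desync_sd_ms,
            quantal_cv=config.quantal_cv,
            seed=seed * 100_003 + 50_000 + b,
        )
        boutons.append(bouton)
        truths.append(events)
    return boutons, truths


def _localize_bouton(
    truth: list[synthkit.GroundTruthEvent],
    config: PipelineConfig,
    psf: localize.PsfModel,
    seed: int,
) -> tuple[list[dict], int]:
    """Render and localize one bouton's frame pairs; returns (records, n_fail)."""
    acq = config.acquisition
    half_fov = acq.fov_nm / 2.0
    by_stim: dict[int, list] = {}
    for ev in truth:
        by_stim.setdefault(ev.stimulus_index, []).append(ev)
    records, n_fail = [], 0
    merge_gap = 2 * localize.roi_window_half(psf.sigma, acq.pixel_size_nm) + 1
    for s, evs in sorted(by_stim.items()):
        pair = synthkit.render_frame_pair(evs, acq, seed=seed * 131 + s)
        rois = localize.detect_candidates(
            pair, psf, snr_threshold=config.snr_threshold,
            pixel_size_nm=acq.pixel_size_nm,
        )
        rois = localize.merge_rois(rois, pair.post - pair.pre, merge_gap)
        for roi in rois:
            mix = localize.fit_two_gaussian_mixture(roi, psf, alpha=config.alpha)
            asym = localize.fit_asymmetric_gaussian(roi)
            if not all(c.converged for c in mix.components):
                n_fail += 1
                logger.info("bouton %s stim %d: fit failure, event discarded",
                            evs[0].bouton_id, s)
                continue
            for comp in mix.components:
                records.append({
                    "bouton_id": evs[0].bouton_id,
                    "stimulus_index": s,
                    "x_nm": comp.x_nm - half_fov,
                    "y_nm": comp.y_nm - half_fov,
                    "amplitude": comp.amplitude,
                    "sigma_nm": comp.sigma_fit,
                    "precision_nm": comp.precision,
                    "n_components": mix.n_selected,
                    "delta1_nm": asym.delta1 if mix.n_selected == 1 else np.nan,
                    "delta2_nm": asym.delta2 if mix.n_selected == 1 else np.nan,
                    "asym_score": (asym.asymmetry_score
                                   if mix.n_selected == 1 else np.nan),
                })
    return records, n_fail


def _truth_records(truth: list[synthkit.GroundTruthEvent]) -> list[dict]:
    return [
        {
            "bouton_id": ev.bouton_id,
            "stimulus_index": ev.stimulus_index,
            "x_nm": ev.x_nm,
            "y_nm": ev.y_nm,
            "amplitude": ev.amplitude,
            "sigma_nm": np.nan,
            "precision_nm": 0.0,
            "n_components": 1,
            "delta1_nm": np.nan,
            "delta2_nm": np.nan,
            "asym_score": np.nan,
        }
        for ev in truth
    ]


def _assign_pairs(events: pd.DataFrame) -> pd.DataFrame:
    """Mark resolved MVR pairs: exactly two co-frame events in one bouton."""
    out = events.copy()
    out["pair_id"] = ""
    out["label"] = quantal.LABEL_UVR
    for (bid, s), grp in out.groupby(["bouton_id", "stimulus_index"]):
        if len(grp) == 2:
            pid = f"{bid}-s{s}"
            out.loc[grp.index, "pair_id"] = pid
            out.loc[grp.index, "label"] = quantal.LABEL_MVR_RESOLVED
    return out


def run_pipeline(config: PipelineConfig, input="synthetic",
                 mode: str = "imaging", seed: int | None = None) -> Report:
    """Run the full analysis and return the machine-readable report.

    ``input`` is ``"synthetic"`` (simulate the configured experiment), a
    path to an event table, or a pre-built events DataFrame. ``mode``
    selects the imaging path (render frames, detect, fit) or ground-truth
    passthrough (``"truth"``); it is ignored for table input.
    """
    seed = config.seed if seed is None else seed
    acq = config.acquisition

    if isinstance(input, str) and input == "synthetic":
        _, truths = simulate_experiment(config, seed=seed)
        records: list[dict] = []
        n_fail = 0
        psf = localize.PsfModel(sigma=acq.psf_sigma_nm)
        for b, truth in enumerate(truths):
            if not truth:
                continue
            if mode == "imaging":
                recs, nf = _localize_bouton(truth, config, psf, seed=seed * 977 + b)
                records.extend(recs)
                n_fail += nf
            elif mode == "truth":
                records.extend(_truth_records(truth))
            else:
                raise ParameterError(f"unknown mode {mode!r}")
        events = pd.DataFrame(
            records, columns=localize._LOC_COLUMNS
        ) if records else pd.DataFrame(columns=localize._LOC_COLUMNS)
    elif isinstance(input, pd.DataFrame):
        events, n_fail = input.copy(), 0
    else:
        events, n_fail = io.read_event_table(input), 0

    events = _assign_pairs(events)
    events["t_s"] = events["stimulus_index"].astype(float) / acq.stim_rate_hz

    n_total = len(events) + n_fail
    logger.info("localization: %d events, %d fit failures", len(events), n_fail)

    # --- per-bouton min-events filter, bleach correction, quantal analysis
    analyzed_parts, quantal_records = [], []
    n_excluded = 0
    for bid, grp in events.groupby("bouton_id", sort=True):
        if len(grp) < config.min_events_per_bouton:
            n_excluded += len(grp)
            continue
        grp, tau = quantal.correct_photobleaching(grp, amplitude_col="amplitude")
        stats = quantal.quantal_stats(
            grp, bouton_id=str(bid), bleach_tau_s=tau,
            sd_mult=config.mvr_amp_sd_multiplier,
        )
        grp = quantal.classify_mvr_by_amplitude(grp, stats)
        grp["q_mean"] = stats.q_mean
        grp["q_sd"] = stats.q_sd
        grp["mvr_threshold"] = stats.mvr_threshold
        analyzed_parts.append(grp)
        quantal_records.append({
            "bouton_id": stats.bouton_id,
            "q_mean": stats.q_mean,
            "q_sd": stats.q_sd,
            "mvr_threshold": stats.mvr_threshold,
            "n_events": stats.n_events,
            "bleach_tau_fit_s": (None if math.isinf(stats.bleach_tau_fit)
                                 else stats.bleach_tau_fit),
        })
    analyzed = (pd.concat(analyzed_parts, ignore_index=True)
                if analyzed_parts else pd.DataFrame())
    n_analyzed = len(analyzed)
    assert n_total == n_analyzed + n_excluded + n_fail, "filter accounting broken"

    # --- site-level analyses
    bouton_summaries, all_sites, pair_objs = [], [], []
    for bid, grp in (analyzed.groupby("bouton_id", sort=True)
                     if n_analyzed else ()):
        pos = grp[["x_nm", "y_nm"]].to_numpy(dtype=float)
        geom = sitemap.compute_az_geometry(pos, bouton_id=str(bid))
        sites = sitemap.cluster_release_sites(
            pos, bouton_id=str(bid), event_ids=list(grp.index),
            diameter=config.cluster_diameter_nm,
        )
        sites = sitemap.assign_site_pr(sites, acq.n_stimuli,
                                       az_center=geom.center)
        all_sites.extend(sites)
        # map event index -> site
        ev_site = {eid: s for s in sites for eid in s.member_event_ids}
        uvr_site_ids = {
            ev_site[i].site_id for i in grp.index
            if grp.loc[i, "label"] == quantal.LABEL_UVR
        }
        for pid, pgrp in grp[grp["pair_id"] != ""].groupby("pair_id"):
            if len(pgrp) != 2:
                continue
            i_a, i_b = list(pgrp.index)
            pair = mvrstats.characterize_mvr_pair(
                pid, str(bid), int(pgrp["stimulus_index"].iloc[0]),
                pos_a := pgrp.loc[i_a, ["x_nm", "y_nm"]].to_numpy(dtype=float),
                pos_b := pgrp.loc[i_b, ["x_nm", "y_nm"]].to_numpy(dtype=float),
                float(pgrp.loc[i_a, "amplitude_corrected"]),
                float(pgrp.loc[i_b, "amplitude_corrected"]),
                az_center=geom.center,
            )
            pair_objs.append(pair)
        bouton_summaries.append({
            "bouton_id": str(bid),
            "center_x_nm": float(geom.center[0]),
            "center_y_nm": float(geom.center[1]),
            "hull_area_um2": geom.hull_area_um2,
            "degenerate_hull": geom.degenerate,
            "n_events": int(len(grp)),
            "n_sites": len(sites),
        })

    sites_table = sitemap.sites_to_table(all_sites)
    pairs_table = mvrstats.pairs_to_table(pair_objs)

    # --- population statistics
    tests: dict[str, dict] = {}
    if len(pair_objs) >= 3:
        fit = mvrstats.amp_diff_vs_separation_fit(pair_objs)
        tests["amp_diff_vs_separation"] = {
            "test_name": "ols_slope", "statistic": fit.slope,
            "p_value": fit.p_value, "n": fit.n,
            "intercept": fit.intercept, "slope_se": fit.slope_se,
        }
        fr600 = mvrstats.separation_fraction_below(pair_objs, [400.0, 600.0])
        tests["separation_fraction"] = {
            "test_name": "ecdf", "statistic": fr600[1], "p_value": 1.0,
            "n": len(pair_objs),
            "fraction_below_400nm": fr600[0], "fraction_below_600nm": fr600[1],
        }
    untied = [p for p in pair_objs if not (p.amplitude_tie or p.distance_tie)]
    if len(untied) >= 10:
        t = mvrstats.larger_event_position_test(pair_objs)
        tests["larger_event_position"] = {
            "test_name": t.test_name, "statistic": t.statistic,
            "p_value": t.p_value, "n": t.extra["n_pairs"], **t.extra,
        }
    if n_analyzed and analyzed["stimulus_index"].nunique() >= 2:
        trend = mvrstats.double_event_train_trend(analyzed)
        tests["double_event_train_trend"] = {
            "test_name": "ols_slope", "statistic": trend.slope,
            "p_value": trend.p_value, "n": trend.n,
            "slope_se": trend.slope_se,
        }

    counts = {
        "n_events_total": int(n_total),
        "n_analyzed": int(n_analyzed),
        "n_excluded_by_min_events": int(n_excluded),
        "n_fit_failures": int(n_fail),
        "n_boutons_analyzed": len(bouton_summaries),
        "n_sites": len(all_sites),
        "n_resolved_pairs": len(pair_objs),
        "n_mvr_unresolved": int((analyzed["label"] ==
                                 quantal.LABEL_MVR_UNRESOLVED).sum())
        if n_analyzed else 0,
    }
    from . import __version__

    provenance = {
        "config_hash": config.config_hash(),
        "seed": int(seed),
        "condition": config.condition,
        "mode": mode,
        "package_version": __version__,
    }
    return Report(
        counts=counts, boutons=bouton_summaries, sites=sites_table,
        pairs=pairs_table, events=analyzed, quantal=quantal_records,
        tests=tests, provenance=provenance,
    )
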
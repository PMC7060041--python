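"""Synthetic ground truth for single-active-zone release imaging.

This module simulates the data-generating process the downstream analysis
assumes: a synaptic bouton whose active zone (AZ) contains a handful of
discrete release sites, each firing independently per action potential with
a release probability that decays linearly from the AZ center to the
periphery; occasional multi-vesicular release (MVR), in which a second
vesicle fuses at another site within the same 40 ms acquisition frame after
a millisecond-scale delay; and a camera model (pixel-integrated Gaussian
PSF, Poisson photon noise, constant background, Gaussian read noise, slow
photobleaching) that renders each stimulus as a pre/post frame pair.

Coordinates are continuous, in nanometres. Within a rendered field the
origin sits at the field corner and pixel (i, j) spans rows
[i*px, (i+1)*px) in y and columns [j*px, (j+1)*px) in x (0-based,
half-open). Bouton-local coordinates place the AZ center at (0, 0); the
renderer shifts them to the field center.

Two pharmacology-like condition modes alter the generative process:
``egta`` (slow calcium chelator) tightens the radial offset of the second
fusion of an MVR pair, and ``strontium`` makes all release asynchronous,
drawing fusion delays uniformly within the frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .errors import ConfigurationError, ParameterError

__all__ = [
    "AcquisitionParams",
    "BoutonModel",
    "GroundTruthEvent",
    "FramePair",
    "make_bouton_model",
    "sample_release_sequence",
    "render_frame_pair",
    "simulate_bead_stack",
    "events_to_table",
    "table_to_events",
    "write_truth_table",
    "read_truth_table",
    "write_frame_pairs",
]

CONDITIONS = ("control", "egta", "strontium")

#: nm scale of the second-site offset weighting, per condition
_SPREAD_SCALE_NM = {"control": 250.0, "egta": 120.0, "strontium": 250.0}


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera / stimulation constants of the imaging experiment.

    Defaults reflect the acquisition this analysis is designed for:
    65 nm effective pixels, 40 ms frames (one pre-stimulus frame 45 ms
    before each stimulus, one stimulus-locked frame), 1 Hz stimulation for
    120 s, and a ~130 nm-sigma PSF. The photon budget
    (``photons_per_quantum``, ``background_rate``, ``read_noise_sd``) is
    chosen so that the repeated-fit localization spread of a single-vesicle
    event is a few tens of nanometres, in line with the ~27 nm precision
    such recordings achieve.
    """

    pixel_size_nm: float = 65.0
    frame_duration_ms: float = 40.0
    pre_frame_offset_ms: float = 45.0
    psf_sigma_nm: float = 130.0
    photons_per_quantum: float = 300.0
    background_rate: float = 15.0  # photons / pixel / frame
    read_noise_sd: float = 2.0  # photons
    bleach_tau_s: float = 300.0
    n_stimuli: int = 120
    stim_rate_hz: float = 1.0
    fov_px: int = 48

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_nm", "frame_duration_ms", "pre_frame_offset_ms",
            "psf_sigma_nm", "photons_per_quantum", "background_rate",
            "read_noise_sd", "bleach_tau_s", "stim_rate_hz",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and positive, got {v!r}")
        if self.n_stimuli < 1:
            raise ParameterError("n_stimuli must be >= 1")
        if self.fov_px < 4:
            raise ParameterError("fov_px must be >= 4")
        if self.pixel_size_nm >= 4 * self.psf_sigma_nm:
            raise ParameterError(
                "pixel_size_nm must be < 4 x psf_sigma_nm for sub-pixel fitting"
            )

    @property
    def fov_nm(self) -> float:
        return self.fov_px * self.pixel_size_nm

    @property
    def duration_s(self) -> float:
        return self.n_stimuli / self.stim_rate_hz


@dataclass(frozen=True)
class BoutonModel:
    """A single active zone: release-site positions and probabilities.

    ``site_positions`` are bouton-local (AZ center at the origin);
    ``site_pr`` is each site's per-stimulus release probability.
    """

    bouton_id: str
    site_positions: np.ndarray  # (n_sites, 2) nm
    site_pr: np.ndarray  # (n_sites,)
    az_boundary_radius: float  # nm
    condition: str = "control"

    def __post_init__(self) -> None:
        pos = np.asarray(self.site_positions, dtype=float)
        pr = np.asarray(self.site_pr, dtype=float)
        object.__setattr__(self, "site_positions", pos)
        object.__setattr__(self, "site_pr", pr)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 1:
            raise ParameterError("site_positions must be a non-empty (n, 2) array")
        if pr.shape != (pos.shape[0],):
            raise ParameterError("site_pr must match site_positions in length")
        if not np.all(np.isfinite(pr)) or np.any(pr < 0) or np.any(pr > 1):
            raise ParameterError("site_pr values must lie in [0, 1]")
        radii = np.hypot(pos[:, 0], pos[:, 1])
        if np.any(radii > self.az_boundary_radius + 1e-9):
            raise ParameterError("all sites must lie within az_boundary_radius")
        if self.condition not in CONDITIONS:
            raise ParameterError(f"condition must be one of {CONDITIONS}")

    @property
    def n_sites(self) -> int:
        return self.site_positions.shape[0]

    @property
    def site_radii(self) -> np.ndarray:
        return np.hypot(self.site_positions[:, 0], self.site_positions[:, 1])


@dataclass(frozen=True)
class GroundTruthEvent:
    """One simulated vesicle fusion.

    ``quantal_amplitude`` is the full-frame photon content of the event
    (quantal variability and photobleaching applied); ``amplitude`` is the
    photon count actually collected given the intra-frame delay,
    quantal_amplitude x (frame - delay) / frame.
    """

    bouton_id: str
    stimulus_index: int
    site_index: int
    x_nm: float
    y_nm: float
    delay_ms: float
    quantal_amplitude: float
    amplitude: float
    is_mvr_member: bool = False
    pair_id: str | None = None


@dataclass(frozen=True)
class FramePair:
    """Pre-stimulus and stimulus-locked camera frames (photon counts)."""

    pre: np.ndarray
    post: np.ndarray
    bouton_id: str = ""
    stimulus_index: int = 0

    def __post_init__(self) -> None:
        if self.pre.shape != self.post.shape:
            raise ParameterError("pre and post frames must have identical shapes")
        if np.any(self.pre < 0) or np.any(self.post < 0):
            raise ParameterError("frame intensities must be nonnegative")


def make_bouton_model(
    az_radius_nm: float,
    n_sites: int,
    pr_center: float,
    pr_edge: float,
    condition: str = "control",
    seed: int = 0,
    min_spacing_nm: float = 60.0,
    bouton_id: str = "b0",
) -> BoutonModel:
    """Draw a bouton with sites uniform on the AZ disc and a linear P_r gradient.

    Site positions are rejection-sampled uniformly on the disc of radius
    ``az_radius_nm`` so that no two sites lie closer than ``min_spacing_nm``
    (keeps truth sites resolvable by the 50 nm clustering criterion). Each
    site's release probability is interpolated linearly in radial distance,
    ``pr_center`` at r = 0 down to ``pr_edge`` at r = az_radius_nm.
    """
    for name, v in (("pr_center", pr_center), ("pr_edge", pr_edge)):
        if not np.isfinite(v) or not (0.0 <= v <= 1.0):
            raise ParameterError(f"{name} must be in [0, 1], got {v!r}")
    if pr_edge > pr_center:
        raise ParameterError("pr_edge must not exceed pr_center")
    if n_sites < 1:
        raise ParameterError("n_sites must be >= 1")
    if az_radius_nm <= 0 or not np.isfinite(az_radius_nm):
        raise ParameterError("az_radius_nm must be positive")

    rng = np.random.default_rng(seed)
    positions: list[np.ndarray] = []
    max_tries = 20000 * n_sites
    tries = 0
    while len(positions) < n_sites:
        tries += 1
        if tries > max_tries:
            raise ParameterError(
                "could not place sites with the requested minimum spacing; "
                "reduce n_sites or min_spacing_nm"
            )
        r = az_radius_nm * math.sqrt(rng.random())
        th = 2 * math.pi * rng.random()
        p = np.array([r * math.cos(th), r * math.sin(th)])
        if all(np.hypot(*(p - q)) >= min_spacing_nm for q in positions):
            positions.append(p)
    pos = np.vstack(positions)
    radii = np.hypot(pos[:, 0], pos[:, 1])
    pr = pr_center + (pr_edge - pr_center) * radii / az_radius_nm
    return BoutonModel(
        bouton_id=bouton_id,
        site_positions=pos,
        site_pr=pr,
        az_boundary_radius=az_radius_nm,
        condition=condition,
    )


def _draw_quantum(rng: np.random.Generator, mean: float, cv: float) -> float:
    # quantal variability; floor keeps amplitudes physical
    return mean * max(rng.normal(1.0, cv), 0.05)


def _second_site(
    rng: np.random.Generator,
    bouton: BoutonModel,
    primary: int,
    spread_scale_nm: float,
    peripheral_bias: float,
) -> int:
    """Pick the second fusion site of an MVR pair.

    Weight ~ site P_r (both MVR sites tend to be high-P_r sites), damped by
    distance to the primary site (MVR pairs are predominantly short-range)
    and biased toward sites more peripheral than the primary (the delayed
    second fusion tends to occur farther from the AZ center).
    """
    pos = bouton.site_positions
    d = np.hypot(*(pos - pos[primary]).T)
    radii = bouton.site_radii
    w = bouton.site_pr * np.exp(-d / spread_scale_nm)
    w = w * np.where(radii > radii[primary], peripheral_bias, 1.0)
    w[primary] = 0.0
    if w.sum() <= 0:  # single-site bouton or degenerate weights
        return primary
    return int(rng.choice(len(w), p=w / w.sum()))


def sample_release_sequence(
    bouton: BoutonModel,
    acq: AcquisitionParams,
    mvr_fraction: float = 0.05,
    desync_sd_ms: float = 2.0,
    quantal_cv: float = 0.2,
    seed: int = 0,
    peripheral_bias: float = 2.0,
    site_jitter_nm: float = 0.0,
) -> list[GroundTruthEvent]:
    """Simulate the stimulus-locked fusion sequence of one bouton.

    Per stimulus every site fires independently with its P_r; when several
    sites fire at once, one fusion (uniformly among the firing sites) is
    kept, so spontaneous activity contributes at most one event per
    stimulus. A firing stimulus is then promoted to an MVR pair with
    probability ``mvr_fraction`` (at ~0.05 roughly 9-10% of all fusion
    events end up as members of MVR pairs); the second fusion is placed at
    another site chosen by :func:`_second_site` with a delay drawn
    |Normal(0, desync_sd_ms)| truncated to the frame. Under the
    ``strontium`` condition all delays are instead Uniform(0, frame).

    Quantal amplitudes carry Gaussian quantal variability (CV
    ``quantal_cv``), single-exponential photobleaching in experiment time,
    and the collected amplitude is reduced by the remaining-frame fraction
    (frame - delay) / frame.
    """
    if not (0.0 <= mvr_fraction <= 1.0):
        raise ParameterError("mvr_fraction must be in [0, 1]")
    if desync_sd_ms < 0 or quantal_cv < 0:
        raise ParameterError("desync_sd_ms and quantal_cv must be nonnegative")

    rng = np.random.default_rng(seed)
    frame = acq.frame_duration_ms
    spread = _SPREAD_SCALE_NM[bouton.condition]
    events: list[GroundTruthEvent] = []
    max_delay = frame * (1.0 - 1e-9)

    for s in range(acq.n_stimuli):
        fired = np.flatnonzero(rng.random(bouton.n_sites) < bouton.site_pr)
        if fired.size == 0:
            continue
        primary = int(fired[0] if fired.size == 1 else rng.choice(fired))
        site_list = [primary]
        if bouton.n_sites > 1 and rng.random() < mvr_fraction:
            site_list.append(
                _second_site(rng, bouton, primary, spread, peripheral_bias)
            )

        t_s = s / acq.stim_rate_hz
        bleach = math.exp(-t_s / acq.bleach_tau_s)
        pair = f"{bouton.bouton_id}-s{s}" if len(site_list) == 2 else None
        for k, site in enumerate(site_list):
            if bouton.condition == "strontium":
                delay = rng.uniform(0.0, frame)
            elif k == 0:
                delay = 0.0  # time-locked first fusion
            else:
                delay = min(abs(rng.normal(0.0, desync_sd_ms)) if desync_sd_ms > 0 else 0.0,
                            max_delay)
            q = _draw_quantum(rng, acq.photons_per_quantum, quantal_cv) * bleach
            x, y = bouton.site_positions[site]
            if site_jitter_nm > 0:
                x += rng.normal(0.0, site_jitter_nm)
                y += rng.normal(0.0, site_jitter_nm)
            events.append(
                GroundTruthEvent(
                    bouton_id=bouton.bouton_id,
                    stimulus_index=s,
                    site_index=int(site),
                    x_nm=float(x),
                    y_nm=float(y),
                    delay_ms=float(delay),
                    quantal_amplitude=float(q),
                    amplitude=float(q * (frame - delay) / frame),
                    is_mvr_member=pair is not None,
                    pair_id=pair,
                )
            )
    return events


def _integrated_psf(
    shape: tuple[int, int],
    x0: float,
    y0: float,
    sigma: float,
    px: float,
) -> np.ndarray:
    """Unit-mass symmetric Gaussian integrated over the pixel grid."""
    s = sigma * math.sqrt(2.0)
    xe = np.arange(shape[1] + 1) * px
    ye = np.arange(shape[0] + 1) * px
    cx = 0.5 * (erf((xe[1:] - x0) / s) - erf((xe[:-1] - x0) / s))
    cy = 0.5 * (erf((ye[1:] - y0) / s) - erf((ye[:-1] - y0) / s))
    return np.outer(cy, cx)


def render_frame_pair(
    events: Sequence[GroundTruthEvent],
    acq: AcquisitionParams,
    seed: int = 0,
    noise: bool = True,
    center_origin: bool = True,
) -> FramePair:
    """Render one pre/post frame pair for the given co-frame events.

    The post frame adds, per event, a pixel-integrated symmetric Gaussian
    of width ``psf_sigma_nm`` centered at the true position with expected
    total photons ``quantal_amplitude x (frame - delay)/frame``; the pre
    frame contains background only. With ``noise=True`` Poisson photon
    noise and Gaussian read noise are applied to both frames (negative
    read-noise excursions are clipped at zero). ``center_origin`` treats
    event coordinates as bouton-local and shifts them to the field center.
    """
    if acq.fov_nm < 6 * acq.psf_sigma_nm:
        raise ConfigurationError(
            "field of view must span at least 6 x psf_sigma_nm"
        )
    shape = (acq.fov_px, acq.fov_px)
    off = acq.fov_nm / 2.0 if center_origin else 0.0
    post = np.full(shape, acq.background_rate, dtype=float)
    pre = np.full(shape, acq.background_rate, dtype=float)
    frame = acq.frame_duration_ms
    for ev in events:
        x, y = ev.x_nm + off, ev.y_nm + off
        if not (0 <= x < acq.fov_nm and 0 <= y < acq.fov_nm):
            raise ParameterError(
                f"event at ({ev.x_nm}, {ev.y_nm}) nm falls outside the field of view"
            )
        collected = ev.quantal_amplitude * (frame - ev.delay_ms) / frame
        post += collected * _integrated_psf(shape, x, y, acq.psf_sigma_nm,
                                            acq.pixel_size_nm)
    if noise:
        rng = np.random.default_rng(seed)
        pre = rng.poisson(pre).astype(float)
        post = rng.poisson(post).astype(float)
        pre = np.clip(pre + rng.normal(0.0, acq.read_noise_sd, shape), 0, None)
        post = np.clip(post + rng.normal(0.0, acq.read_noise_sd, shape), 0, None)
    bid = events[0].bouton_id if events else ""
    sidx = events[0].stimulus_index if events else 0
    return FramePair(pre=pre, post=post, bouton_id=bid, stimulus_index=sidx)


def simulate_bead_stack(
    n_beads: int,
    n_frames: int,
    acq: AcquisitionParams,
    seed: int = 0,
    noise: bool = True,
    bead_photons: float | None = None,
) -> np.ndarray:
    """Simulate a stack of frames of stationary sub-diffraction beads.

    Beads are fixed point emitters at random positions kept 3 sigma from
    the field edge; the stack serves as the PSF-calibration fixture.
    Calibration beads are much brighter than single fusion events;
    ``bead_photons`` defaults to 10 x ``photons_per_quantum``.
    """
    if n_beads < 1:
        raise ParameterError("n_beads must be >= 1")
    if acq.fov_nm < 6 * acq.psf_sigma_nm:
        raise ConfigurationError("field of view must span at least 6 x psf_sigma_nm")
    rng = np.random.default_rng(seed)
    if bead_photons is None:
        bead_photons = 10.0 * acq.photons_per_quantum
    margin = 3 * acq.psf_sigma_nm
    xs = rng.uniform(margin, acq.fov_nm - margin, n_beads)
    ys = rng.uniform(margin, acq.fov_nm - margin, n_beads)
    shape = (acq.fov_px, acq.fov_px)
    expected = np.full(shape, acq.background_rate, dtype=float)
    for x, y in zip(xs, ys):
        expected += bead_photons * _integrated_psf(
            shape, x, y, acq.psf_sigma_nm, acq.pixel_size_nm
        )
    frames = np.empty((n_frames,) + shape, dtype=float)
    for f in range(n_frames):
        if noise:
            fr = rng.poisson(expected).astype(float)
            fr = np.clip(fr + rng.normal(0.0, acq.read_noise_sd, shape), 0, None)
        else:
            fr = expected.copy()
        frames[f] = fr
    return frames


# ---------------------------------------------------------------------------
# table / file plumbing

_TRUTH_COLUMNS = [
    "bouton_id", "stimulus_index", "site_index", "x_nm", "y_nm",
    "delay_ms", "amplitude", "pair_id",
]


def events_to_table(events: Iterable[GroundTruthEvent]) -> pd.DataFrame:
    rows = [
        {
            "bouton_id": e.bouton_id,
            "stimulus_index": e.stimulus_index,
            "site_index": e.site_index,
            "x_nm": e.x_nm,
            "y_nm": e.y_nm,
            "delay_ms": e.delay_ms,
            "amplitude": e.amplitude,
            "pair_id": e.pair_id if e.pair_id is not None else "",
            "quantal_amplitude": e.quantal_amplitude,
        }
        for e in events
    ]
    cols = _TRUTH_COLUMNS + ["quantal_amplitude"]
    return pd.DataFrame(rows, columns=cols)


def table_to_events(df: pd.DataFrame) -> list[GroundTruthEvent]:
    events = []
    for _, r in df.iterrows():
        pair = r.get("pair_id", "")
        pair = None if (pd.isna(pair) or pair == "") else str(pair)
        q = r.get("quantal_amplitude", np.nan)
        if pd.isna(q):
            q = r["amplitude"]
        events.append(
            GroundTruthEvent(
                bouton_id=str(r["bouton_id"]),
                stimulus_index=int(r["stimulus_index"]),
                site_index=int(r["site_index"]),
                x_nm=float(r["x_nm"]),
                y_nm=float(r["y_nm"]),
                delay_ms=float(r["delay_ms"]),
                quantal_amplitude=float(q),
                amplitude=float(r["amplitude"]),
                is_mvr_member=pair is not None,
                pair_id=pair,
            )
        )
    return events


def write_truth_table(events: Iterable[GroundTruthEvent], path) -> None:
    events_to_table(events).to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> list[GroundTruthEvent]:
    return table_to_events(pd.read_csv(path, sep="\t"))


def write_frame_pairs(pairs: Sequence[FramePair], path) -> None:
    """Write frame pairs as a multi-page 16-bit TIFF, pre/post interleaved."""
    import tifffile

    pages = []
    for p in pairs:
        for frame in (p.pre, p.post):
            pages.append(np.clip(np.round(frame), 0, 65535).astype(np.uint16))
    tifffile.imwrite(path, np.stack(pages))
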
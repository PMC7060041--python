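"""Release-site definition and active-zone spatial analyses.

Release sites are defined by agglomerative (complete-linkage) clustering
of fusion-event localizations within one bouton, cutting the dendrogram at
a 50 nm cluster diameter so that every site's maximal within-cluster
pairwise distance stays below the diameter. The active zone (AZ) is
approximated by the convex hull of all fusion positions, its center by
their arithmetic mean. Per-site release probability (P_r-site) is the
event count divided by the number of stimuli, so values are quantized at
multiples of 1/n_stimuli (0.008, 0.017, ... at 120 stimuli).

Site-level spatial analyses: MVR/UVR overlap classification (site-based
or 25 nm proximity), comparison of an MVR-engaged site's P_r against
other sites equidistant from the AZ center (+-25 nm band), and radial
profiles of site reuse and P_r versus distance to the AZ center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .errors import ParameterError

__all__ = [
    "ReleaseSite",
    "AzGeometry",
    "OverlapClass",
    "BandComparison",
    "RadialProfile",
    "cluster_release_sites",
    "compute_az_geometry",
    "site_release_probability",
    "assign_site_pr",
    "classify_mvr_uvr_overlap",
    "equidistant_band_comparison",
    "radial_profiles",
    "sites_to_table",
    "DEFAULT_CLUSTER_DIAMETER_NM",
    "DEFAULT_PROXIMITY_RADIUS_NM",
    "DEFAULT_BAND_HALFWIDTH_NM",
]

DEFAULT_CLUSTER_DIAMETER_NM = 50.0
DEFAULT_PROXIMITY_RADIUS_NM = 25.0
DEFAULT_BAND_HALFWIDTH_NM = 25.0


@dataclass
class ReleaseSite:
    """A cluster of fusion-event localizations treated as one release site."""

    site_id: str
    bouton_id: str
    centroid: np.ndarray  # (2,) nm
    member_event_ids: list
    n_events: int
    pr_site: float | None = None
    dist_to_center: float | None = None


@dataclass(frozen=True)
class AzGeometry:
    """Convex-hull area and event-mean center of one bouton's AZ."""

    bouton_id: str
    center: np.ndarray  # (2,) nm
    hull_area_um2: float
    n_events: int
    degenerate: bool = False  # fewer than 3 non-collinear events


@dataclass(frozen=True)
class OverlapClass:
    """Full/partial/no overlap of an MVR pair with UVR release sites."""

    pair_id: str
    overlap: str  # {"full", "partial", "none"}
    proximal_site_reused: bool
    distal_site_reused: bool


@dataclass(frozen=True)
class BandComparison:
    """An MVR-engaged site's P_r vs equidistant non-engaged sites."""

    site_id: str
    band_halfwidth: float
    pr_site: float
    mean_pr_equidistant_others: float | None
    ratio: float | None
    undefined: bool = False  # no comparator in the band


@dataclass(frozen=True)
class RadialProfile:
    """Binned site statistics vs distance to the AZ center and vs P_r."""

    distance_bin_edges: np.ndarray
    reuse_fraction: np.ndarray  # per distance bin; NaN where n = 0
    n_per_bin: np.ndarray
    pr_values: np.ndarray  # quantized P_r levels present
    mean_distance_per_pr: np.ndarray
    n_per_pr: np.ndarray


def cluster_release_sites(
    positions: np.ndarray,
    bouton_id: str = "",
    event_ids: Sequence | None = None,
    diameter: float = DEFAULT_CLUSTER_DIAMETER_NM,
) -> list[ReleaseSite]:
    """Cluster one bouton's event positions into release sites.

    Complete-linkage agglomerative clustering cut at ``diameter`` nm, so
    every cluster's maximal pairwise span is <= diameter (boundary
    inclusive). Site labels are ordered by each cluster's smallest member
    event index, making the partition deterministic given input order.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 1:
        raise ParameterError("positions must be a non-empty (n, 2) array")
    ids = list(event_ids) if event_ids is not None else list(range(len(pos)))
    if len(ids) != len(pos):
        raise ParameterError("event_ids must match positions in length")

    if len(pos) == 1:
        labels = np.zeros(1, dtype=int)
    else:
        Z = linkage(pdist(pos), method="complete")
        labels = fcluster(Z, t=diameter, criterion="distance") - 1

    # order clusters by smallest member index
    first_idx = {}
    for i, lab in enumerate(labels):
        first_idx.setdefault(lab, i)
    order = sorted(first_idx, key=lambda lab: first_idx[lab])
    sites = []
    for rank, lab in enumerate(order):
        members = np.flatnonzero(labels == lab)
        sites.append(
            ReleaseSite(
                site_id=f"{bouton_id}:site{rank}" if bouton_id else f"site{rank}",
                bouton_id=bouton_id,
                centroid=pos[members].mean(axis=0),
                member_event_ids=[ids[i] for i in members],
                n_events=int(members.size),
            )
        )
    return sites


def compute_az_geometry(positions: np.ndarray, bouton_id: str = "") -> AzGeometry:
    """Convex-hull area (um^2) and mean-position center of a bouton's events.

    Collinear or too-few-point configurations return area 0 with the
    ``degenerate`` flag set.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2 or len(pos) < 1:
        raise ParameterError("positions must be a non-empty (n, 2) array")
    center = pos.mean(axis=0)
    if len(pos) < 3:
        return AzGeometry(bouton_id, center, 0.0, len(pos), degenerate=True)
    try:
        hull = ConvexHull(pos)
        area_um2 = hull.volume * 1e-6  # nm^2 -> um^2 (2-D hull "volume" is area)
        return AzGeometry(bouton_id, center, float(area_um2), len(pos))
    except QhullError:
        return AzGeometry(bouton_id, center, 0.0, len(pos), degenerate=True)


def site_release_probability(site: ReleaseSite, n_stimuli: int) -> float:
    """P_r-site = events at the site / number of stimuli.

    Each member of a resolved MVR pair counts once at its own site, so MVR
    does not change the per-site accounting.
    """
    if n_stimuli < 1:
        raise ParameterError("n_stimuli must be >= 1")
    return site.n_events / n_stimuli


def assign_site_pr(sites: Iterable[ReleaseSite], n_stimuli: int,
                   az_center: np.ndarray | None = None) -> list[ReleaseSite]:
    """Fill pr_site (and dist_to_center when a center is given) in place."""
    out = []
    for s in sites:
        s.pr_site = site_release_probability(s, n_stimuli)
        if az_center is not None:
            s.dist_to_center = float(np.hypot(*(s.centroid - np.asarray(az_center))))
        out.append(s)
    return out


def classify_mvr_uvr_overlap(
    pair_id: str,
    member_positions: np.ndarray,
    uvr_positions: np.ndarray | None = None,
    member_site_ids: tuple | None = None,
    uvr_site_ids: set | None = None,
    az_center: np.ndarray | None = None,
    mode: str = "proximity_25nm",
    proximity_radius: float = DEFAULT_PROXIMITY_RADIUS_NM,
) -> OverlapClass:
    """Classify an MVR pair's overlap with UVR activity as full/partial/none.

    ``site_based`` mode asks whether each member's release site also hosts
    at least one UVR event (requires ``member_site_ids`` and
    ``uvr_site_ids``); ``proximity_25nm`` mode asks whether any UVR event
    lies within ``proximity_radius`` nm of the member position (boundary
    inclusive). Proximal/distal labels follow distance to ``az_center``
    (member order is used as given when no center is supplied).
    """
    mem = np.asarray(member_positions, dtype=float)
    if mem.shape != (2, 2):
        raise ParameterError("member_positions must be a (2, 2) array")

    if mode == "site_based":
        if member_site_ids is None or uvr_site_ids is None:
            raise ParameterError("site_based mode needs member_site_ids and uvr_site_ids")
        reused = [sid in uvr_site_ids for sid in member_site_ids]
    elif mode == "proximity_25nm":
        if uvr_positions is None:
            raise ParameterError("proximity mode needs uvr_positions")
        uvr = np.asarray(uvr_positions, dtype=float).reshape(-1, 2)
        reused = []
        for m in mem:
            if len(uvr) == 0:
                reused.append(False)
            else:
                d = np.hypot(*(uvr - m).T)
                reused.append(bool(np.min(d) <= proximity_radius))
    else:
        raise ParameterError(f"unknown overlap mode {mode!r}")

    if az_center is not None:
        dists = np.hypot(*(mem - np.asarray(az_center)).T)
        prox_i = int(np.argmin(dists))
    else:
        prox_i = 0
    dist_i = 1 - prox_i
    n_reused = sum(reused)
    overlap = "full" if n_reused == 2 else ("partial" if n_reused == 1 else "none")
    return OverlapClass(
        pair_id=pair_id,
        overlap=overlap,
        proximal_site_reused=bool(reused[prox_i]),
        distal_site_reused=bool(reused[dist_i]),
    )


def equidistant_band_comparison(
    target_site: ReleaseSite,
    all_sites: Sequence[ReleaseSite],
    az_center: np.ndarray,
    band: float = DEFAULT_BAND_HALFWIDTH_NM,
    exclude_site_ids: set | None = None,
) -> BandComparison:
    """Compare a site's P_r against equidistant (+- band nm) comparators.

    Comparators are other sites of the same bouton whose distance to the AZ
    center is within ``band`` nm of the target's, excluding any site in
    ``exclude_site_ids`` (typically the sites engaged in the MVR pair under
    test). With no comparator in the band the result carries the
    ``undefined`` flag.
    """
    center = np.asarray(az_center, dtype=float)
    excl = exclude_site_ids or set()
    excl = excl | {target_site.site_id}

    def dist(s: ReleaseSite) -> float:
        if s.dist_to_center is not None:
            return s.dist_to_center
        return float(np.hypot(*(s.centroid - center)))

    d_t = dist(target_site)
    pr_t = target_site.pr_site
    if pr_t is None:
        raise ParameterError("target site has no pr_site; call assign_site_pr first")
    comp = [
        s.pr_site for s in all_sites
        if s.site_id not in excl and s.bouton_id == target_site.bouton_id
        and s.pr_site is not None and abs(dist(s) - d_t) <= band
    ]
    if not comp:
        return BandComparison(target_site.site_id, band, pr_t, None, None,
                              undefined=True)
    mean_pr = float(np.mean(comp))
    ratio = pr_t / mean_pr if mean_pr > 0 else math.inf
    return BandComparison(target_site.site_id, band, pr_t, mean_pr, ratio)


def radial_profiles(
    sites: Sequence[ReleaseSite],
    az_center: np.ndarray,
    n_stimuli: int,
    distance_bin_nm: float = 50.0,
) -> RadialProfile:
    """Radial reuse profile and P_r-binned mean distances.

    (a) fraction of sites reused at least once (n_events >= 2) per
    distance-to-center bin of width ``distance_bin_nm`` starting at 0;
    (b) mean distance to the AZ center per quantized P_r level
    ({1, 2, ...}/n_stimuli). Empty distance bins report n = 0 and NaN.
    """
    if not sites:
        raise ParameterError("radial_profiles needs at least one site")
    center = np.asarray(az_center, dtype=float)
    d = np.array([
        s.dist_to_center if s.dist_to_center is not None
        else float(np.hypot(*(s.centroid - center)))
        for s in sites
    ])
    counts = np.array([s.n_events for s in sites])
    n_bins = int(math.ceil((d.max() + 1e-9) / distance_bin_nm)) or 1
    edges = np.arange(n_bins + 1) * distance_bin_nm
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    reuse = np.full(n_bins, np.nan)
    n_per = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        n_per[b] = sel.sum()
        if n_per[b]:
            reuse[b] = float(np.mean(counts[sel] >= 2))

    levels = np.unique(counts)
    pr_vals = levels / n_stimuli
    mean_d = np.array([float(d[counts == k].mean()) for k in levels])
    n_pr = np.array([int((counts == k).sum()) for k in levels])
    return RadialProfile(
        distance_bin_edges=edges,
        reuse_fraction=reuse,
        n_per_bin=n_per,
        pr_values=pr_vals,
        mean_distance_per_pr=mean_d,
        n_per_pr=n_pr,
    )


_SITE_COLUMNS = [
    "bouton_id", "site_id", "centroid_x_nm", "centroid_y_nm", "n_events",
    "pr_site", "dist_to_center_nm",
]


def sites_to_table(sites: Iterable[ReleaseSite]) -> pd.DataFrame:
    rows = [
        {
            "bouton_id": s.bouton_id,
            "site_id": s.site_id,
            "centroid_x_nm": float(s.centroid[0]),
            "centroid_y_nm": float(s.centroid[1]),
            "n_events": s.n_events,
            "pr_site": s.pr_site,
            "dist_to_center_nm": s.dist_to_center,
        }
        for s in sites
    ]
    return pd.DataFrame(rows, columns=_SITE_COLUMNS)
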
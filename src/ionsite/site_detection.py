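"""Binding-site detection from ion positions across an ensemble.

Formalizes "spontaneous binding" analysis: after Calpha superposition of
all frames onto the first frame, every ion observation that has at least
one protein donor in its first shell is recorded in the common reference
frame; observations are clustered by single-linkage with a distance
threshold, clusters reaching a minimum frame occupancy become sites, and
pairs of sites sharing their protein fingerprint are reported as sub-sites
of one double site (the pattern of two adjacent pockets flanking a
catalytic center).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .ensemble_metrics import apply_superposition, superpose
from .solvation_shell import (
    DEFAULT_DONOR_ELEMENTS,
    CoordinationRecord,
    CoordinationSummary,
    coordination_sphere,
    default_cutoff,
)
from .structure_io import Ensemble, Structure

__all__ = ["IonSite", "detect_sites", "site_report", "site_records"]


@dataclass
class IonSite:
    """A detected pocket: member observations, centroid and fingerprint."""

    label: str
    observations: list[tuple[int, int]]  # (frame, ion atom index)
    centroid: np.ndarray  # reference-frame coordinates, A
    fingerprint: dict[tuple[str, int, str], float]  # residue -> %t_occ
    species: set[str]
    occupancy: float  # percent of frames with any ion at the site
    double_site: str | None = None  # shared label when part of a double site
    co_occupied_frames: int = 0  # frames where >=2 sub-sites held ions


def _observations(
    e: Ensemble,
    species_filter: set[str] | None,
    donors,
    cutoff_overrides: dict[str, float] | None,
    fit_sel: str,
):
    """Superpose frames and collect bound-ion observations."""
    ref = e.frames[0]
    obs_pos: list[np.ndarray] = []
    obs_meta: list[tuple[int, int, frozenset, str]] = []
    for k, fr in enumerate(e.frames):
        fit = superpose(fr, ref, fit_sel)
        xyz = apply_superposition(fr.coords, fit)
        for i, a in enumerate(fr.atoms):
            if not a.is_ion:
                continue
            if species_filter and a.resname.upper() not in {
                s.upper() for s in species_filter
            }:
                continue
            cutoff = default_cutoff(a.resname, cutoff_overrides)
            rec = coordination_sphere(fr, i, cutoff, donors, frame_index=k)
            if rec.cn_aa >= 1:
                obs_pos.append(xyz[i])
                obs_meta.append((k, i, frozenset(rec.protein_residues), a.resname.upper()))
    return obs_pos, obs_meta


def detect_sites(
    e: Ensemble,
    species_filter: set[str] | None = None,
    eps: float = 2.5,
    min_occupancy: float = 20.0,
    donors=DEFAULT_DONOR_ELEMENTS,
    cutoff_overrides: dict[str, float] | None = None,
    fit_sel: str = "name CA",
) -> list[IonSite]:
    """Cluster bound-ion observations into discrete binding sites.

    Frames are first superposed on ``fit_sel`` (default Calpha) onto frame
    0, removing global rigid motion. Ion observations with >= 1 protein
    donor in the shell are clustered by single linkage at distance ``eps``
    (default 2.5 A, the scale of a couple of metal-oxygen bond lengths);
    clusters occupying at least ``min_occupancy`` percent of frames become
    sites, labeled site1, site2, ... by descending occupancy.  Two sites
    sharing >= 2 fingerprint residues at >= 50 %t_occ are flagged as
    sub-sites of one double site (labels gain a/b/... suffixes).
    """
    n_frames = len(e)
    obs_pos, obs_meta = _observations(e, species_filter, donors, cutoff_overrides, fit_sel)
    if not obs_pos:
        return []
    pos = np.asarray(obs_pos)
    if len(pos) == 1:
        cluster_ids = np.array([1])
    else:
        z = linkage(pos, method="single")
        cluster_ids = fcluster(z, t=eps, criterion="distance")

    sites: list[IonSite] = []
    for cid in sorted(set(cluster_ids)):
        members = np.flatnonzero(cluster_ids == cid)
        frames_hit = {obs_meta[m][0] for m in members}
        occupancy = 100.0 * len(frames_hit) / n_frames
        if occupancy < min_occupancy:
            continue
        res_frames: dict[tuple[str, int, str], set[int]] = {}
        species: set[str] = set()
        for m in members:
            frame_k, _, residues, resname = obs_meta[m]
            species.add(resname)
            for rk in residues:
                res_frames.setdefault(rk, set()).add(frame_k)
        fingerprint = {
            rk: 100.0 * len(fs) / n_frames for rk, fs in sorted(res_frames.items())
        }
        sites.append(
            IonSite(
                label="",
                observations=[(obs_meta[m][0], obs_meta[m][1]) for m in members],
                centroid=pos[members].mean(axis=0),
                fingerprint=fingerprint,
                species=species,
                occupancy=occupancy,
            )
        )

    sites.sort(key=lambda s: (-s.occupancy, s.centroid[0]))
    _label_sites(sites, n_frames)
    return sites


def _label_sites(sites: list[IonSite], n_frames: int) -> None:
    """Assign rank labels; merge fingerprint-sharing sites into double sites.

    The sharing relation is evaluated symmetrically and closed transitively
    (connected components), so chained pockets merge into one group.
    """
    n = len(sites)
    adj = [set() for _ in range(n)]
    for i in range(n):
        fi = {rk for rk, p in sites[i].fingerprint.items() if p >= 50.0}
        for j in range(i + 1, n):
            fj = {rk for rk, p in sites[j].fingerprint.items() if p >= 50.0}
            if len(fi & fj) >= 2:
                adj[i].add(j)
                adj[j].add(i)
    seen: set[int] = set()
    components: list[list[int]] = []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.append(k)
            stack.extend(adj[k] - seen)
        components.append(sorted(comp))
    rank = 1
    for comp in components:
        if len(comp) == 1:
            sites[comp[0]].label = f"site{rank}"
        else:
            group = f"site{rank}"
            frames_per = [
                {f for f, _ in sites[k].observations} for k in comp
            ]
            co = set.intersection(*frames_per) if len(frames_per) > 1 else set()
            for sub, k in enumerate(comp):
                sites[k].label = f"{group}{chr(ord('a') + sub)}"
                sites[k].double_site = group
                sites[k].co_occupied_frames = len(co)
        rank += 1


def site_records(
    e: Ensemble,
    site: IonSite,
    donors=DEFAULT_DONOR_ELEMENTS,
    cutoff_overrides: dict[str, float] | None = None,
) -> list[CoordinationRecord]:
    """Per-frame coordination records for a site's member observations.

    Frames where the site is unoccupied contribute an empty record, so
    downstream %t_occ statistics stay normalized over the full window.
    """
    by_frame = {f: i for f, i in site.observations}
    out: list[CoordinationRecord] = []
    for k, fr in enumerate(e.frames):
        if k in by_frame:
            i = by_frame[k]
            cutoff = default_cutoff(fr.atoms[i].resname, cutoff_overrides)
            out.append(coordination_sphere(fr, i, cutoff, donors, frame_index=k))
        else:
            any_ion = by_frame[next(iter(by_frame))]
            out.append(CoordinationRecord(k, any_ion, 0.0, tuple()))
    return out


def site_report(
    sites: list[IonSite],
    summaries: dict[str, CoordinationSummary],
) -> pd.DataFrame:
    """Merged per-site table: species, residue %t_occ and CN split.

    Rows are ordered by site label, then %t_occ descending, then resid.
    Raises when the summary keys do not match the site labels.
    """
    labels = {s.label for s in sites}
    if labels != set(summaries):
        missing = labels ^ set(summaries)
        raise KeyError(f"site/summary key mismatch: {sorted(missing)}")
    rows = []
    for site in sites:
        summ = summaries[site.label]
        if not site.fingerprint:
            continue
        ordered = sorted(site.fingerprint.items(), key=lambda kv: (-kv[1], kv[0][1]))
        for rk, pct in ordered:
            rows.append(
                {
                    "site": site.label,
                    "species": "/".join(sorted(site.species)),
                    "chain": rk[0],
                    "resid": rk[1],
                    "resname": rk[2],
                    "pct_t_occ": round(pct, 1),
                    "cn_aa": round(summ.cn_aa, 1),
                    "cn_water": round(summ.cn_water, 1),
                    "cn_total": round(summ.cn_total, 1),
                    "site_occupancy_pct": round(site.occupancy, 1),
                }
            )
    columns = [
        "site",
        "species",
        "chain",
        "resid",
        "resname",
        "pct_t_occ",
        "cn_aa",
        "cn_water",
        "cn_total",
        "site_occupancy_pct",
    ]
    return pd.DataFrame(rows, columns=columns)
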
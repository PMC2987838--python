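"""Superposition and flexibility metrics for structure ensembles.

Least-squares (Kabsch) rigid-body superposition, per-frame RMSD series
against a reference structure, and per-residue root-mean-square
fluctuations (RMSF) about the iteratively fitted ensemble mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Ensemble, Selection, Structure

__all__ = [
    "SuperpositionResult",
    "RMSDSeries",
    "FlexibilityProfile",
    "kabsch_rotation",
    "superpose",
    "apply_superposition",
    "rmsd_series",
    "rmsf",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform mapping mobile onto reference: x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclass(frozen=True)
class RMSDSeries:
    values: np.ndarray  # per-frame RMSD, A
    mean: float
    sd: float
    window: tuple[int, int]  # [start, stop) frame range used for mean/sd


@dataclass(frozen=True)
class FlexibilityProfile:
    """Per-residue RMSF (A) over an ensemble, after fitting to the mean."""

    residue_keys: list[tuple[str, int, str]]
    rmsf: np.ndarray
    selection: str
    per_atom_rmsf: np.ndarray = field(repr=False, default=None)

    def range_stats(self, resid_lo: int, resid_hi: int) -> tuple[float, float]:
        """Mean and sd of RMSF over residues with resid in [lo, hi]."""
        vals = [
            v
            for (_, rid, _), v in zip(self.residue_keys, self.rmsf)
            if resid_lo <= rid <= resid_hi
        ]
        if not vals:
            raise ValueError(f"no residues in range {resid_lo}-{resid_hi}")
        arr = np.asarray(vals)
        return float(arr.mean()), float(arr.std())


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R minimizing ||R x_i - y_i|| for centered sets."""
    h = mobile.T @ reference  # 3x3 cross-covariance
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def superpose(
    mobile: Structure,
    reference: Structure,
    sel: Selection | str = "name CA",
) -> SuperpositionResult:
    """Least-squares fit of ``mobile`` onto ``reference`` over a selection.

    Reflections are excluded (det(R) = +1). Raises if the selection resolves
    to fewer than 3 atoms or to different lengths on the two structures.
    """
    im = mobile.select(sel)
    ir = reference.select(sel)
    if len(im) != len(ir):
        raise ValueError(
            f"selection resolves to {len(im)} atoms on mobile but {len(ir)} on reference"
        )
    if len(im) < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    x = mobile.coords[im]
    y = reference.coords[ir]
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    r = kabsch_rotation(x - xc, y - yc)
    t = yc - r @ xc
    fitted = (x - xc) @ r.T + yc
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=r, translation=t, rmsd=rmsd)


def apply_superposition(coords: np.ndarray, fit: SuperpositionResult) -> np.ndarray:
    return coords @ fit.rotation.T + fit.translation


def rmsd_series(
    e: Ensemble,
    reference: Structure,
    sel: Selection | str = "name CA",
    fit: bool = True,
    window: tuple[int, int] | None = None,
) -> RMSDSeries:
    """Per-frame RMSD to a reference over a selection, with window statistics.

    With ``fit`` each frame is superposed on the reference before measuring.
    ``window`` is a [start, stop) frame range for the mean/sd; the default is
    the final 80% of frames (the equilibrated tail of a trajectory).
    """
    ir = reference.select(sel)
    y = reference.coords[ir]
    vals = np.empty(len(e))
    for k, fr in enumerate(e.frames):
        ix = fr.select(sel)
        if len(ix) != len(ir):
            raise ValueError(f"frame {k}: selection length mismatch with reference")
        x = fr.coords[ix]
        if fit:
            res = superpose(fr, reference, sel)
            vals[k] = res.rmsd
        else:
            vals[k] = float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))
    if window is None:
        window = (len(e) - max(1, int(round(0.8 * len(e)))), len(e))
    lo, hi = window
    sub = vals[lo:hi]
    if sub.size == 0:
        raise ValueError(f"empty analysis window {window}")
    return RMSDSeries(values=vals, mean=float(sub.mean()), sd=float(sub.std()), window=(lo, hi))


def _fitted_frames(e: Ensemble, fit_sel: Selection | str, n_iter: int = 2) -> np.ndarray:
    """Fit all frames on ``fit_sel`` to the iteratively refined ensemble mean."""
    idx = e.frames[0].select(fit_sel)
    if len(idx) < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    all_xyz = e.coords  # (F, N, 3)
    fit_xyz = all_xyz[:, idx, :]
    ref = fit_xyz[0]
    out = all_xyz.copy()
    for _ in range(n_iter):
        for k in range(len(e)):
            x = out[k, idx, :]
            xc, rc = x.mean(axis=0), ref.mean(axis=0)
            r = kabsch_rotation(x - xc, ref - rc)
            out[k] = (out[k] - xc) @ r.T + rc
        ref = out[:, idx, :].mean(axis=0)
    return out


def rmsf(
    e: Ensemble,
    sel: Selection | str = "name CA",
    fit_sel: Selection | str | None = None,
) -> FlexibilityProfile:
    """Per-residue RMSF about the ensemble mean structure.

    Frames are superposed on ``fit_sel`` (default: same as ``sel``) to the
    mean structure, refined over two fit-then-average passes; then
    RMSF_i = sqrt(<|x_i - <x_i>|^2>) per selected atom, averaged per residue.
    Undefined for single-frame ensembles.
    """
    if len(e) < 2:
        raise ValueError("RMSF is undefined for a single-frame ensemble")
    fit_sel = fit_sel if fit_sel is not None else sel
    fitted = _fitted_frames(e, fit_sel)
    idx = e.frames[0].select(sel)
    xyz = fitted[:, idx, :]
    mean = xyz.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((xyz - mean) ** 2, axis=2), axis=0))
    keys: list[tuple[str, int, str]] = []
    per_res: list[float] = []
    acc: dict[tuple[str, int, str], list[float]] = {}
    order: list[tuple[str, int, str]] = []
    for local, atom_i in enumerate(idx):
        key = e.frames[0].atoms[atom_i].residue_key
        if key not in acc:
            acc[key] = []
            order.append(key)
        acc[key].append(per_atom[local])
    for key in order:
        keys.append(key)
        per_res.append(float(np.mean(acc[key])))
    sel_str = sel.expression if isinstance(sel, Selection) else str(sel)
    return FlexibilityProfile(
        residue_keys=keys,
        rmsf=np.asarray(per_res),
        selection=sel_str,
        per_atom_rmsf=per_atom,
    )
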
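"""Model-evaluation metrics: energy/force/barrier MAEs and analyses.

Conventions (each the common one for meV-scale reporting, switchable
where noted):

* Energy MAE — mean |ΔE| over configurations, in meV; the per-atom
  variant divides each error by that configuration's atom count first.
* Force MAE — mean absolute deviation pooled over all 3N Cartesian
  components of all configurations, in meV/Å.  A per-atom vector-norm
  variant is available via ``norm_based=True``.
* Barrier MAE — barriers are recomputed from the predicted and reference
  energy profiles of each interpolation path; left and right barriers are
  pooled equally.  Because a barrier is a difference along one path, any
  constant per-path energy offset cancels exactly — the mechanism that
  makes indirect barrier predictions more accurate than raw energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hat_systems import BarrierResult, compute_barriers


@dataclass
class PredictionSet:
    """Per-configuration predicted energies (eV) and forces (eV/Å)."""

    energies: dict
    forces: dict = field(default_factory=dict)
    provenance: str = ""

    def ids(self):
        return set(self.energies)


@dataclass
class ErrorReport:
    energy_mae: float = 0.0          # meV
    per_atom_energy_mae: float = 0.0  # meV/atom
    force_mae: float = 0.0           # meV/Å
    barrier_mae: float = 0.0         # meV
    n_configurations: int = 0
    n_barriers: int = 0
    empty: bool = False


def _check_ids(pred_ids, ref_ids):
    missing = sorted(set(ref_ids) - set(pred_ids))
    if missing:
        raise KeyError(f"predictions missing for ids: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))


def energy_mae(
    pred: PredictionSet,
    ref: PredictionSet,
    atom_counts: dict | None = None,
    per_atom: bool = False,
) -> float:
    """Mean absolute total-energy error in meV (meV/atom if ``per_atom``)."""
    _check_ids(pred.energies, ref.energies)
    ids = sorted(ref.energies)
    if not ids:
        raise ValueError("empty reference set")
    errs = np.array([abs(pred.energies[i] - ref.energies[i]) for i in ids])
    if per_atom:
        if atom_counts is None:
            raise ValueError("per_atom energy MAE needs atom counts")
        errs = errs / np.array([atom_counts[i] for i in ids], dtype=float)
    return float(errs.mean() * 1000.0)


def force_mae(pred: PredictionSet, ref: PredictionSet, norm_based: bool = False) -> float:
    """Mean absolute force error in meV/Å, pooled over Cartesian components
    (or over per-atom vector norms with ``norm_based=True``)."""
    _check_ids(pred.forces, ref.forces)
    if not ref.forces:
        raise ValueError("empty reference force set")
    pooled = []
    for i in sorted(ref.forces):
        fp = np.asarray(pred.forces[i], dtype=float)
        fr = np.asarray(ref.forces[i], dtype=float)
        if fp.shape != fr.shape:
            raise ValueError(f"force shape mismatch for id {i!r}")
        diff = fp - fr
        if norm_based:
            pooled.append(np.linalg.norm(diff.reshape(-1, 3), axis=1))
        else:
            pooled.append(np.abs(diff).ravel())
    return float(np.concatenate(pooled).mean() * 1000.0)


def barrier_mae(pred_paths: dict, ref_paths: dict) -> float:
    """MAE over pooled {ΔE_left, ΔE_right} of all paths, in meV.

    ``pred_paths``/``ref_paths`` map path id → ordered per-image energies.
    """
    _check_ids(pred_paths, ref_paths)
    errs = []
    for pid in sorted(ref_paths):
        ep = np.asarray(pred_paths[pid], dtype=float)
        er = np.asarray(ref_paths[pid], dtype=float)
        if ep.shape != er.shape:
            raise ValueError(f"image count mismatch on path {pid!r}")
        bp = compute_barriers(ep)
        br = compute_barriers(er)
        errs.append(abs(bp.delta_e_left - br.delta_e_left))
        errs.append(abs(bp.delta_e_right - br.delta_e_right))
    if not errs:
        raise ValueError("no paths")
    return float(np.mean(errs) * 1000.0)


# ---------------------------------------------------------------------------
# Transferability
# ---------------------------------------------------------------------------

def _subset_report(pred, ref, atom_counts, ids) -> ErrorReport:
    if not ids:
        return ErrorReport(empty=True)
    sub_pred = PredictionSet(
        {i: pred.energies[i] for i in ids},
        {i: pred.forces[i] for i in ids if i in pred.forces},
    )
    sub_ref = PredictionSet(
        {i: ref.energies[i] for i in ids},
        {i: ref.forces[i] for i in ids if i in ref.forces},
    )
    rep = ErrorReport(n_configurations=len(ids))
    rep.energy_mae = energy_mae(sub_pred, sub_ref)
    rep.per_atom_energy_mae = energy_mae(sub_pred, sub_ref, atom_counts, per_atom=True)
    if sub_ref.forces:
        rep.force_mae = force_mae(sub_pred, sub_ref)
    return rep


def size_binned_errors(
    pred: PredictionSet,
    ref: PredictionSet,
    atom_counts: dict,
    atom_threshold: int = 50,
    bin_width: int = 10,
) -> tuple[dict, ErrorReport, ErrorReport]:
    """Partition configurations by atom count.

    Returns (bins, small_report, large_report): half-open bins
    [lo, lo+width) keyed by lo, plus the small/large pair where small
    means ≤ ``atom_threshold`` atoms (a 50-atom system counts as small).
    """
    _check_ids(pred.energies, ref.energies)
    ids = sorted(ref.energies)
    bins: dict = {}
    for i in ids:
        lo = (atom_counts[i] // bin_width) * bin_width
        bins.setdefault(lo, []).append(i)
    bin_reports = {
        lo: _subset_report(pred, ref, atom_counts, members)
        for lo, members in sorted(bins.items())
    }
    small = [i for i in ids if atom_counts[i] <= atom_threshold]
    large = [i for i in ids if atom_counts[i] > atom_threshold]
    return (
        bin_reports,
        _subset_report(pred, ref, atom_counts, small),
        _subset_report(pred, ref, atom_counts, large),
    )


# ---------------------------------------------------------------------------
# Learning-curve fit
# ---------------------------------------------------------------------------

def fit_power_law(dataset_sizes, maes) -> tuple[float, float, float]:
    """Least-squares power-law fit MAE ≈ a · N^(−b) on log–log axes.

    Returns (amplitude a, exponent b, RMS residual in log space); b > 0
    for curves that improve with more data.  Requires ≥ 3 strictly
    positive (N, MAE) pairs.
    """
    n = np.asarray(dataset_sizes, dtype=float)
    y = np.asarray(maes, dtype=float)
    if n.size < 3:
        raise ValueError("need at least three points for a power-law fit")
    if np.any(n <= 0) or np.any(y <= 0):
        raise ValueError("sizes and MAEs must be strictly positive")
    slope, intercept = np.polyfit(np.log(n), np.log(y), 1)
    resid = np.log(y) - (slope * np.log(n) + intercept)
    return float(np.exp(intercept)), float(-slope), float(np.sqrt(np.mean(resid**2)))


# ---------------------------------------------------------------------------
# Parent / child comparison
# ---------------------------------------------------------------------------

@dataclass
class ParentChildReport:
    deviations: np.ndarray     # child − parent, pooled over both sides
    median_shift: float        # eV
    mean_abs_deviation: float  # eV
    n_pairs: int
    fraction_within_0p1: float


def parent_child_report(pairs: list) -> ParentChildReport:
    """Compare barrier results of matched (parent, child) system pairs.

    Each pair is (parent :class:`BarrierResult`, child
    :class:`BarrierResult`); deviations are child − parent per side.
    """
    if not pairs:
        raise ValueError("no parent/child pairs")
    devs = []
    for parent, child in pairs:
        devs.append(child.delta_e_left - parent.delta_e_left)
        devs.append(child.delta_e_right - parent.delta_e_right)
    devs = np.array(devs)
    return ParentChildReport(
        devs,
        float(np.median(devs)),
        float(np.abs(devs).mean()),
        len(pairs),
        float(np.mean(np.abs(devs) <= 0.1)),
    )


# ---------------------------------------------------------------------------
# Offset-outlier flagging
# ---------------------------------------------------------------------------

def flag_offset_outliers(
    pred_paths: dict,
    ref_paths: dict,
    rel_std_max: float = 0.2,
    min_offset: float = 0.1,
) -> list:
    """Flag paths whose error is a near-constant energy offset.

    A path is an offset outlier when the standard deviation of
    (pred − ref) along it is below ``rel_std_max`` times its mean absolute
    offset and that offset exceeds ``min_offset`` eV — systems where the
    model misplaces the absolute energy reference but keeps the profile
    shape.  Both thresholds are configuration.
    """
    out = []
    for pid in sorted(ref_paths):
        diff = np.asarray(pred_paths[pid], float) - np.asarray(ref_paths[pid], float)
        mean_abs = np.abs(diff.mean())
        if mean_abs > min_offset and diff.std() < rel_std_max * mean_abs:
            out.append(pid)
    return out


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------

def predictions_from_extxyz(path, id_key: str = "system_id") -> PredictionSet:
    """Read a prediction set from extended-XYZ (energy key + forces block).

    The configuration id is ``info[id_key]``, suffixed with the image
    index when present, matching how datasets are written.
    """
    from . import io as hio

    energies, forces = {}, {}
    for frame in hio.read_extxyz(path):
        cid = str(frame.info.get(id_key, ""))
        if "image_index" in frame.info:
            cid = f"{cid}#{frame.info['image_index']}"
        energies[cid] = float(frame.info["energy"])
        if frame.forces is not None:
            forces[cid] = frame.forces
    return PredictionSet(energies, forces, provenance=str(path))


def predictions_from_csv(path) -> PredictionSet:
    """Read predictions from CSV with columns id, energy[, fx0, fy0, fz0, ...]."""
    import pandas as pd

    df = pd.read_csv(path)
    energies = dict(zip(df["id"].astype(str), df["energy"].astype(float)))
    force_cols = [c for c in df.columns if c not in ("id", "energy")]
    forces = {}
    if force_cols:
        for _, row in df.iterrows():
            vals = row[force_cols].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            forces[str(row["id"])] = vals.reshape(-1, 3)
    return PredictionSet(energies, forces, provenance=str(path))
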
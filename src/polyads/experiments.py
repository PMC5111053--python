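"""Replica management, parameter sweeps and result files.

A *point* is one physical condition (N, E_PP, E_PS, boundary mode).  It is
simulated with a configurable number of independent replicas, each with its
own recorded seed; per-replica MSD and end-to-end ACF curves are pooled into
ensemble curves from which D_xy and tau_R are fitted, with uncertainties
from a bootstrap over replicas.  A *sweep* runs a grid of points and fits
the scaling exponents alpha (D_xy ~ N^-alpha) and beta (tau_R ~ N^beta).

Budgets default to desk scale (tens of replicas, trajectories spanning a
couple of dozen rotational relaxation times); the reference ensemble size
for this model in the literature is 5000 replicas, selectable via
``paper_scale=True`` (or ``--paper-scale`` on the command line) at
correspondingly long run times.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lattice_model import (BULK3D, MODES, PLANE2D, SLAB, BoxSpec,
                            EnergyParams, default_box)
from .mc_engine import (AdsorptionError, RunProtocol, Simulation,
                        equilibrate_and_adsorb, initial_chain)
from .observables import (AcfCurve, MsdCurve, TrajectoryRecord, average_acf,
                          average_msd, end_to_end_acf, estimate_Dxy,
                          estimate_tau_R, fit_scaling_exponent, msd_com,
                          record_trajectory)

__all__ = ["PointSummary", "SweepConfig", "run_point", "run_sweep",
           "run_replica", "default_production_mcs", "write_xyz",
           "PAPER_REPLICAS"]

PAPER_REPLICAS = 5000

# rough per-mode rotational-relaxation scales (tau_R ~ coef * N^exp in MCS),
# measured once on this implementation at E_PP = 0 and used only to size
# default run budgets (~40 tau_R of production per replica)
_TAU_SCALE = {BULK3D: (0.75, 2.31), SLAB: (1.0, 2.7), PLANE2D: (1.4, 2.82)}
_SPAN_FACTOR = 40.0


def estimated_tau_r(n: int, mode: str = BULK3D, e_pp: float = 0.0) -> float:
    """Order-of-magnitude rotational relaxation time used for budgeting."""
    coef, expo = _TAU_SCALE[mode]
    return coef * (1.0 + 2.0 * e_pp) * n ** expo


def default_production_mcs(n: int, mode: str = BULK3D, e_pp: float = 0.0) -> int:
    """Production length covering ~40 estimated tau_R (longer when E_PP > 0
    slows the internal dynamics)."""
    return int(max(500, math.ceil(_SPAN_FACTOR * estimated_tau_r(n, mode, e_pp))))


@dataclass
class PointSummary:
    """Aggregated observables for one (N, E_PP, E_PS, mode) condition."""

    n: int
    e_pp: float
    e_ps: float
    mode: str
    replicas: int
    production_mcs: int
    sample_interval: int
    seed: int
    d_xy: Optional[float] = None
    d_xy_err: Optional[float] = None
    tau_r: Optional[float] = None
    tau_r_err: Optional[float] = None
    rg_sq_mean: Optional[float] = None
    rg_sq_err: Optional[float] = None
    r_sq_mean: Optional[float] = None
    r_sq_err: Optional[float] = None
    n_ps_mean: Optional[float] = None
    desorbed_fraction: Optional[float] = None
    acceptance_rate: Optional[float] = None
    n_failed: int = 0
    notes: str = ""
    msd: Optional[MsdCurve] = None
    acf: Optional[AcfCurve] = None

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)
             if f.name not in ("msd", "acf")}
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "PointSummary":
        return cls(**d)

    def write_curves(self, stem: str | Path) -> None:
        """CSV curve files ``<stem>_msd.csv`` and ``<stem>_acf.csv``."""
        stem = Path(stem)
        if self.msd is not None:
            pd.DataFrame({"lag_mcs": self.msd.lags, "msd": self.msd.values,
                          "origins": self.msd.origin_counts}
                         ).to_csv(stem.with_name(stem.name + "_msd.csv"),
                                  index=False)
        if self.acf is not None:
            pd.DataFrame({"lag_mcs": self.acf.lags, "rho": self.acf.rho,
                          "origins": self.acf.origin_counts}
                         ).to_csv(stem.with_name(stem.name + "_acf.csv"),
                                  index=False)


def _replica_seeds(seed: int, replicas: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(replicas, dtype=np.uint64)]


def run_replica(n: int, params: EnergyParams, mode: str, box: BoxSpec,
                protocol: RunProtocol, seed: int) -> tuple[TrajectoryRecord, Simulation]:
    """One independent run: build, equilibrate (and adsorb in the slab),
    then record a production trajectory."""
    state = initial_chain(n, box)
    if mode == SLAB:
        sim = equilibrate_and_adsorb(state, protocol, params, rng=seed)
    else:
        sim = Simulation(state, params, seed)
        sim.run(protocol.equilibration_mcs)
    traj = record_trajectory(sim, protocol.production_mcs,
                             protocol.sample_interval)
    return traj, sim


def run_point(n: int, e_pp: float = 0.0, e_ps: float = 0.0,
              mode: str = BULK3D, replicas: int = 100,
              production_mcs: Optional[int] = None,
              sample_interval: Optional[int] = None,
              equilibration_mcs: Optional[int] = None,
              seed: int = 0, box: Optional[BoxSpec] = None,
              n_boot: int = 200, paper_scale: bool = False) -> PointSummary:
    """Simulate one condition over independent replicas and aggregate.

    Per-replica MSD/ACF curves (already multi-origin time averages) are
    pooled into ensemble curves; D_xy and tau_R are fitted on the pooled
    curves and their uncertainties estimated by bootstrap over replicas.
    Scalar observables (R_G^2, R^2, n_PS) are time averages per replica,
    then averaged with a standard error over replicas.  Replicas failing
    with an engine error are skipped; the point fails only if a majority do.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if paper_scale:
        replicas = max(replicas, PAPER_REPLICAS)
    box = box or default_box(n, mode)
    params = EnergyParams(e_pp, e_ps if mode == SLAB else 0.0)
    if production_mcs is None:
        production_mcs = default_production_mcs(n, mode, e_pp)
    if sample_interval is None:
        sample_interval = max(1, production_mcs // 4096)
    production_mcs = (production_mcs // sample_interval) * sample_interval
    if equilibration_mcs is None:
        # at least the nominal N^2.2 relaxation, but in practice several
        # actual relaxation times: tie it to the production span
        equilibration_mcs = max(int(math.ceil(n ** 2.2)), production_mcs // 6)
    protocol = RunProtocol.for_chain(n, production_mcs, sample_interval,
                                     equilibration_mcs=equilibration_mcs,
                                     settle_mcs=equilibration_mcs)

    msds, acfs = [], []
    rg_means, r_sq_means, nps_means, desorbed, acc = [], [], [], [], []
    n_failed = 0
    notes = []
    for rep_seed in _replica_seeds(seed, replicas):
        try:
            traj, sim = run_replica(n, params, mode, box, protocol, rep_seed)
        except AdsorptionError as exc:
            n_failed += 1
            notes.append(str(exc))
            continue
        msds.append(msd_com(traj, component="xy"))
        if n > 1:
            acfs.append(end_to_end_acf(traj))
            r_sq_means.append(float(np.mean(np.sum(traj.end_to_end ** 2, axis=1))))
        rg_means.append(float(np.mean(traj.rg_sq)))
        nps_means.append(float(np.mean(traj.n_ps)))
        desorbed.append(traj.desorbed_fraction)
        acc.append(sim.acceptance_rate)
    if len(msds) <= replicas // 2:
        raise RuntimeError(
            f"majority of replicas failed ({n_failed}/{replicas}): "
            + "; ".join(notes[:3]))

    summary = PointSummary(
        n=n, e_pp=e_pp, e_ps=params.e_ps, mode=mode, replicas=len(msds),
        production_mcs=production_mcs, sample_interval=sample_interval,
        seed=seed, n_failed=n_failed, notes="; ".join(notes[:3]))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))

    summary.msd = average_msd(msds)
    try:
        summary.d_xy = estimate_Dxy(summary.msd).d_xy
        summary.d_xy_err = _bootstrap_fit(
            msds, average_msd, lambda c: estimate_Dxy(c).d_xy, rng, n_boot)
    except ValueError as exc:
        notes.append(f"D fit failed: {exc}")
        summary.notes = "; ".join(notes[:4])
    if acfs:
        summary.acf = average_acf(acfs)
        try:
            summary.tau_r = estimate_tau_R(summary.acf).tau_r
            summary.tau_r_err = _bootstrap_fit(
                acfs, average_acf, lambda c: estimate_tau_R(c).tau_r, rng, n_boot)
        except ValueError as exc:
            notes.append(f"tau fit failed: {exc}")
            summary.notes = "; ".join(notes[:4])

    def mean_err(vals):
        v = np.asarray(vals, dtype=float)
        err = float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0
        return float(v.mean()), err

    summary.rg_sq_mean, summary.rg_sq_err = mean_err(rg_means)
    if r_sq_means:
        summary.r_sq_mean, summary.r_sq_err = mean_err(r_sq_means)
    summary.n_ps_mean, _ = mean_err(nps_means)
    summary.desorbed_fraction, _ = mean_err(desorbed)
    summary.acceptance_rate, _ = mean_err(acc)
    return summary


def _bootstrap_fit(curves, average, fit, rng, n_boot: int) -> float:
    """Std dev of a curve-fit statistic under bootstrap over replicas."""
    if n_boot < 2 or len(curves) < 2:
        return float("nan")
    vals = []
    m = len(curves)
    for _ in range(n_boot):
        idx = rng.integers(m, size=m)
        try:
            vals.append(fit(average([curves[i] for i in idx])))
        except ValueError:
            continue
    if len(vals) < 2:
        return float("nan")
    return float(np.std(vals, ddof=1))


@dataclass
class SweepConfig:
    """Grid of conditions plus run budgets; flat and JSON-serializable.

    ``production_mcs`` of None sizes each point automatically from the
    expected relaxation time of its chain length and mode.
    """

    n_values: Sequence[int] = (8, 16, 32, 64)
    e_pp_values: Sequence[float] = (0.0,)
    e_ps_values: Sequence[float] = (1.0,)
    mode: str = SLAB
    replicas: int = 100
    production_mcs: Optional[int] = None
    sample_interval: Optional[int] = None
    seed: int = 0
    out_dir: Optional[str] = None
    paper_scale: bool = False

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode != SLAB:
            # surface strength is meaningless off the slab; normalize so
            # that manifests and tables carry a single canonical value
            self.e_ps_values = (0.0,)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("n_values", "e_pp_values", "e_ps_values"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "SweepConfig":
        return cls(**json.loads(Path(path).read_text()))


def _point_key(cfg: SweepConfig, n: int, e_pp: float, e_ps: float) -> str:
    return f"{cfg.mode}_N{n}_epp{e_pp:g}_eps{e_ps:g}"


def _point_hash(cfg: SweepConfig, n: int, e_pp: float, e_ps: float) -> str:
    payload = json.dumps([cfg.to_dict(), n, e_pp, e_ps], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_sweep(cfg: SweepConfig, min_n_for_fit: Optional[int] = None
              ) -> pd.DataFrame:
    """Run the full grid and fit alpha and beta per (mode, E_PP, E_PS).

    Returns the exponent table; per-point summaries, curves and a resumable
    manifest are written under ``cfg.out_dir`` when it is set (a completed
    point found in the manifest with a matching configuration hash is loaded
    instead of re-run, so interrupted sweeps resume deterministically).
    """
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    manifest_path = out_dir / "manifest.json" if out_dir else None
    manifest: dict = {}
    if manifest_path and manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for e_pp in cfg.e_pp_values:
        for e_ps in cfg.e_ps_values:
            points: list[PointSummary] = []
            for n in cfg.n_values:
                key = _point_key(cfg, n, e_pp, e_ps)
                h = _point_hash(cfg, n, e_pp, e_ps)
                entry = manifest.get(key)
                if entry and entry.get("hash") == h and entry.get("status") == "done":
                    points.append(PointSummary.from_dict(
                        json.loads((out_dir / entry["summary"]).read_text())))
                    continue
                point_seed = int(np.random.SeedSequence(
                    [cfg.seed, n, int(e_pp * 1000), int(e_ps * 1000)]
                ).generate_state(1)[0]) % (2 ** 31)
                try:
                    summary = run_point(
                        n, e_pp=e_pp, e_ps=e_ps, mode=cfg.mode,
                        replicas=cfg.replicas,
                        production_mcs=cfg.production_mcs,
                        sample_interval=cfg.sample_interval,
                        seed=point_seed, paper_scale=cfg.paper_scale)
                except RuntimeError as exc:
                    manifest[key] = {"hash": h, "status": f"failed: {exc}"}
                    continue
                points.append(summary)
                if out_dir:
                    summary.to_json(out_dir / f"{key}.json")
                    summary.write_curves(out_dir / key)
                    manifest[key] = {"hash": h, "status": "done",
                                     "seed": point_seed,
                                     "summary": f"{key}.json"}
                    manifest_path.write_text(json.dumps(manifest, indent=1))
            row = {"mode": cfg.mode, "e_pp": e_pp, "e_ps": e_ps,
                   "n_points": len(points)}
            row.update(_fit_exponents(points, min_n_for_fit))
            rows.append(row)
    table = pd.DataFrame(rows)
    if out_dir and len(table):
        table.to_csv(out_dir / "exponents.csv", index=False)
        table.to_json(out_dir / "exponents.json", orient="records", indent=1)
    return table


def _fit_exponents(points: Sequence[PointSummary],
                   min_n: Optional[int]) -> dict:
    out = {"alpha": None, "alpha_err": None, "beta": None, "beta_err": None,
           "n_range": None}
    pts = [p for p in points if min_n is None or p.n >= min_n]
    d_pts = [(p.n, p.d_xy) for p in pts if p.d_xy]
    t_pts = [(p.n, p.tau_r) for p in pts if p.tau_r]
    if len(d_pts) >= 3:
        fit = fit_scaling_exponent(*zip(*d_pts))
        out["alpha"], out["alpha_err"] = fit.exponent, fit.stderr
    if len(t_pts) >= 3:
        fit = fit_scaling_exponent(*zip(*t_pts))
        out["beta"], out["beta_err"] = fit.exponent, fit.stderr
    if pts:
        out["n_range"] = f"{min(p.n for p in pts)}-{max(p.n for p in pts)}"
    return out


def write_xyz(frames: Sequence[np.ndarray], path: str | Path,
              element: str = "C") -> None:
    """Dump chain conformations as a multi-frame XYZ file (one atom per
    monomer), readable by standard molecular viewers."""
    with open(path, "w") as fh:
        for k, pos in enumerate(frames):
            fh.write(f"{len(pos)}\nframe {k}\n")
            for p in pos:
                fh.write(f"{element} {p[0]:.1f} {p[1]:.1f} {p[2]:.1f}\n")
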
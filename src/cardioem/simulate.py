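"""Simulation driver: run a configured experiment, record probes, activation
maps and VTK snapshots.

``run_simulation`` builds the mesh and fiber field, initializes every node at
the Beeler-Reuter resting state with zero active tension, and advances the
coupled (or electrophysiology-only) stepper over the configured duration.
Per PDE step it records probe traces and updates the activation map (first
upstroke crossing of the threshold, linearly interpolated between steps);
every ``output_interval`` it writes a legacy-VTK snapshot with point fields
``v`` (mV), ``displacement`` (cm), ``active_tension`` (MPa) and cell fields
``stretch`` and ``scar``.  Runs are deterministic: identical configurations
produce bit-identical results.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .config import RunConfig
from .fem import CoupledStepper
from .geometry import make_mesh, select_stimulus_nodes
from .mesh import Mesh
from .vtkio import snapshot_filename, write_vtk

#: default upstroke-detection threshold (mV)
ACTIVATION_THRESHOLD = -40.0


@dataclass
class SimulationResult:
    config: RunConfig
    mesh: Mesh
    stepper: CoupledStepper
    times: np.ndarray                       # per-PDE-step instants incl. t = 0
    probe_nodes: List[int]
    probe_v: np.ndarray                     # (T, n_probes)
    probe_ta: np.ndarray
    probe_disp: np.ndarray                  # (T, n_probes, 3)
    activation_time: np.ndarray             # (n_nodes,), inf = never
    snapshot_files: List[str] = field(default_factory=list)
    v_history: Optional[np.ndarray] = None  # (T, n_nodes) if requested
    x_history: Optional[np.ndarray] = None  # (T, n_nodes, 3) if requested

    def write_probe_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["t_ms"]
            for k in range(len(self.probe_nodes)):
                header += [f"v{k}_mV", f"Ta{k}_MPa",
                           f"ux{k}_cm", f"uy{k}_cm", f"uz{k}_cm"]
            w.writerow(header)
            for i, t in enumerate(self.times):
                row = [f"{t:.6g}"]
                for k in range(len(self.probe_nodes)):
                    row += [f"{self.probe_v[i, k]:.9g}",
                            f"{self.probe_ta[i, k]:.9g}",
                            *(f"{self.probe_disp[i, k, c]:.9g}" for c in range(3))]
                w.writerow(row)
        return path


def _update_activation(act, v_prev, v_cur, t_prev, t_cur, threshold):
    """First-crossing times with linear interpolation, in place."""
    crossing = (act == np.inf) & (v_cur >= threshold)
    if not crossing.any():
        return
    frac = np.ones(np.count_nonzero(crossing))
    dv = v_cur[crossing] - v_prev[crossing]
    ok = dv > 0
    frac[ok] = (threshold - v_prev[crossing][ok]) / dv[ok]
    frac = np.clip(frac, 0.0, 1.0)
    act[crossing] = t_prev + frac * (t_cur - t_prev)


def activation_map(v_history, times, threshold: float = ACTIVATION_THRESHOLD):
    """Per-node first time v >= threshold from a stored voltage history.

    ``v_history`` has shape (n_snapshots, n_nodes); crossings are linearly
    interpolated between snapshots.  Nodes that never cross get ``inf``.
    """
    v_history = np.asarray(v_history, dtype=float)
    times = np.asarray(times, dtype=float)
    act = np.full(v_history.shape[1], np.inf)
    act[v_history[0] >= threshold] = times[0]
    for i in range(1, len(times)):
        _update_activation(act, v_history[i - 1], v_history[i],
                           times[i - 1], times[i], threshold)
    return act


def _write_snapshot(stepper, output_dir, index):
    mesh = stepper.mesh
    kin = stepper._kinematics()
    stretch_elem = kin.stretch.mean(axis=1)
    scar = mesh.scar_element_mask().astype(float)
    return write_vtk(
        snapshot_filename(output_dir, index),
        mesh.x_cur, mesh.hexes,
        point_data={"v": stepper.cells.v,
                    "displacement": mesh.displacement(),
                    "active_tension": stepper.t_a},
        cell_data={"stretch": stretch_elem, "scar": scar},
    )


def run_simulation(config: RunConfig, output_dir=None,
                   keep_history: bool = False,
                   activation_threshold: float = ACTIVATION_THRESHOLD
                   ) -> SimulationResult:
    """Execute a configured simulation and return the result bundle."""
    mesh = make_mesh(config.geometry)
    stim_nodes = select_stimulus_nodes(mesh, config.geometry.stimulus)
    stepper = CoupledStepper(
        mesh, ionic=config.ionic, tension=config.tension,
        material=config.material, solver=config.solver, mode=config.mode,
        stim_nodes=stim_nodes, stim_onset=config.geometry.stimulus.onset)

    dt = config.solver.dt_pde
    n_steps = int(round(config.duration / dt))
    out_every = max(1, int(round(config.output_interval / dt)))
    probe_nodes = [mesh.node_near(p) for p in config.probes]

    n = mesh.n_nodes
    act = np.full(n, np.inf)
    act[stepper.cells.v >= activation_threshold] = 0.0
    times = [0.0]
    pv = [stepper.cells.v[probe_nodes].copy()]
    pta = [stepper.t_a[probe_nodes].copy()]
    pdisp = [mesh.displacement()[probe_nodes].copy()]
    vh = [stepper.cells.v.copy()] if keep_history else None
    xh = [mesh.x_cur.copy()] if keep_history else None

    snapshots = []
    if output_dir is not None:
        os.makedirs(output_dir, exist_ok=True)
        snapshots.append(_write_snapshot(stepper, output_dir, 0))

    v_prev = stepper.cells.v.copy()
    for k in range(n_steps):
        t = k * dt
        try:
            stepper.step(t)
        except Exception:
            # flush the last valid state before propagating
            if output_dir is not None:
                snapshots.append(
                    _write_snapshot(stepper, output_dir, len(snapshots)))
            raise
        t1 = (k + 1) * dt
        _update_activation(act, v_prev, stepper.cells.v, t, t1,
                           activation_threshold)
        v_prev = stepper.cells.v.copy()
        times.append(t1)
        pv.append(stepper.cells.v[probe_nodes].copy())
        pta.append(stepper.t_a[probe_nodes].copy())
        pdisp.append(mesh.displacement()[probe_nodes].copy())
        if keep_history:
            vh.append(stepper.cells.v.copy())
            xh.append(mesh.x_cur.copy())
        if output_dir is not None and (k + 1) % out_every == 0:
            snapshots.append(
                _write_snapshot(stepper, output_dir, len(snapshots)))

    result = SimulationResult(
        config=config, mesh=mesh, stepper=stepper,
        times=np.asarray(times), probe_nodes=probe_nodes,
        probe_v=np.asarray(pv), probe_ta=np.asarray(pta),
        probe_disp=np.asarray(pdisp), activation_time=act,
        snapshot_files=snapshots,
        v_history=np.asarray(vh) if keep_history else None,
        x_history=np.asarray(xh) if keep_history else None,
    )
    if output_dir is not None and probe_nodes:
        result.write_probe_csv(os.path.join(output_dir, "probes.csv"))
    return result
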
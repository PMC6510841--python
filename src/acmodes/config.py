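"""Run configuration, result persistence, and miniature test anatomies."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .anatomy import (
    AnatomyLayout,
    ConnectionMatrices,
    ConnectivityParams,
    FieldInfo,
    _block_rng,
    _gaussian_kernel,
    _noise,
)
from .dynamics import StimulusSpec
from .meg import KValues

__all__ = ["RunConfig", "load_config", "save_config", "save_results",
           "save_connections", "save_trajectory", "make_fixture"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    k_values: KValues = field(default_factory=KValues)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    tau_m_ms: float = 40.0
    alpha: float = 1.0
    t_max_ms: float = 600.0
    dt_ms: float = 1.0

    def validate(self) -> None:
        if self.tau_m_ms <= 0:
            raise ValueError("tau_m_ms must be positive")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")
        if not (self.t_max_ms > 0 and self.dt_ms > 0):
            raise ValueError("time grid parameters must be positive")
        self.connectivity.validate()

    def time_grid(self) -> np.ndarray:
        return np.arange(0.0, self.t_max_ms + 0.5 * self.dt_ms, self.dt_ms)

    def to_dict(self) -> dict:
        return {
            "connectivity": dataclasses.asdict(self.connectivity),
            "k_values": dataclasses.asdict(self.k_values),
            "stimulus": dataclasses.asdict(self.stimulus),
            "tau_m_ms": self.tau_m_ms,
            "alpha": self.alpha,
            "t_max_ms": self.t_max_ms,
            "dt_ms": self.dt_ms,
        }


def _from_dict(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")
    return cls(**data)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; missing keys fall back to the defaults.

    Unknown keys are rejected with the offending section named.  ``None`` or
    an empty file yields the full default configuration.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    top = {"connectivity", "k_values", "stimulus", "tau_m_ms", "alpha",
           "t_max_ms", "dt_ms"}
    unknown = set(raw) - top
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config")
    cfg = RunConfig(
        connectivity=_from_dict(ConnectivityParams, raw.get("connectivity", {}),
                                "connectivity"),
        k_values=_from_dict(KValues, raw.get("k_values", {}), "k_values"),
        stimulus=_from_dict(StimulusSpec, raw.get("stimulus", {}), "stimulus"),
        tau_m_ms=float(raw.get("tau_m_ms", 40.0)),
        alpha=float(raw.get("alpha", 1.0)),
        t_max_ms=float(raw.get("t_max_ms", 600.0)),
        dt_ms=float(raw.get("dt_ms", 1.0)),
    )
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def save_results(result, out_dir: str | Path, cfg: RunConfig | None = None) -> Path:
    """Persist a default-run result as tidy CSVs plus a JSON manifest.

    Writes ``erf.csv`` (time, total and component traces, per-field columns),
    ``modes.csv`` (eigenvalue, gamma, omega0^2, delta, regime per mode),
    ``metrics.json`` and ``manifest.json``; returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    erf = result.erf
    df = pd.DataFrame({"time_ms": erf.t_ms, "total": erf.total,
                       "excitatory": erf.excitatory,
                       "inh_within": erf.inh_within,
                       "inh_lateral": erf.inh_lateral})
    for name, tr in zip(erf.field_names, erf.per_field):
        df[f"field_{name}"] = tr
    df.to_csv(out / "erf.csv", index=False)

    spec = result.spectrum
    pd.DataFrame({
        "mode": np.arange(spec.n),
        "w_ac_d": spec.eigenvalues,
        "gamma": spec.gamma,
        "omega0_sq": spec.omega0_sq,
        "delta_re": spec.delta.real,
        "delta_im": spec.delta.imag,
        "regime": [r.value for r in spec.regimes],
    }).to_csv(out / "modes.csv", index=False)

    metrics = dataclasses.asdict(result.metrics)
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, default=float)

    manifest = {
        "config": (cfg or RunConfig()).to_dict(),
        "files": ["erf.csv", "modes.csv", "metrics.json"],
        "n_columns": result.layout.n,
        "n_cortical": result.layout.n_cortical,
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return path


def save_connections(conn: ConnectionMatrices, out_dir: str | Path) -> Path:
    """Persist the connection matrices: dense .npz plus a CSV of ``W_AC``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "connections.npz"
    np.savez_compressed(
        path, w_ac=conn.w_ac, w_ei_diag=conn.w_ei_diag,
        w_ii_diag=conn.w_ii_diag, w_ie_diag=conn.w_ie_diag,
        field_class=conn.field_class,
    )
    np.savetxt(out / "w_ac.csv", conn.w_ac, delimiter=",")
    return path


def save_trajectory(traj, out_dir: str | Path) -> Path:
    """Persist a coupled trajectory as tidy CSV (time, column, u, v) + .npz."""
    if traj.u is None or traj.v is None:
        raise ValueError("trajectory must be coupled before export")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out / "trajectory.npz", t_ms=traj.t_ms,
                        u=traj.u, v=traj.v, u_d=traj.u_d, v_d=traj.v_d)
    import pandas as pd

    n, T = traj.u.shape
    df = pd.DataFrame({
        "time_ms": np.repeat(traj.t_ms, n),
        "column": np.tile(np.arange(n), T),
        "u": traj.u.T.ravel(),
        "v": traj.v.T.ravel(),
    })
    path = out / "trajectory.csv"
    df.to_csv(path, index=False)
    return path


def make_fixture(
    n_fields: int = 3,
    columns_per_field: int = 4,
    seed: int = 0,
    params: ConnectivityParams | None = None,
) -> tuple[AnatomyLayout, ConnectionMatrices]:
    """Miniature hierarchy for fast tests: one afferent relay plus a cortical chain.

    Field 0 is the subcortical relay (area ``IC`` so the default stimulus
    protocol applies unchanged); the remaining fields form a cortical chain
    with areas cycling core -> belt -> parabelt.  All structural rules of the
    full anatomy hold: Gaussian tonotopic spread with multiplicative noise,
    Mexican-hat within-field kernels, one-to-one afferents, a symmetrized
    cortical block, and connection-class labels usable by the MEG model.
    """
    if n_fields < 2:
        raise ValueError("need at least one relay and one cortical field")
    if columns_per_field < 1:
        raise ValueError("columns_per_field must be positive")
    params = params or ConnectivityParams(seed=seed)
    if params.seed != seed:
        params = replace(params, seed=seed)
    params.validate()

    areas = ["IC"] + [("core", "belt", "parabelt")[min(k, 2)]
                      for k in range(n_fields - 1)]
    names = ["IC"] + [f"F{k}" for k in range(1, n_fields)]
    fields = tuple(
        FieldInfo(nm, ar, k * columns_per_field, columns_per_field)
        for k, (nm, ar) in enumerate(zip(names, areas))
    )
    layout = AnatomyLayout(fields)

    n = layout.n
    npc = columns_per_field
    w = np.zeros((n, n))
    cls = np.full((n_fields, n_fields), "", dtype="<U4")
    eye = np.eye(npc)

    def sl(k):
        return slice(fields[k].start, fields[k].stop)

    w[sl(0), sl(0)] = params.ic_recurrent * eye
    cls[0, 0] = "sub"
    w[sl(1), sl(0)] = params.thalamus_to_core * eye
    w[sl(0), sl(1)] = params.thalamus_to_core * eye
    cls[1, 0] = "ff"
    cls[0, 1] = "sub"

    for k in range(1, n_fields):
        kern = _gaussian_kernel(npc, params.r, params.sigma)
        kern -= _gaussian_kernel(npc, params.li_strength, params.li_sigma,
                                 spare_self=True)
        rng = _block_rng(params.seed, k, k)
        w[sl(k), sl(k)] = kern * _noise(rng, params.s, kern.shape)
        cls[k, k] = "wf"
    for k in range(1, n_fields - 1):
        kern = _gaussian_kernel(npc, params.between_high, params.sigma)
        rng = _block_rng(params.seed, k, k + 1)
        block = kern * _noise(rng, params.s, kern.shape)
        w[sl(k + 1), sl(k)] = block
        w[sl(k), sl(k + 1)] = block.T
        cls[k + 1, k] = "ff"
        cls[k, k + 1] = "fb"

    c0 = fields[1].start
    w[c0:, c0:] = 0.5 * (w[c0:, c0:] + w[c0:, c0:].T)

    conn = ConnectionMatrices(
        layout=layout, params=params, w_ac=w,
        w_ei_diag=np.ones(n), w_ii_diag=np.full(n, 0.2), w_ie_diag=np.ones(n),
        field_class=cls,
    )
    return layout, conn
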
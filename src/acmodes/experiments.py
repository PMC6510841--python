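"""In-silico experiments: default run, topography sweeps, parabelt perturbation,
and the topographical-vs-dynamical randomization ensembles.

The randomization ensembles separate the two parameter families that shape
the simulated ERF: the dynamical set P (connection matrices, time constant,
rate slope) and the topographical K matrices.  Per run, multipliers are drawn
from the half-half mixture of U[0.5, 1] and U[1, 2]; topographical runs
randomize the nonzero field-level K entries with the dynamics frozen, while
dynamical runs randomize the three scalar within-column weights and draw a
fresh stochastic connection matrix with the K values frozen.  Runs whose
normal-mode spectrum contains any unstable mode are excluded from the
waveform statistics and counted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np

from .anatomy import build_connections, build_layout, modify_parabelt
from .config import RunConfig
from .dynamics import (
    ModeSpectrum,
    StateTrajectory,
    canonicalize,
    couple,
    decompose,
    solve_modes,
)
from .meg import ERFTrace, KValues, TopographyMatrices, build_K, compute_erf
from .waveform import WaveformMetrics, waveform_metrics

__all__ = [
    "DefaultRun",
    "RandomizationConfig",
    "EnsembleResult",
    "run_default",
    "sweep_K1",
    "parabelt_experiment",
    "run_ensemble",
    "mode_summary",
    "sample_multipliers",
]


@dataclass(frozen=True)
class DefaultRun:
    """End-to-end result of one simulation with a fixed configuration."""

    config: RunConfig
    layout: object
    conn: object
    system: object
    spectrum: ModeSpectrum
    traj: StateTrajectory
    K: TopographyMatrices
    erf: ERFTrace
    metrics: WaveformMetrics


def run_default(config: RunConfig | None = None) -> DefaultRun:
    """Build the default model, apply the standard stimulus, compute the ERF.

    Default protocol: resting start, 50-ms excitatory drive of amplitude 0.01
    to the central IC channel, 10-ms subcortical delay, 0-600 ms grid.
    """
    cfg = config or RunConfig()
    cfg.validate()
    layout = build_layout()
    conn = build_connections(layout, cfg.connectivity)
    system = canonicalize(conn, tau_m=cfg.tau_m_ms, alpha=cfg.alpha)
    spectrum = decompose(system)
    _, traj = solve_modes(spectrum, cfg.stimulus, cfg.time_grid())
    traj = couple(spectrum, traj)
    K = build_K(layout, conn, cfg.k_values)
    erf = compute_erf(traj, conn, K)
    metrics = waveform_metrics(erf)
    return DefaultRun(cfg, layout, conn, system, spectrum, traj, K, erf, metrics)


def sweep_K1(
    connection_class: str,
    values,
    config: RunConfig | None = None,
    base: DefaultRun | None = None,
) -> list[tuple[float, WaveformMetrics, ERFTrace]]:
    """Vary one K1 connection-class weight with the dynamics frozen.

    One connection-matrix realization is solved once; for each requested
    value the K matrices are rebuilt and only the forward model recomputed.
    """
    if connection_class not in ("feedforward", "feedback"):
        raise ValueError("connection_class must be 'feedforward' or 'feedback'")
    base = base or run_default(config)
    out = []
    for val in values:
        kv = replace(base.config.k_values, **{connection_class: float(val)})
        K = build_K(base.layout, base.conn, kv)
        erf = compute_erf(base.traj, base.conn, K)
        out.append((float(val), waveform_metrics(erf), erf))
    return out


@dataclass(frozen=True)
class ParabeltResult:
    baseline: DefaultRun
    perturbed: DefaultRun
    r_factor: float
    s_factor: float


def parabelt_experiment(
    r_factor: float = 3.0,
    s_factor: float = 2.0,
    config: RunConfig | None = None,
) -> ParabeltResult:
    """Regenerate the parabelt wiring (r x r_factor, s x s_factor) and rerun.

    Baseline and perturbed models share the seed, so every non-parabelt
    weight is bit-identical; only the parabelt blocks differ.
    """
    baseline = run_default(config)
    cfg = baseline.config
    conn2 = modify_parabelt(baseline.conn, r_factor, s_factor)
    system2 = canonicalize(conn2, tau_m=cfg.tau_m_ms, alpha=cfg.alpha)
    spectrum2 = decompose(system2)
    _, traj2 = solve_modes(spectrum2, cfg.stimulus, cfg.time_grid())
    traj2 = couple(spectrum2, traj2)
    K2 = build_K(baseline.layout, conn2, cfg.k_values)
    erf2 = compute_erf(traj2, conn2, K2)
    perturbed = DefaultRun(cfg, baseline.layout, conn2, system2, spectrum2,
                           traj2, K2, erf2, waveform_metrics(erf2))
    return ParabeltResult(baseline, perturbed, r_factor, s_factor)


def sample_multipliers(rng: np.random.Generator, size) -> np.ndarray:
    """Half-half mixture of U[0.5, 1] and U[1, 2] (equiprobable halves)."""
    low = rng.uniform(0.5, 1.0, size=size)
    high = rng.uniform(1.0, 2.0, size=size)
    pick_low = rng.random(size=size) < 0.5
    return np.where(pick_low, low, high)


@dataclass(frozen=True)
class RandomizationConfig:
    """What to randomize, how often, and from which base seed."""

    mode: str = "topographical"  # or "dynamical"
    n_runs: int = 1000
    base_seed: int = 0
    #: N1m floor for latency-range summaries, as a fraction of the
    #: default-run N1m amplitude (the signal units of R(t) are arbitrary,
    #: so the filter that drops the smallest-amplitude waveforms is defined
    #: relative to the unrandomized waveform).
    amplitude_floor_frac: float = 0.35
    #: absolute override for the floor, in R(t) units; wins when set.
    amplitude_floor: float | None = None
    store_spectra: bool = False
    store_waveforms: bool = False

    def validate(self) -> None:
        if self.mode not in ("topographical", "dynamical"):
            raise ValueError("mode must be 'topographical' or 'dynamical'")
        if self.n_runs <= 0:
            raise ValueError("n_runs must be positive")


@dataclass
class EnsembleResult:
    """Per-run waveform metrics and stability bookkeeping of one ensemble."""

    config: RandomizationConfig
    t_ms: np.ndarray
    reference_n1m_amplitude: float
    stable: np.ndarray
    p1m_latency: np.ndarray
    n1m_latency: np.ndarray
    n1m_amplitude: np.ndarray
    f_erf: np.ndarray
    tau_erf: np.ndarray
    tau_valid: np.ndarray
    spectra: list | None = None      # per stored run: (gamma, delta) arrays
    waveforms: np.ndarray | None = None

    @property
    def n_runs(self) -> int:
        return self.stable.size

    @property
    def fraction_unstable(self) -> float:
        return float(1.0 - self.stable.mean())

    def f_mode(self, bin_width_hz: float = 1.0) -> float:
        """Histogram mode of the dominant-frequency distribution (stable runs)."""
        f = self.f_erf[self.stable & np.isfinite(self.f_erf)]
        edges = np.arange(bin_width_hz / 2, f.max() + bin_width_hz, bin_width_hz)
        counts, _ = np.histogram(f, bins=edges)
        k = int(np.argmax(counts))
        return float((edges[k] + edges[k + 1]) / 2)

    def tau_center(self) -> float:
        """Median envelope decay constant over stable runs with valid fits."""
        sel = self.stable & self.tau_valid & np.isfinite(self.tau_erf)
        return float(np.median(self.tau_erf[sel]))

    def n1m_latency_range(self, floor: float | None = None) -> tuple[float, float]:
        """(min, max) N1m latency over stable runs above the amplitude floor.

        ``floor`` is an absolute amplitude; when omitted, the configured
        absolute override is used if set, otherwise the configured fraction
        of the default-run N1m amplitude.
        """
        if floor is None:
            floor = (self.config.amplitude_floor
                     if self.config.amplitude_floor is not None
                     else self.config.amplitude_floor_frac
                     * abs(self.reference_n1m_amplitude))
        sel = self.stable & (np.abs(self.n1m_amplitude) > floor)
        lat = self.n1m_latency[sel]
        return float(np.min(lat)), float(np.max(lat))


def _field_block_signals(conn, layout, traj):
    """Field-resolved partial sums of the three R(t) terms.

    ``g1[fi, fj, t]`` is the summed excitatory synaptic input from field fj to
    field fi weighted by W+; multiplying by a field-level K1 and summing gives
    the excitatory ERF component without touching column space again.
    """
    nf = layout.n_fields
    T = traj.t_ms.size
    wp = conn.w_ac_pos
    wn = conn.w_ac_neg
    g1 = np.zeros((nf, nf, T))
    g3 = np.zeros((nf, nf, T))
    g2 = np.zeros((nf, T))
    cortical = {layout.fields.index(f) for f in layout.cortical_fields}
    for fi in cortical:
        a = layout.fields[fi]
        for fj in range(nf):
            b = layout.fields[fj]
            blk = wp[a.start:a.stop, b.start:b.stop]
            if blk.any():
                g1[fi, fj] = blk.sum(axis=0) @ traj.u[b.start:b.stop]
            blk = wn[a.start:a.stop, b.start:b.stop]
            if blk.any():
                g3[fi, fj] = blk.sum(axis=0) @ traj.u[b.start:b.stop]
        g2[fi] = (conn.w_ei_diag[a.start:a.stop][:, None]
                  * traj.v[a.start:a.stop]).sum(axis=0)
    return g1, g2, g3


def _solve_and_measure(cfg, layout, conn, k_values, scalar_multipliers=None):
    """One full analytic run; returns (spectrum, erf, metrics) or the unstable spectrum.

    ``scalar_multipliers = (m_ie, m_ei, m_ii)`` rescales the canonical scalar
    weights (the tilde matrices), as in the dynamical randomization.
    """
    system = canonicalize(conn, tau_m=cfg.tau_m_ms, alpha=cfg.alpha)
    if scalar_multipliers is not None:
        m_ie, m_ei, m_ii = scalar_multipliers
        system = dataclasses.replace(system, w_ie=system.w_ie * m_ie,
                                     w_ei=system.w_ei * m_ei,
                                     w_ii=system.w_ii * m_ii)
    spectrum = decompose(system)
    if not spectrum.stable:
        return spectrum, None, None
    _, traj = solve_modes(spectrum, cfg.stimulus, cfg.time_grid())
    traj = couple(spectrum, traj)
    K = build_K(layout, conn, k_values)
    erf = compute_erf(traj, conn, K)
    return spectrum, erf, waveform_metrics(erf)


def run_ensemble(
    rand: RandomizationConfig,
    config: RunConfig | None = None,
) -> EnsembleResult:
    """Run one randomization ensemble with reproducible per-run seeds.

    Every run derives its random stream from ``(base_seed, run_index)``, so
    any single run can be regenerated independently and a full re-run with
    the same base seed is identical.
    """
    rand.validate()
    cfg = config or RunConfig()
    cfg.validate()
    n = rand.n_runs
    layout = build_layout()
    conn0 = build_connections(layout, cfg.connectivity)
    K0 = build_K(layout, conn0, cfg.k_values)
    _, _, metrics0 = _solve_and_measure(cfg, layout, conn0, cfg.k_values)
    if metrics0 is None:
        raise RuntimeError("default dynamics unstable; cannot run ensemble")

    nan = np.full(n, np.nan)
    res = EnsembleResult(
        config=rand, t_ms=cfg.time_grid(),
        reference_n1m_amplitude=float(metrics0.n1m_amplitude),
        stable=np.zeros(n, dtype=bool),
        p1m_latency=nan.copy(), n1m_latency=nan.copy(),
        n1m_amplitude=nan.copy(), f_erf=nan.copy(), tau_erf=nan.copy(),
        tau_valid=np.zeros(n, dtype=bool),
        spectra=[] if rand.store_spectra else None,
        waveforms=np.full((n, cfg.time_grid().size), np.nan)
        if rand.store_waveforms else None,
    )

    if rand.mode == "topographical":
        # dynamics frozen: solve once, randomize only the forward model
        system = canonicalize(conn0, tau_m=cfg.tau_m_ms, alpha=cfg.alpha)
        spectrum = decompose(system)
        if not spectrum.stable:
            raise RuntimeError("default dynamics unstable; cannot run ensemble")
        _, traj = solve_modes(spectrum, cfg.stimulus, cfg.time_grid())
        traj = couple(spectrum, traj)
        g1, g2, g3 = _field_block_signals(conn0, layout, traj)
        nz1 = np.nonzero(K0.k1)
        nz2 = np.nonzero(K0.k2)
        nz3 = np.nonzero(K0.k3)
        for i in range(n):
            rng = np.random.default_rng(np.random.SeedSequence((rand.base_seed, i)))
            k1 = K0.k1.copy()
            k2 = K0.k2.copy()
            k3 = K0.k3.copy()
            k1[nz1] *= sample_multipliers(rng, nz1[0].size)
            k2[nz2] *= sample_multipliers(rng, nz2[0].size)
            k3[nz3] *= sample_multipliers(rng, nz3[0].size)
            total = (np.tensordot(k1, g1, axes=2) + k2.diagonal() @ g2
                     + np.tensordot(k3, g3, axes=2))
            m = waveform_metrics((cfg.time_grid(), total))
            _record(res, i, m, spectrum if rand.store_spectra else None, total)
            res.stable[i] = True
        return res

    # dynamical mode: fresh stochastic W_AC and three scalar multipliers per run
    for i in range(n):
        ss = np.random.SeedSequence((rand.base_seed, i))
        child_rng, child_seed = ss.spawn(2)
        rng = np.random.default_rng(child_rng)
        mult = tuple(sample_multipliers(rng, 3))
        wseed = int(child_seed.generate_state(1)[0] % (2**31))
        params = replace(cfg.connectivity, seed=wseed)
        conn = build_connections(layout, params)
        spectrum, erf, metrics = _solve_and_measure(
            cfg, layout, conn, cfg.k_values, scalar_multipliers=mult)
        if erf is None:
            if rand.store_spectra:
                res.spectra.append((spectrum.gamma, spectrum.delta))
            continue
        res.stable[i] = True
        _record(res, i, metrics, spectrum if rand.store_spectra else None,
                erf.total)
    return res


def _record(res, i, m, spectrum, waveform):
    res.p1m_latency[i] = m.p1m_latency_ms
    res.n1m_latency[i] = m.n1m_latency_ms
    res.n1m_amplitude[i] = m.n1m_amplitude
    res.f_erf[i] = m.f_erf_hz
    res.tau_erf[i] = m.tau_erf_ms
    res.tau_valid[i] = m.tau_valid
    if spectrum is not None:
        res.spectra.append((spectrum.gamma, spectrum.delta))
    if res.waveforms is not None:
        res.waveforms[i] = waveform


def mode_summary(result: EnsembleResult, run_indices) -> list[dict]:
    """Per-run (gamma_d, Re delta_d) scatter data tagged with that run's f_ERF."""
    if result.spectra is None:
        raise ValueError("ensemble was run without store_spectra=True")
    out = []
    for r in run_indices:
        r = int(r)
        if not 0 <= r < len(result.spectra):
            raise IndexError(f"run {r} has no stored spectrum")
        gamma, delta = result.spectra[r]
        out.append({"run": r, "gamma": np.asarray(gamma),
                    "delta": np.asarray(delta).real,
                    "f_erf_hz": float(result.f_erf[r])})
    return out
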
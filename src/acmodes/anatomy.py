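"""Hierarchical anatomy of the auditory-cortex network and its connection matrices.

The model network comprises 15 tonotopically organized fields of 16 columns
each: one inferior-colliculus (IC) field, one thalamic field, and a
core-belt-parabelt cortical hierarchy of 13 fields (3 core, 8 belt,
2 parabelt) wired after the macaque scheme.  Every column holds one excitatory
and one inhibitory mean-field population; between-column connections are
collected in a single signed matrix ``W_AC`` whose positive part carries
excitation and whose negative part carries lateral (within-field surround)
inhibition.  Within-column inhibitory weights live on the diagonal matrices
``W_ei``, ``W_ii``, ``W_ie,d``.

Connections between tonotopic counterparts spread to neighboring channels
with a Gaussian profile that is perturbed multiplicatively by log-uniform
stochastic factors; the cortical block is symmetrized after generation, which
the analytic normal-mode solution requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "AREAS",
    "COLUMNS_PER_FIELD",
    "FIELD_SPECS",
    "CORTICAL_EDGES",
    "FieldInfo",
    "AnatomyLayout",
    "ConnectivityParams",
    "ConnectionMatrices",
    "build_layout",
    "build_connections",
    "modify_parabelt",
]

AREAS = ("IC", "thalamus", "core", "belt", "parabelt")

COLUMNS_PER_FIELD = 16

#: Canonical field roster: (name, area).  Order fixes the column indexing:
#: IC occupies columns 0-15, thalamus 16-31, cortex 32-239.
FIELD_SPECS = (
    ("IC", "IC"),
    ("TH", "thalamus"),
    ("A1", "core"),
    ("R", "core"),
    ("RT", "core"),
    ("CM", "belt"),
    ("CL", "belt"),
    ("ML", "belt"),
    ("MM", "belt"),
    ("RM", "belt"),
    ("AL", "belt"),
    ("RTM", "belt"),
    ("RTL", "belt"),
    ("CPB", "parabelt"),
    ("RPB", "parabelt"),
)

#: Bidirectional cortical between-field connections (field_a, field_b,
#: density class).  36 edges after the macaque core-belt-parabelt scheme:
#: core fields interconnect and project to flanking belt fields, belt fields
#: form a ring around the core and feed the two parabelt fields.
CORTICAL_EDGES = (
    # core-core
    ("A1", "R", "high"),
    ("R", "RT", "high"),
    ("A1", "RT", "low"),
    # core-belt
    ("A1", "CM", "high"),
    ("A1", "CL", "high"),
    ("A1", "ML", "high"),
    ("A1", "MM", "high"),
    ("A1", "RM", "low"),
    ("R", "ML", "high"),
    ("R", "MM", "low"),
    ("R", "RM", "high"),
    ("R", "AL", "high"),
    ("RT", "AL", "high"),
    ("RT", "RTM", "high"),
    ("RT", "RTL", "high"),
    # belt-belt ring
    ("CM", "CL", "high"),
    ("CM", "MM", "high"),
    ("CL", "ML", "high"),
    ("ML", "MM", "high"),
    ("MM", "RM", "high"),
    ("ML", "AL", "high"),
    ("RM", "AL", "high"),
    ("RM", "RTM", "high"),
    ("AL", "RTL", "high"),
    ("RTM", "RTL", "high"),
    # belt-parabelt
    ("CM", "CPB", "high"),
    ("CL", "CPB", "high"),
    ("ML", "CPB", "high"),
    ("MM", "CPB", "low"),
    ("RM", "CPB", "low"),
    ("RM", "RPB", "high"),
    ("AL", "RPB", "high"),
    ("RTM", "RPB", "high"),
    ("RTL", "RPB", "high"),
    ("MM", "RPB", "low"),
    # parabelt-parabelt
    ("CPB", "RPB", "high"),
)


@dataclass(frozen=True)
class FieldInfo:
    """One tonotopic field: a contiguous run of column indices."""

    name: str
    area: str
    start: int
    size: int

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.size)

    @property
    def stop(self) -> int:
        return self.start + self.size


@dataclass(frozen=True)
class AnatomyLayout:
    """Ordered fields plus derived index maps for the column vector space."""

    fields: tuple[FieldInfo, ...]

    def __post_init__(self):
        stops = [f.start for f in self.fields]
        if stops != sorted(stops):
            raise ValueError("fields must be ordered by start index")
        pos = 0
        for f in self.fields:
            if f.start != pos:
                raise ValueError("field column indices must be contiguous")
            pos = f.stop
        if any(f.area not in AREAS for f in self.fields):
            raise ValueError(f"field areas must be among {AREAS}")

    @property
    def n(self) -> int:
        return self.fields[-1].stop

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    @property
    def cortical_areas(self) -> tuple[str, ...]:
        return ("core", "belt", "parabelt")

    @property
    def cortical_fields(self) -> tuple[FieldInfo, ...]:
        return tuple(f for f in self.fields if f.area in self.cortical_areas)

    @property
    def n_cortical(self) -> int:
        return sum(f.size for f in self.cortical_fields)

    @property
    def cortical_mask(self) -> np.ndarray:
        m = np.zeros(self.n, dtype=bool)
        for f in self.cortical_fields:
            m[f.start:f.stop] = True
        return m

    @property
    def field_of_column(self) -> np.ndarray:
        """Field index (position in ``fields``) for every column."""
        out = np.empty(self.n, dtype=np.intp)
        for k, f in enumerate(self.fields):
            out[f.start:f.stop] = k
        return out

    def field_index(self, name: str) -> int:
        for k, f in enumerate(self.fields):
            if f.name == name:
                return k
        raise KeyError(f"unknown field {name!r}")

    def field(self, name: str) -> FieldInfo:
        return self.fields[self.field_index(name)]

    def columns(self, name: str) -> np.ndarray:
        return self.field(name).indices

    def area_fields(self, area: str) -> tuple[FieldInfo, ...]:
        return tuple(f for f in self.fields if f.area == area)


def build_layout() -> AnatomyLayout:
    """The canonical 15-field, 240-column layout (32 subcortical, 208 cortical)."""
    fields = []
    pos = 0
    for name, area in FIELD_SPECS:
        fields.append(FieldInfo(name, area, pos, COLUMNS_PER_FIELD))
        pos += COLUMNS_PER_FIELD
    return AnatomyLayout(tuple(fields))


@dataclass(frozen=True)
class ConnectivityParams:
    """Strengths and spread of the tonotopic connections.

    Parameters
    ----------
    r
        Peak weight of the within-field excitatory Gaussian spread.
    sigma
        Width of the Gaussian spread, in tonotopic channel units.
    s
        Stochasticity scale: every cortical weight is multiplied by
        ``exp(s * U(-1, 1))`` drawn independently per connection.
    li_strength, li_sigma
        Peak and width of the within-field lateral-inhibition Gaussian
        (all cortical fields).  The inhibitory surround spares the column
        itself (d = 0), so the net within-field kernel keeps a positive
        self-weight ``r`` while neighbouring channels inhibit one another.
    alt_strength, alt_sigma
        Interleaved (sign-alternating) side bands added to the secondary
        (belt and parabelt) within-field kernels: nearest tonotopic
        neighbours are inhibited, next-nearest facilitated, and so on, with
        a Gaussian envelope of width ``alt_sigma``.  This gives the
        secondary fields the multi-peaked tuning structure seen away from
        the core and places their alternating (high-tonotopic-frequency)
        activity patterns close to the oscillatory stability boundary.
        Because those patterns are orthogonal both to the smooth tonotopic
        spread of the afferent drive and to the field-level MEG readout,
        the marginal modes set the network's stability margin without
        dominating the simulated signal.
    between_high, between_low
        Gaussian peak weights for the high- and low-density between-field
        connection classes.
    sub_li_strength, sub_li_sigma
        Surround (lateral) inhibition within the IC and thalamic fields,
        sharpening the subcortical tonotopic relay and speeding its smooth
        response (stronger damping of the leak-dominated modes).
    ic_recurrent, ic_to_thalamus, thalamus_recurrent, thalamus_to_core
        Subcortical weights; one-to-one tonotopic.
    seed
        Base seed; every field-pair block derives its own independent stream,
        so regenerating a single block (parabelt perturbation) leaves all
        other entries bit-identical.
    """

    r: float = 0.102
    sigma: float = 1.391
    s: float = 0.353
    li_strength: float = 0.667
    li_sigma: float = 1.5
    alt_strength: float = 0.292
    alt_sigma: float = 1.23
    between_high: float = 0.156
    between_low: float = 0.044
    sub_li_strength: float = 0.308
    sub_li_sigma: float = 1.339
    ic_recurrent: float = 0.09
    ic_to_thalamus: float = 0.015
    thalamus_recurrent: float = 0.09
    thalamus_to_core: float = 0.015
    seed: int = 0

    def validate(self) -> None:
        if not self.r > 0:
            raise ValueError("Gaussian amplitude r must be positive")
        if not self.sigma > 0:
            raise ValueError("Gaussian width sigma must be positive")
        if not self.s >= 0:
            raise ValueError("stochasticity s must be non-negative")
        if not (self.li_strength >= 0 and self.li_sigma > 0):
            raise ValueError("lateral-inhibition parameters must be positive")
        if not (self.alt_strength >= 0 and self.alt_sigma > 0):
            raise ValueError("alternating side-band parameters must be positive")
        if not (self.sub_li_strength >= 0 and self.sub_li_sigma > 0):
            raise ValueError("subcortical surround parameters must be positive")
        for name in ("between_high", "between_low", "ic_recurrent",
                     "ic_to_thalamus", "thalamus_recurrent", "thalamus_to_core"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class ConnectionMatrices:
    """Signed between-column matrix ``W_AC`` plus diagonal within-column weights.

    ``field_class`` is the 15x15 (post, pre) connection-class label matrix with
    entries '' (none), 'wf' (cortical within-field), 'ff'/'fb' (cortical
    between-field feedforward/feedback; also thalamus-to-core afferents as
    'ff'), and 'sub' (remaining subcortical wiring).  The functional direction
    of subcortical afferents is preserved only here; in ``w_ac`` they are
    entered symmetrically so the matrix stays diagonalizable by an orthogonal
    eigenbasis.
    """

    layout: AnatomyLayout
    params: ConnectivityParams
    w_ac: np.ndarray
    w_ei_diag: np.ndarray
    w_ii_diag: np.ndarray
    w_ie_diag: np.ndarray
    field_class: np.ndarray

    @property
    def n(self) -> int:
        return self.layout.n

    @property
    def w_ac_pos(self) -> np.ndarray:
        """Excitatory part of ``W_AC`` (entries > 0)."""
        return np.where(self.w_ac > 0, self.w_ac, 0.0)

    @property
    def w_ac_neg(self) -> np.ndarray:
        """Lateral-inhibition part of ``W_AC`` (entries < 0)."""
        return np.where(self.w_ac < 0, self.w_ac, 0.0)

    def with_diagonals(self, w_ei: float, w_ii: float, w_ie: float) -> "ConnectionMatrices":
        n = self.n
        return replace(
            self,
            w_ei_diag=np.full(n, float(w_ei)),
            w_ii_diag=np.full(n, float(w_ii)),
            w_ie_diag=np.full(n, float(w_ie)),
        )


def _gaussian_kernel(n: int, amp: float, sigma: float, spare_self: bool = False) -> np.ndarray:
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    k = amp * np.exp(-(d.astype(float) ** 2) / (2.0 * sigma**2))
    if spare_self:
        np.fill_diagonal(k, 0.0)
    return k


def _alternating_kernel(n: int, amp: float, sigma: float) -> np.ndarray:
    """Sign-alternating side bands: -amp at |d|=1, +.. at |d|=2, Gaussian envelope."""
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    k = amp * np.cos(np.pi * d) * np.exp(-(d.astype(float) ** 2) / (2.0 * sigma**2))
    np.fill_diagonal(k, 0.0)
    return k


def _noise(rng: np.random.Generator, s: float, shape) -> np.ndarray:
    # Multiplicative log-uniform perturbation of scale s; s = 0 is exact.
    return np.exp(s * rng.uniform(-1.0, 1.0, size=shape))


def _block_rng(seed: int, fi: int, fj: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), fi, fj)))


def build_connections(
    layout: AnatomyLayout,
    params: ConnectivityParams | None = None,
    *,
    _block_overrides: Mapping[tuple[int, int], tuple[float, float]] | None = None,
) -> ConnectionMatrices:
    """Assemble ``W_AC`` and the diagonal matrices for the given layout.

    ``_block_overrides`` maps an (ordered) cortical field-index pair to
    ``(r_factor, s_factor)`` multipliers applied when that block is generated;
    this is the regeneration hook used by :func:`modify_parabelt`.
    """
    params = params or ConnectivityParams()
    params.validate()
    for area in AREAS:
        if not layout.area_fields(area):
            raise ValueError(f"layout lacks an {area!r} field")
    overrides = dict(_block_overrides or {})

    nf = layout.n_fields
    n = layout.n
    npc = layout.fields[0].size
    w = np.zeros((n, n))
    cls = np.full((nf, nf), "", dtype="<U4")

    name2idx = {f.name: k for k, f in enumerate(layout.fields)}
    area_rank = {"core": 0, "belt": 1, "parabelt": 2}

    def sl(k):
        f = layout.fields[k]
        return slice(f.start, f.stop)

    # --- subcortical wiring: one-to-one tonotopic, deterministic -------------
    ic_f = layout.area_fields("IC")[0]
    th_f = layout.area_fields("thalamus")[0]
    ic_k = layout.fields.index(ic_f)
    th_k = layout.fields.index(th_f)
    eye = np.eye(npc)
    sub_surround = _gaussian_kernel(npc, params.sub_li_strength,
                                    params.sub_li_sigma, spare_self=True)
    w[sl(ic_k), sl(ic_k)] = params.ic_recurrent * eye - sub_surround
    w[sl(th_k), sl(th_k)] = params.thalamus_recurrent * eye - sub_surround
    # afferents entered symmetrically (both directions) so W_AC stays symmetric
    w[sl(th_k), sl(ic_k)] = params.ic_to_thalamus * eye
    w[sl(ic_k), sl(th_k)] = params.ic_to_thalamus * eye
    cls[ic_k, ic_k] = cls[th_k, th_k] = "sub"
    cls[th_k, ic_k] = cls[ic_k, th_k] = "sub"
    for f in layout.area_fields("core"):
        k = layout.fields.index(f)
        w[sl(k), sl(th_k)] = params.thalamus_to_core * eye
        w[sl(th_k), sl(k)] = params.thalamus_to_core * eye
        cls[k, th_k] = "ff"   # thalamocortical afferent, feedforward class
        cls[th_k, k] = "sub"  # symmetry partner; functionally not a feedback path

    # --- cortical within-field blocks: Mexican-hat kernel --------------------
    cortical_idx = [layout.fields.index(f) for f in layout.cortical_fields]
    for k in cortical_idx:
        rf, sf = overrides.get((k, k), (1.0, 1.0))
        kern = _gaussian_kernel(npc, params.r * rf, params.sigma)
        kern -= _gaussian_kernel(npc, params.li_strength, params.li_sigma,
                                 spare_self=True)
        if layout.fields[k].area in ("belt", "parabelt"):
            kern += _alternating_kernel(npc, params.alt_strength, params.alt_sigma)
        rng = _block_rng(params.seed, k, k)
        w[sl(k), sl(k)] = kern * _noise(rng, params.s * sf, kern.shape)
        cls[k, k] = "wf"

    # --- cortical between-field blocks ---------------------------------------
    strength = {"high": params.between_high, "low": params.between_low}
    for a, b, density in CORTICAL_EDGES:
        if a not in name2idx or b not in name2idx:
            continue
        ka, kb = name2idx[a], name2idx[b]
        ka, kb = min(ka, kb), max(ka, kb)
        rf, sf = overrides.get((ka, kb), (1.0, 1.0))
        kern = _gaussian_kernel(npc, strength[density], params.sigma)
        rng = _block_rng(params.seed, ka, kb)
        block = kern * _noise(rng, params.s * sf, kern.shape)
        w[sl(kb), sl(ka)] = block
        w[sl(ka), sl(kb)] = block.T
        fa, fb = layout.fields[ka], layout.fields[kb]
        ra = (area_rank[fa.area], ka)
        rb = (area_rank[fb.area], kb)
        # entry (i, j) is the connection j -> i; higher-ranked post = feedforward
        if rb > ra:
            cls[kb, ka] = "ff"
            cls[ka, kb] = "fb"
        else:
            cls[kb, ka] = "fb"
            cls[ka, kb] = "ff"

    # --- symmetrize the cortical block (analytic requirement) ----------------
    c0 = layout.cortical_fields[0].start
    w[c0:, c0:] = 0.5 * (w[c0:, c0:] + w[c0:, c0:].T)

    return ConnectionMatrices(
        layout=layout,
        params=params,
        w_ac=w,
        w_ei_diag=np.ones(n),
        w_ii_diag=np.full(n, 0.2),
        w_ie_diag=np.ones(n),
        field_class=cls,
    )


def modify_parabelt(
    conn: ConnectionMatrices,
    r_factor: float,
    s_factor: float,
) -> ConnectionMatrices:
    """Regenerate the parabelt blocks with scaled Gaussian amplitude and noise.

    Within-parabelt blocks are regenerated with ``r * r_factor`` and
    ``s * s_factor``; the between-parabelt block with ``s * s_factor`` only.
    All other entries are reproduced bit-identically from the stored seed.
    ``(r_factor, s_factor) = (1, 1)`` returns matrices equal to the input.
    """
    if not (r_factor > 0 and s_factor > 0):
        raise ValueError("perturbation factors must be positive")
    layout = conn.layout
    pb = [layout.fields.index(f) for f in layout.area_fields("parabelt")]
    overrides = {(k, k): (float(r_factor), float(s_factor)) for k in pb}
    for i, ka in enumerate(pb):
        for kb in pb[i + 1:]:
            overrides[(min(ka, kb), max(ka, kb))] = (1.0, float(s_factor))
    out = build_connections(layout, conn.params, _block_overrides=overrides)
    return replace(
        out,
        w_ei_diag=conn.w_ei_diag.copy(),
        w_ii_diag=conn.w_ii_diag.copy(),
        w_ie_diag=conn.w_ie_diag.copy(),
    )
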
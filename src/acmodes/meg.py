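"""MEG forward model: the event-related field as a topographically weighted sum.

The simulated MEG signal is the sum over all synaptic inputs to the cortical
excitatory (pyramidal) populations, with each input weighted by a topography
factor that stands in for current orientation, synapse placement on the
apical dendrite, and sensor distance:

    R(t) = sum_ij [ K1[i,j] W+_AC[i,j] u_j(t)
                  + K2[i,j] W_ei[i,j]  v_j(t)
                  + K3[i,j] W-_AC[i,j] u_j(t) ],   i cortical.

``K1`` modulates excitatory connections and distinguishes feedforward,
feedback and within-field classes (feedback carries the opposite polarity to
feedforward, reflecting the deep- vs. superficial-layer termination of the
two pathways); ``K2`` and ``K3`` modulate within-column and lateral
inhibition and share the feedback polarity.  The K matrices have field-level
granularity: one value per 16x16 block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import AnatomyLayout, ConnectionMatrices

__all__ = ["KValues", "TopographyMatrices", "ERFTrace", "build_K",
           "compute_erf", "decompose_by_field"]


@dataclass(frozen=True)
class KValues:
    """Field-level topography weights (defaults from the reference table)."""

    feedforward: float = -4.0
    feedback: float = 20.0
    within_field: float = -5.0
    k2_within_field: float = 2.0
    k3_within_field: float = 2.0


@dataclass(frozen=True)
class TopographyMatrices:
    """Field-level K matrices (n_fields x n_fields), expanded on demand."""

    layout: AnatomyLayout
    k1: np.ndarray
    k2: np.ndarray
    k3: np.ndarray

    def expand(self, field_matrix: np.ndarray) -> np.ndarray:
        """Blow a field-level matrix up to column resolution (block-constant)."""
        fo = self.layout.field_of_column
        return field_matrix[np.ix_(fo, fo)]


def build_K(
    layout: AnatomyLayout,
    conn: ConnectionMatrices,
    values: KValues | None = None,
) -> TopographyMatrices:
    """Assign topography weights to every labelled connection class.

    ``K1`` is nonzero wherever a cortical row carries an excitatory
    connection class ('ff', 'fb' or 'wf' — including the thalamocortical
    afferents onto the core, which are feedforward); ``K2`` and ``K3`` are
    nonzero on the cortical within-field diagonal only.
    """
    values = values or KValues()
    cls = conn.field_class
    nf = layout.n_fields
    cortical = {layout.fields.index(f) for f in layout.cortical_fields}
    k1 = np.zeros((nf, nf))
    k2 = np.zeros((nf, nf))
    k3 = np.zeros((nf, nf))
    lut = {"ff": values.feedforward, "fb": values.feedback, "wf": values.within_field}
    for i in range(nf):
        if i not in cortical:
            continue  # subcortical populations do not contribute to the MEG
        for j in range(nf):
            label = cls[i, j]
            if label in lut:
                k1[i, j] = lut[label]
        k2[i, i] = values.k2_within_field
        k3[i, i] = values.k3_within_field
    return TopographyMatrices(layout, k1, k2, k3)


@dataclass(frozen=True)
class ERFTrace:
    """Simulated ERF with exact connection-type and field decompositions."""

    t_ms: np.ndarray
    total: np.ndarray
    excitatory: np.ndarray
    inh_within: np.ndarray
    inh_lateral: np.ndarray
    field_names: tuple[str, ...]
    per_field: np.ndarray          # (n_cortical_fields, T)
    area_names: tuple[str, ...]
    per_area: np.ndarray           # (3, T)


def _component_weights(conn: ConnectionMatrices, K: TopographyMatrices):
    """Per-presynaptic-column weight vectors of the three R(t) terms,
    resolved by post-synaptic cortical field (rows of the returned arrays)."""
    layout = conn.layout
    k1x = K.expand(K.k1)
    k3x = K.expand(K.k3)
    m1 = k1x * conn.w_ac_pos
    m3 = k3x * conn.w_ac_neg
    k2_diag = K.expand(K.k2).diagonal() * conn.w_ei_diag
    cfields = layout.cortical_fields
    w1 = np.stack([m1[f.start:f.stop, :].sum(axis=0) for f in cfields])
    w3 = np.stack([m3[f.start:f.stop, :].sum(axis=0) for f in cfields])
    w2 = np.zeros((len(cfields), layout.n))
    for k, f in enumerate(cfields):
        w2[k, f.start:f.stop] = k2_diag[f.start:f.stop]
    return w1, w2, w3


def compute_erf(traj, conn: ConnectionMatrices, K: TopographyMatrices) -> ERFTrace:
    """Evaluate R(t) with its connection-type and per-field decompositions.

    Both decompositions are exact partitions of the double sum, so the three
    component traces and the 13 field traces each add up to the total.
    """
    if traj.u is None or traj.v is None:
        raise ValueError("trajectory must be coupled (column space) first")
    layout = conn.layout
    if traj.u.shape[0] != layout.n:
        raise ValueError("trajectory and connection matrices are inconsistent")
    w1, w2, w3 = _component_weights(conn, K)
    exc_f = w1 @ traj.u            # (n_fields_cortical, T)
    inw_f = w2 @ traj.v
    lat_f = w3 @ traj.u
    per_field = exc_f + inw_f + lat_f
    cfields = layout.cortical_fields
    areas = ("core", "belt", "parabelt")
    per_area = np.stack([
        per_field[[k for k, f in enumerate(cfields) if f.area == a]].sum(axis=0)
        for a in areas
    ])
    return ERFTrace(
        t_ms=traj.t_ms,
        total=per_field.sum(axis=0),
        excitatory=exc_f.sum(axis=0),
        inh_within=inw_f.sum(axis=0),
        inh_lateral=lat_f.sum(axis=0),
        field_names=tuple(f.name for f in cfields),
        per_field=per_field,
        area_names=areas,
        per_area=per_area,
    )


def decompose_by_field(traj, conn, K, layout=None):
    """Per-field and per-area ERF contributions (post-synaptic attribution)."""
    erf = compute_erf(traj, conn, K)
    fields = dict(zip(erf.field_names, erf.per_field))
    areas = dict(zip(erf.area_names, erf.per_area))
    return fields, areas
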
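"""Multi-bite peak-strain statistics over a set of solved load cases.

Every bite produces one per-element strain field.  The cumulative peak
element strain table keeps, for each bone element, the largest equivalent
(von Mises) strain generated by any bite, together with which bite produced
it; from it follow the dominant-bite-mode map (did incisor or molar biting
produce the element's peak?), the dominant-principal-strain map (is the
peak tensile strain or the peak compressive strain larger in magnitude?),
element-count histograms on a fixed 20 µε grid, and the volume fraction of
bone inside the normal-remodelling ("mechanostat") strain band.

Statistics are restricted to bone-labelled elements: teeth and sutures are
carried through the solves but excluded from reporting, and both
element-count and volume-weighted versions of the fractions are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from craniostrain.fe_solver import StrainField
from craniostrain.mesh import LabeledTetMesh

__all__ = [
    "PeakStrainTable",
    "DominanceMap",
    "peak_strain_map",
    "dominant_bite_mode",
    "dominant_principal",
    "strain_histogram",
    "band_volume_fraction",
    "sensitivity_compare",
]


@dataclass
class PeakStrainTable:
    """Per-bone-element maxima across load cases.

    ``argmax_regime`` indexes ``regime_ids``; ties between regimes resolve
    to the lowest index (first in the supplied case order).
    """

    element_ids: np.ndarray    #: indices into the mesh's element array (bone only)
    peak_vm: np.ndarray        #: peak von Mises strain (µε)
    argmax_regime: np.ndarray  #: index of the regime producing peak_vm
    peak_e1: np.ndarray        #: peak (most tensile) ε1 over regimes (µε)
    peak_e3: np.ndarray        #: peak compressive (most negative) ε3 (µε)
    volume: np.ndarray         #: element volumes (mm³)
    regime_ids: list           #: regime id per case index
    regime_modes: list         #: bite mode per case index

    def __len__(self) -> int:
        return len(self.element_ids)


@dataclass
class DominanceMap:
    """Binary per-element classification plus its volume fractions."""

    element_ids: np.ndarray
    label: np.ndarray              #: per-element class name
    volume_fraction: dict          #: class -> volume-weighted fraction
    count_fraction: dict           #: class -> element-count fraction


def peak_strain_map(fields: list[StrainField], mesh: LabeledTetMesh) -> PeakStrainTable:
    """Cumulative peak element strain table over all load cases.

    Selects the largest von Mises strain in each bone element from any of
    the separate bites (and, independently, the extreme tensile ε1 and
    compressive ε3).
    """
    if not fields:
        raise ValueError("need at least one strain field")
    n = mesh.n_elements
    for f in fields:
        if len(f.von_mises) != n:
            raise ValueError("all strain fields must share the mesh")
    bone = np.nonzero(mesh.material == "bone")[0]
    vm = np.stack([f.von_mises[bone] for f in fields])        # (ncase, nbone)
    e1 = np.stack([f.principal[bone, 0] for f in fields])
    e3 = np.stack([f.principal[bone, 2] for f in fields])
    argmax = vm.argmax(axis=0)                                # first max wins
    return PeakStrainTable(
        element_ids=bone,
        peak_vm=vm.max(axis=0),
        argmax_regime=argmax,
        peak_e1=e1.max(axis=0),
        peak_e3=e3.min(axis=0),
        volume=mesh.volumes()[bone],
        regime_ids=[f.regime_id for f in fields],
        regime_modes=[f.mode for f in fields],
    )


def _fractions(label: np.ndarray, volume: np.ndarray, classes) -> tuple[dict, dict]:
    vtot = volume.sum()
    vol = {c: float(volume[label == c].sum() / vtot) for c in classes}
    cnt = {c: float((label == c).sum() / len(label)) for c in classes}
    return vol, cnt


def dominant_bite_mode(table: PeakStrainTable,
                       regime_modes: list | None = None) -> DominanceMap:
    """Which mode of biting produced the largest strain in each element.

    Fractions are element-volume-weighted over bone (count-weighted also
    reported).
    """
    modes = regime_modes if regime_modes is not None else table.regime_modes
    label = np.array([modes[i] for i in table.argmax_regime], dtype="U16")
    vol, cnt = _fractions(label, table.volume, ("incisor", "molar"))
    return DominanceMap(table.element_ids, label, vol, cnt)


def dominant_principal(table: PeakStrainTable) -> DominanceMap:
    """Tensile- vs compressive-dominant classification of the peak strains.

    An element is compressive-dominant iff |peak ε3| > peak ε1; the tie
    goes to tensile.
    """
    comp = np.abs(table.peak_e3) > table.peak_e1
    label = np.where(comp, "compressive", "tensile").astype("U16")
    vol, cnt = _fractions(label, table.volume, ("tensile", "compressive"))
    return DominanceMap(table.element_ids, label, vol, cnt)


def strain_histogram(values: np.ndarray, bin_width: float = 20.0) -> pd.DataFrame:
    """Element counts on half-open strain bins ``[k*w, (k+1)*w)`` (µε)."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empty strain array")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    nbins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(nbins + 1) * bin_width
    idx = np.floor(values / bin_width).astype(int)
    counts = np.bincount(idx, minlength=nbins)
    return pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})


def band_volume_fraction(table: PeakStrainTable, low: float = 100.0,
                         high: float = 1500.0) -> float:
    """Volume fraction of bone with peak strain strictly inside (low, high).

    The default band 100–1500 µε is the range associated with normal bone
    remodelling (mechanostat homeostasis); the bounds are exclusive, per
    "above low / below high".
    """
    inside = (table.peak_vm > low) & (table.peak_vm < high)
    return float(table.volume[inside].sum() / table.volume.sum())


def sensitivity_compare(table_base: PeakStrainTable, table_variant: PeakStrainTable,
                        mesh: LabeledTetMesh, near_distance: float = 4.0) -> dict:
    """Per-element |Δ peak strain| between two runs, split near/far from
    compliant soft tissue.

    "Near" bone elements have centroids within ``near_distance`` mm of the
    nearest PDL or suture element centroid.  Returns the per-element
    absolute differences plus near/far medians — the expected signature of
    a soft-tissue stiffness perturbation is a localized change:
    ``median |Δ| (near) > median |Δ| (far)``.
    """
    if not np.array_equal(table_base.element_ids, table_variant.element_ids):
        raise ValueError("tables must cover the same bone elements")
    delta = np.abs(table_variant.peak_vm - table_base.peak_vm)
    cent = mesh.centroids()
    soft = np.isin(mesh.material, ("pdl", "suture"))
    if not soft.any():
        raise ValueError("mesh has no pdl/suture elements")
    tree = cKDTree(cent[soft])
    dist, _ = tree.query(cent[table_base.element_ids])
    near = dist <= near_distance
    return {
        "delta": delta,
        "near_mask": near,
        "near_distance": float(near_distance),
        "median_near": float(np.median(delta[near])) if near.any() else float("nan"),
        "median_far": float(np.median(delta[~near])) if (~near).any() else float("nan"),
        "max_delta": float(delta.max()),
    }
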
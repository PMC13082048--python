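"""Downstream-DNA deformation measured in a PCA reference frame.

The twelve nucleotides downstream of the active site in the reference
elongation complex define a coordinate frame: principal axes of the 3x3
covariance of their centers of mass.  PC1 runs along the DNA long axis;
PC2 spans the dominant lateral direction.  A query structure is core-
aligned to the reference and each nucleotide's center-of-mass displacement
is projected onto PC1/PC2; the means over the twelve nucleotides summarise
how far the downstream duplex has been pushed off its active-complex path.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .rigidgeom import kabsch_superpose
from .structio import (
    DEFAULT_CHAIN_MAP,
    ResidueSelection,
    StructureModel,
    residue_centers_of_mass,
    select_calpha,
)

__all__ = ["DNAFrame", "DisplacementResult", "build_dna_frame", "project_displacement", "coupling_fit"]


@dataclasses.dataclass(frozen=True)
class DNAFrame:
    origin: np.ndarray  # centroid of the 12 reference COMs, Å
    pc1: np.ndarray
    pc2: np.ndarray
    pc3: np.ndarray
    reference_coms: np.ndarray  # (12, 3), Å, selection order
    reference_keys: tuple  # ((chain, resnum), ...) matching reference_coms
    eigenvalues: np.ndarray  # descending, Å²

    def __post_init__(self) -> None:
        axes = np.array([self.pc1, self.pc2, self.pc3])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes are not orthonormal")
        if not np.allclose(np.cross(self.pc1, self.pc2), self.pc3, atol=1e-9):
            raise ValueError("frame is not right-handed")
        ev = np.asarray(self.eigenvalues)
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("eigenvalues must be descending")


@dataclasses.dataclass(frozen=True)
class DisplacementResult:
    mean_pc1: float  # Å
    mean_pc2: float  # Å
    per_nucleotide: np.ndarray  # (12, 2): pc1, pc2 projections, Å
    core_rmsd: float  # Å


def build_dna_frame(
    reference: StructureModel,
    nucleotides: ResidueSelection,
    mass_weighted: bool = True,
) -> DNAFrame:
    """PCA frame over the centers of mass of exactly twelve nucleotides.

    Sign convention (deterministic): pc1 points downstream (positive dot
    with last COM minus first COM); pc3 points from the DNA centroid toward
    the centroid of the rest of the model (the protein core), falling back
    to a fixed largest-component rule for DNA-only models; pc2 completes a
    right-handed frame.
    """
    coms = residue_centers_of_mass(reference, nucleotides, mass_weighted=mass_weighted)
    if len(coms) != 12:
        raise ValueError(f"expected exactly 12 nucleotides, got {len(coms)}")
    keys = tuple(k for k, _ in coms)
    X = np.array([c for _, c in coms], dtype=float)
    origin = X.mean(axis=0)
    cov = (X - origin).T @ (X - origin) / len(X)  # population (1/N) covariance
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[1] <= 1e-9 * max(evals[0], 1.0):
        raise ValueError("degenerate covariance: nucleotide COMs are collinear, pc2 undefined")

    pc1 = evecs[:, 0]
    # permutation-invariant downstream direction: sorted residue keys
    order_keys = sorted(range(12), key=lambda i: keys[i])
    downstream = X[order_keys[-1]] - X[order_keys[0]]
    if np.dot(pc1, downstream) < 0:
        pc1 = -pc1

    pc3 = evecs[:, 2]
    selected = set(keys)
    outside = np.array(
        [
            a.position
            for a in reference.atoms
            if (a.chain_id, a.residue_number) not in selected
        ]
    )
    if len(outside):
        toward_core = outside.mean(axis=0) - origin
        if np.dot(pc3, toward_core) < 0:
            pc3 = -pc3
    else:
        # DNA-only model: fix the sign by the largest-magnitude component
        if pc3[np.argmax(np.abs(pc3))] < 0:
            pc3 = -pc3
    pc2 = np.cross(pc3, pc1)

    return DNAFrame(
        origin=origin,
        pc1=pc1,
        pc2=pc2,
        pc3=np.cross(pc1, pc2),
        reference_coms=X,
        reference_keys=keys,
        eigenvalues=evals,
    )


def project_displacement(
    query: StructureModel,
    reference: StructureModel,
    frame: DNAFrame,
    core: ResidueSelection,
    nucleotides: ResidueSelection,
    chain_map: Mapping[str, str] | None = None,
    mass_weighted: bool = True,
) -> DisplacementResult:
    """Mean PC1/PC2 displacement of the twelve downstream nucleotides.

    The query is first core-aligned to the reference (CA Kabsch over the
    shared core residues), so the result is invariant to any prior global
    motion of the query.
    """
    chain_map = dict(chain_map) if chain_map is not None else dict(DEFAULT_CHAIN_MAP)
    core_mapped = core.mapped(chain_map)
    q_entries, _ = select_calpha(query, core_mapped)
    r_entries, _ = select_calpha(reference, core_mapped)
    q_pos = {(c, n): p for c, n, p in q_entries}
    shared = [(c, n) for c, n, _ in r_entries if (c, n) in q_pos]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared core residues for alignment")
    r_pos = {(c, n): p for c, n, p in r_entries}
    t_core = kabsch_superpose(
        np.array([q_pos[k] for k in shared]), np.array([r_pos[k] for k in shared])
    )

    q_coms = residue_centers_of_mass(query, nucleotides, mass_weighted=mass_weighted)
    q_map = {k: c for k, c in q_coms}
    missing = [k for k in frame.reference_keys if k not in q_map]
    if missing:
        raise ValueError(f"query is missing nucleotides: {missing}")

    per = np.empty((12, 2))
    for i, key in enumerate(frame.reference_keys):
        moved = t_core.rotation @ q_map[key] + t_core.translation
        delta = moved - frame.reference_coms[i]
        per[i, 0] = np.dot(delta, frame.pc1)
        per[i, 1] = np.dot(delta, frame.pc2)

    return DisplacementResult(
        mean_pc1=float(per[:, 0].mean()),
        mean_pc2=float(per[:, 1].mean()),
        per_nucleotide=per,
        core_rmsd=t_core.rmsd,
    )


def coupling_fit(points: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Least-squares line through (swivel angle, displacement) points.

    Returns (slope, intercept, Pearson r).  Captures the linear coupling
    between swivel-module rotation and downstream DNA displacement.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("need at least 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
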
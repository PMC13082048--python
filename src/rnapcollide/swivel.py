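"""Swivel-angle measurement for RNA polymerase elongation complexes.

The swivel module (clamp and associated regions: β 1241–1341 plus four β′
segments) rotates as a near-rigid body relative to the RNAP structural
core, and the magnitude of that rotation tracks transcriptional pausing.
The measurement is a two-stage superposition: align the structural cores
of query and reference, then find the residual rotation mapping the
reference swivel module onto the core-aligned query swivel module.  The
active elongation complex serves as the 0° reference.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np

from .rigidgeom import AxisAngle, RigidTransform, kabsch_superpose, rotation_to_axis_angle
from .structio import (
    DEFAULT_CHAIN_MAP,
    ResidueSelection,
    StructureModel,
    select_calpha,
)

__all__ = [
    "ModuleDefinition",
    "SwivelResult",
    "default_module_definition",
    "compute_swivel",
    "swivel_series",
    "infer_rnap_chain_map",
    "CoverageError",
]


class CoverageError(ValueError):
    """Too few shared residues between query and reference."""


@dataclasses.dataclass(frozen=True)
class ModuleDefinition:
    """Core and swivel residue selections (in canonical subunit chains)."""

    core: ResidueSelection
    swivel: ResidueSelection

    def __post_init__(self) -> None:
        for chain, s1, e1 in self.swivel.parts:
            lo1 = -(10**9) if s1 is None else s1
            hi1 = 10**9 if s1 is None else e1
            for chain2, s2, e2 in self.core.parts:
                if chain != chain2:
                    continue
                lo2 = -(10**9) if s2 is None else s2
                hi2 = 10**9 if s2 is None else e2
                if lo1 <= hi2 and lo2 <= hi1:
                    raise ValueError(
                        f"core and swivel selections overlap on chain {chain}"
                    )


# Core: all of both alpha subunits and omega, plus the rigid beta and
# beta-prime segments that do not move during swiveling.  Swivel: the
# clamp-containing beta/beta-prime segments.
_CORE_PARTS = (
    ("alpha", None, None),
    ("beta", 3, 27),
    ("beta", 142, 152),
    ("beta", 445, 455),
    ("beta", 520, 713),
    ("beta", 786, 828),
    ("betaprime", 343, 368),
    ("betaprime", 412, 524),
    ("betaprime", 530, 552),
    ("betaprime", 569, 701),
    ("betaprime", 720, 786),
    ("omega", None, None),
)
_SWIVEL_PARTS = (
    ("beta", 1241, 1341),
    ("betaprime", 1, 342),
    ("betaprime", 369, 420),
    ("betaprime", 787, 930),
    ("betaprime", 1135, 1375),
)


def default_module_definition() -> ModuleDefinition:
    """The standard E. coli RNAP core/swivel partition.

    Note the beta-prime core segment 412–524 overlaps the swivel segment
    369–420 in the raw residue lists; residues claimed by the swivel module
    are removed from the core so the two selections are disjoint.
    """
    # trim core betaprime 412-524 to 421-524: 412-420 belongs to the swivel
    parts = tuple(
        ("betaprime", 421, 524) if p == ("betaprime", 412, 524) else p
        for p in _CORE_PARTS
    )
    return ModuleDefinition(
        core=ResidueSelection(parts, "core"),
        swivel=ResidueSelection(_SWIVEL_PARTS, "swivel"),
    )


@dataclasses.dataclass(frozen=True)
class SwivelResult:
    angle: float  # degrees
    axis: AxisAngle
    core_rmsd: float  # Å
    swivel_rmsd: float  # Å
    n_core_pairs: int
    n_swivel_pairs: int
    core_transform: RigidTransform  # query -> reference core alignment
    swivel_translation: np.ndarray  # reported but not part of the angle


def _paired_calpha(
    query: StructureModel,
    reference: StructureModel,
    selection: ResidueSelection,
    chain_map: Mapping[str, str],
) -> tuple[np.ndarray, np.ndarray, float]:
    """CA positions for residues present in both structures, plus coverage."""
    mapped = selection.mapped(chain_map)
    try:
        q_entries, _ = select_calpha(query, mapped)
        r_entries, _ = select_calpha(reference, mapped)
    except Exception as exc:
        raise CoverageError(
            f"selection {selection.label!r} failed under chain map: {exc}"
        ) from exc
    q_pos = {(c, n): p for c, n, p in q_entries}
    r_pos = {(c, n): p for c, n, p in r_entries}
    shared = [k for (c, n, _p) in r_entries for k in [(c, n)] if k in q_pos]
    union = set(q_pos) | set(r_pos)
    coverage = len(shared) / len(union) if union else 0.0
    q = np.array([q_pos[k] for k in shared], dtype=float).reshape(-1, 3)
    r = np.array([r_pos[k] for k in shared], dtype=float).reshape(-1, 3)
    return q, r, coverage


def compute_swivel(
    query: StructureModel,
    reference: StructureModel,
    module_def: ModuleDefinition | None = None,
    chain_map: Mapping[str, str] | None = None,
    min_coverage: float = 0.5,
    warn_coverage: float = 0.8,
) -> SwivelResult:
    """Swivel angle of ``query`` relative to ``reference``.

    Residues are paired by identical (chain, residue number) after chain
    mapping; unpaired residues are dropped symmetrically.  The result is
    invariant to any prior global rigid motion of the query.
    """
    module_def = module_def or default_module_definition()
    chain_map = dict(chain_map) if chain_map is not None else dict(DEFAULT_CHAIN_MAP)

    q_core, r_core, cov_core = _paired_calpha(query, reference, module_def.core, chain_map)
    q_sw, r_sw, cov_sw = _paired_calpha(query, reference, module_def.swivel, chain_map)
    for name, cov in (("core", cov_core), ("swivel", cov_sw)):
        if cov < min_coverage:
            raise CoverageError(
                f"{name} CA coverage {cov:.0%} below {min_coverage:.0%} "
                f"between {query.identifier} and {reference.identifier}"
            )
        if cov < warn_coverage:
            warnings.warn(
                f"{name} CA coverage only {cov:.0%}; swivel angle may be noisy",
                stacklevel=2,
            )

    # stage 1: core of query onto core of reference
    t_core = kabsch_superpose(q_core, r_core)
    q_sw_aligned = q_sw @ t_core.rotation.T + t_core.translation

    # stage 2: reference swivel onto the core-aligned query swivel
    t_swivel = kabsch_superpose(r_sw, q_sw_aligned)
    axis = rotation_to_axis_angle(t_swivel)

    return SwivelResult(
        angle=axis.angle,
        axis=axis,
        core_rmsd=t_core.rmsd,
        swivel_rmsd=t_swivel.rmsd,
        n_core_pairs=len(q_core),
        n_swivel_pairs=len(q_sw),
        core_transform=t_core,
        swivel_translation=t_swivel.translation,
    )


def infer_rnap_chain_map(model: StructureModel) -> dict[str, str]:
    """Guess the actual-chain -> subunit mapping of a bacterial RNAP entry.

    Deposited E. coli RNAP structures label the subunits inconsistently, but
    their sizes are unmistakable: beta-prime reaches residue ~1375, beta
    ~1342, the two alpha copies span ~330 residues, and omega ~90.  Chains
    that look like none of these (nucleic acids, factors, roadblocks) are
    left unmapped.
    """
    mapping: dict[str, str] = {}
    for chain in model.chains:
        residues = model.residues(chain)
        has_ca = any(
            a.atom_name == "CA"
            for num in residues[:20]
            for a in model.atoms_of(chain, num)
        )
        if not has_ca or not residues:
            continue
        n, top = len(residues), residues[-1]
        if n > 1100 and top > 1350:
            mapping[chain] = "betaprime"
        elif n > 1000:
            mapping[chain] = "beta"
        elif 200 <= n <= 400 and top <= 500:
            mapping[chain] = "alpha"
        elif 40 <= n <= 120 and top <= 150:
            mapping[chain] = "omega"
    return mapping


def swivel_series(
    frames: Sequence[StructureModel],
    reference: StructureModel,
    module_def: ModuleDefinition | None = None,
    chain_map: Mapping[str, str] | None = None,
) -> tuple[list[SwivelResult], tuple[float, float]]:
    """Per-frame swivel results (input order) plus (min, max) angle summary."""
    if not frames:
        raise ValueError("need at least one frame")
    results: list[SwivelResult] = []
    for i, frame in enumerate(frames):
        try:
            results.append(compute_swivel(frame, reference, module_def, chain_map))
        except Exception as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
    angles = [r.angle for r in results]
    return results, (min(angles), max(angles))
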
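"""Synthetic inputs for every pipeline stage.

Each generator is a pure function of its seed and parameters and emits a
truth table (or has truth built into its construction) sufficient to score
the corresponding analysis stage: mock two-module polymerases with a known
swivel rotation, ideal B-form DNA (3.4 Å rise, 10.5 bp per turn), steric
collision scenes with known contact geometry, paired 5'/3' reads with a
recorded origin, bi-exponential decay curves, and salt-titration gel
tables.  Mock polymerases are CA-only: the swivel and displacement math
touches only alpha-carbons and centers of mass, so side chains add nothing.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biochem import DecayCurve, LaneQuant, TitrationSeries
from .rigidgeom import apply_transform, axis_angle_to_rotation
from .sendseq import TemplateSpec
from .structio import AtomRecord, StructureModel
from .swivel import default_module_definition

__all__ = [
    "MockPolymeraseSpec",
    "HelixSpec",
    "make_mock_polymerase",
    "make_bdna",
    "make_collision_scene",
    "make_template",
    "simulate_reads",
    "simulate_decay",
    "simulate_titration",
    "BDNA_RISE",
    "BDNA_TWIST",
]

BDNA_RISE = 3.4  # Å per base pair
BDNA_TWIST = 360.0 / 10.5  # degrees per base pair (10.5 bp/turn pitch)

# chain layout mirroring the subunit ranges the default module definition
# expects: two alpha copies, beta, beta-prime, omega
_DEFAULT_CHAINS: dict[str, tuple[int, int]] = {
    "A": (1, 329),  # alpha I
    "B": (1, 329),  # alpha II
    "C": (1, 1342),  # beta
    "D": (1, 1375),  # beta-prime
    "E": (1, 91),  # omega
}


@dataclasses.dataclass(frozen=True)
class MockPolymeraseSpec:
    seed: int = 0
    residues_per_chain: Mapping[str, tuple[int, int]] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_CHAINS)
    )
    swivel_angle: float = 3.0  # degrees
    swivel_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    axis_point: tuple[float, float, float] | None = None  # default: swivel centroid
    coordinate_noise: float = 0.0  # Å, Gaussian, applied to the query copy

    def __post_init__(self) -> None:
        if self.coordinate_noise < 0:
            raise ValueError("noise must be non-negative")


@dataclasses.dataclass(frozen=True)
class HelixSpec:
    n_bp: int = 40
    rise: float = BDNA_RISE  # Å
    twist: float = BDNA_TWIST  # degrees per bp
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bp < 2:
            raise ValueError("need at least 2 base pairs")


def _ca(chain: str, num: int, pos: np.ndarray) -> AtomRecord:
    return AtomRecord(
        chain_id=chain,
        residue_number=num,
        residue_name="ALA",
        atom_name="CA",
        element="C",
        occupancy=1.0,
        altloc="",
        position=pos,
        mass=12.011,
    )


def _chain_curve(chain_index: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth, non-planar space curve with ~3.8 Å CA spacing."""
    radius = 18.0 + 4.0 * chain_index
    turn = 0.18 + 0.015 * chain_index  # radians per residue
    pitch = 1.3 + 0.1 * chain_index
    phase = rng.uniform(0, 2 * np.pi)
    center = rng.uniform(-25.0, 25.0, size=3)
    i = np.arange(n)
    pts = np.stack(
        [
            radius * np.cos(turn * i + phase),
            radius * np.sin(turn * i + phase),
            pitch * i,
        ],
        axis=1,
    )
    # random rigid orientation so no two chains share an axis
    rot = axis_angle_to_rotation(rng.normal(size=3), rng.uniform(0, 360)).rotation
    return pts @ rot.T + center


def make_mock_polymerase(
    spec: MockPolymeraseSpec | None = None,
) -> tuple[StructureModel, StructureModel]:
    """(reference, query) pair with a known swivel-module rotation.

    The reference places CA pseudo-atoms on smooth per-chain space curves;
    the query equals the reference with the swivel-selection residues
    rotated by ``swivel_angle`` about ``(swivel_axis, axis_point)``, plus
    optional Gaussian coordinate noise.  Deterministic per seed.
    """
    spec = spec or MockPolymeraseSpec()
    rng = np.random.default_rng(spec.seed)
    module_def = default_module_definition()

    ref_atoms: list[AtomRecord] = []
    canonical = {"A": "alpha", "B": "alpha", "C": "beta", "D": "betaprime", "E": "omega"}
    for ci, (chain, (start, end)) in enumerate(spec.residues_per_chain.items()):
        pts = _chain_curve(ci, end - start + 1, rng)
        for k, num in enumerate(range(start, end + 1)):
            ref_atoms.append(_ca(chain, num, pts[k]))
    reference = StructureModel("mock-reference", ref_atoms)

    swivel_mask = np.array(
        [
            module_def.swivel.contains(canonical.get(a.chain_id, a.chain_id), a.residue_number)
            for a in ref_atoms
        ]
    )
    coords = reference.coordinates()
    if spec.axis_point is None:
        axis_point = coords[swivel_mask].mean(axis=0)
    else:
        axis_point = np.asarray(spec.axis_point, dtype=float)
    rot = axis_angle_to_rotation(
        np.asarray(spec.swivel_axis, dtype=float), spec.swivel_angle, axis_point
    )
    moved = coords.copy()
    moved[swivel_mask] = apply_transform(coords[swivel_mask], rot)
    if spec.coordinate_noise > 0:
        moved = moved + rng.normal(0.0, spec.coordinate_noise, size=moved.shape)
    query = StructureModel("mock-query", ref_atoms).with_coordinates(moved)
    return reference, query


# idealised backbone offsets (radius Å, azimuth deg, axial offset Å) for one
# strand, chosen near canonical B-form backbone geometry
_BACKBONE_OFFSETS: tuple[tuple[str, float, float, float], ...] = (
    ("P", 8.9, 95.0, -1.0),
    ("O5'", 8.8, 87.0, -0.4),
    ("C5'", 9.4, 80.0, 0.1),
    ("C4'", 9.2, 72.0, 0.6),
    ("C3'", 8.7, 66.0, 1.1),
    ("O3'", 8.9, 59.0, 1.7),
)


def _nt_atom(chain: str, num: int, name: str, pos: np.ndarray) -> AtomRecord:
    element = name[0]
    mass = {"P": 30.974, "O": 15.999, "C": 12.011}[element]
    return AtomRecord(
        chain_id=chain,
        residue_number=num,
        residue_name="DA",
        atom_name=name,
        element=element,
        occupancy=1.0,
        altloc="",
        position=pos,
        mass=mass,
    )


def make_bdna(spec: HelixSpec | None = None) -> StructureModel:
    """Ideal B-form DNA: two antiparallel backbone-only strands.

    Chains "T" (template) and "N" (non-template); residues on both strands
    are numbered 1..n_bp by base-pair level, so advancing every residue
    number by one is exactly the helical screw step (rise Å, twist°).
    """
    spec = spec or HelixSpec()
    atoms: list[AtomRecord] = []
    for i in range(spec.n_bp):
        phi = np.radians(spec.twist * i)
        c, s = np.cos(phi), np.sin(phi)
        rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        lift = np.array([0.0, 0.0, spec.rise * i])
        for name, r, az, dz in _BACKBONE_OFFSETS:
            a = np.radians(az)
            local = np.array([r * np.cos(a), r * np.sin(a), dz])
            atoms.append(_nt_atom("T", i + 1, name, rz @ local + lift))
            # antiparallel strand: reflected through the dyad (x-z) plane,
            # which puts the two backbones ~206 deg apart as in B-form DNA
            local2 = np.array([r * np.cos(-a), r * np.sin(-a), -dz])
            atoms.append(_nt_atom("N", i + 1, name, rz @ local2 + lift))
    return StructureModel(f"bdna-{spec.n_bp}bp", atoms)


def _blob(chain: str, center: np.ndarray, radius: float, atom_radius: float = 1.7) -> list[AtomRecord]:
    """Pseudo-atom ball whose solvent-excluded body is ~ a sphere of ``radius``."""
    shell_r = max(radius - atom_radius, 0.0)
    pts = [center]
    if shell_r > 0:
        n = max(16, int(4 * np.pi * shell_r**2 / 1.5))
        # Fibonacci sphere
        k = np.arange(n) + 0.5
        theta = np.arccos(1 - 2 * k / n)
        phi = np.pi * (1 + 5**0.5) * k
        pts.extend(
            center
            + shell_r
            * np.stack(
                [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
                axis=1,
            )
        )
        # one intermediate shell keeps the interior probe-tight
        if shell_r > 3.0:
            m = max(12, int(4 * np.pi * (shell_r / 2) ** 2 / 1.5))
            k = np.arange(m) + 0.5
            theta = np.arccos(1 - 2 * k / m)
            phi = np.pi * (1 + 5**0.5) * k
            pts.extend(
                center
                + (shell_r / 2)
                * np.stack(
                    [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
                    axis=1,
                )
            )
    return [
        AtomRecord(
            chain_id=chain,
            residue_number=i + 1,
            residue_name="BLB",
            atom_name=f"C{i+1}",
            element="C",
            occupancy=1.0,
            altloc="",
            position=np.asarray(p, dtype=float),
            mass=12.011,
        )
        for i, p in enumerate(pts)
    ]


def make_collision_scene(
    seed: int = 0,
    helix: HelixSpec | None = None,
    mobile_radius: float = 5.0,
    fixed_radius: float = 5.0,
    fixed_position: int = 30,
    mobile_position: int = 1,
) -> tuple[StructureModel, StructureModel, StructureModel]:
    """(mobile, fixed, dna): two pseudo-atom blobs anchored on an ideal helix.

    Blob centers sit on the helix axis at their base-pair positions, so the
    ground-truth center separation after n forward steps is
    ``(fixed_position - mobile_position - n) * rise`` and first surface
    contact occurs when that distance falls below the sum of blob radii.
    """
    helix = helix or HelixSpec(n_bp=max(50, fixed_position + 10), seed=seed)
    if not (1 <= fixed_position <= helix.n_bp):
        raise ValueError("fixed_position outside the helix")
    dna = make_bdna(helix)
    axis_at = lambda bp: np.array([0.0, 0.0, helix.rise * (bp - 1)])
    mobile = StructureModel(
        "mobile-blob", _blob("M", axis_at(mobile_position), mobile_radius)
    )
    fixed = StructureModel(
        "fixed-blob", _blob("F", axis_at(fixed_position), fixed_radius)
    )
    return mobile, fixed, dna


def make_template(
    seed: int = 0,
    length: int = 120,
    hairpin: bool = True,
    hairpin_start: int = 60,
    hairpin_len: int = 20,
) -> TemplateSpec:
    """Random convergent-template spec with independent forward/reverse RNAs."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    fwd = "".join(rng.choice(bases, size=length))
    rev = "".join(rng.choice(bases, size=length))
    region = (hairpin_start, hairpin_start + hairpin_len - 1) if hairpin else None
    return TemplateSpec(forward_rna=fwd, reverse_rna=rev, hairpin_region=region)


def simulate_reads(
    template: TemplateSpec,
    n: int = 200,
    end_model: Mapping | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
    read_length: int = 40,
    tss_jitter: int = 3,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Paired 5'/3' reads plus a truth table.

    ``end_model`` is a mapping: ``{"kind": "uniform", "min_len": a,
    "max_len": b}`` draws 3' ends uniformly; ``{"kind": "hairpin",
    "fraction": f, ...}`` piles that fraction of 3' ends at the hairpin
    boundary.  Returns ``(reads, truth)`` where reads are
    ``(read_id, five_read, three_read)`` and truth records orientation and
    true end coordinates.
    """
    if not (0.0 <= error_rate <= 0.2):
        raise ValueError("error_rate must be in [0, 0.2]")
    end_model = dict(end_model or {"kind": "uniform", "min_len": 30, "max_len": 100})
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    reads: list[tuple[str, str, str]] = []
    rows = []
    for i in range(n):
        orientation = "forward" if rng.random() < 0.5 else "reverse"
        rna = template.forward_rna if orientation == "forward" else template.reverse_rna
        tss = template.forward_tss if orientation == "forward" else template.reverse_tss
        five = int(tss + rng.integers(0, tss_jitter + 1))
        min_len = int(end_model.get("min_len", 30))
        max_len = int(min(end_model.get("max_len", 100), len(rna) - five + 1))
        if max_len <= min_len:
            max_len = min_len + 1
        if end_model["kind"] == "hairpin":
            if template.hairpin_region is None:
                raise ValueError("hairpin end model needs a hairpin region")
            if rng.random() < float(end_model.get("fraction", 0.8)):
                three = int(template.hairpin_region[0])
            else:
                three = five + int(rng.integers(min_len, max_len))
        elif end_model["kind"] == "uniform":
            three = five + int(rng.integers(min_len, max_len))
        else:
            raise ValueError(f"unknown end model {end_model['kind']!r}")
        three = min(three, len(rna))

        transcript = rna[five - 1 : three]
        five_read = transcript[:read_length]
        three_read = transcript[-read_length:]

        def mutate(seq: str) -> str:
            if error_rate == 0:
                return seq
            chars = list(seq)
            for j in range(len(chars)):
                if rng.random() < error_rate:
                    chars[j] = bases[
                        (bases.index(chars[j]) + int(rng.integers(1, 4))) % 4
                    ]
            return "".join(chars)

        read_id = f"read{i:05d}"
        reads.append((read_id, mutate(five_read), mutate(three_read)))
        rows.append(
            {
                "read_id": read_id,
                "orientation": orientation,
                "five_prime": five,
                "three_prime": three,
            }
        )
    return reads, pd.DataFrame(rows)


def simulate_decay(
    a1: float,
    k1: float,
    a2: float,
    k2: float,
    timepoints: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    no_ntp_control: float = 1000.0,
    pk_control: float = 100.0,
) -> DecayCurve:
    """Gel time course from a bi-exponential intact fraction plus noise."""
    if a1 < 0 or a2 < 0 or not (k1 >= k2 >= 0):
        raise ValueError("parameters must satisfy a1,a2 >= 0 and k1 >= k2 >= 0")
    t = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(seed)
    frac = a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)
    if noise_sd > 0:
        frac = frac + rng.normal(0.0, noise_sd, size=t.size)
    signal = pk_control + frac * (no_ntp_control - pk_control)
    return DecayCurve(
        timepoints=t,
        signal=signal,
        no_ntp_control=no_ntp_control,
        pk_control=pk_control,
    )


def simulate_titration(
    true_erb_by_salt: Mapping[float, float],
    intensity_scale: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    anchor_salt: float = 50.0,
    anchor_raw_ratio: float = 0.8,
    condition: str = "EcoRI*",
) -> TitrationSeries:
    """Gel lane intensities consistent with given per-salt E_RB values.

    With zero noise, :func:`rnapcollide.biochem.rescale_titration` recovers
    ``true_erb_by_salt`` exactly.  Noise is multiplicative on intensities.
    """
    if anchor_salt not in true_erb_by_salt:
        raise ValueError(f"anchor salt {anchor_salt} missing from input map")
    rng = np.random.default_rng(seed)
    background = 0.05 * intensity_scale
    lanes = []
    for salt, erb in true_erb_by_salt.items():
        scaffold = intensity_scale * (1.0 + (rng.normal(0, noise_sd) if noise_sd else 0.0))
        roadblock = background + erb * anchor_raw_ratio * (scaffold - background)
        if noise_sd:
            roadblock *= 1.0 + rng.normal(0, noise_sd)
        lanes.append(
            LaneQuant(
                condition=condition,
                salt_mM=float(salt),
                roadblock_intensity=float(max(roadblock, 0.0)),
                scaffold_intensity=float(max(scaffold, background + 1e-9)),
                background=float(background),
            )
        )
    return TitrationSeries(lanes=tuple(lanes), anchor_salt=anchor_salt)
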
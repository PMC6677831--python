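"""Cn-symmetric oligomer models and inter-protomer label distance classes.

For spin labels placed at equivalent sites on an n-fold symmetric ring of
radius R, the pairwise label-label distances fall into floor(n/2) chord
classes d_k = 2 R sin(k pi / n), k = 1..floor(n/2). A monomer yields no
distance, a trimer one class, a pentamer two, a hexamer three — the
geometric fingerprint that lets a single-site DEER experiment discriminate
oligomeric states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import Structure, ResidueMapping, superpose_structures

__all__ = [
    "RingAssembly",
    "DistanceClassSet",
    "build_ideal_ring",
    "distance_classes",
    "assemble_on_template",
    "label_site_coordinate",
    "interface_contacts",
]


@dataclass
class DistanceClassSet:
    """Merged pairwise label distances: list of (distance Å, multiplicity)."""

    classes: list[tuple[float, int]]

    @property
    def distances(self) -> list[float]:
        return [d for d, _ in self.classes]

    @property
    def total_pairs(self) -> int:
        return sum(m for _, m in self.classes)

    def __len__(self) -> int:
        return len(self.classes)


@dataclass
class RingAssembly:
    """An n-protomer Cn ring with a designated label site per protomer.

    ``protomer_transforms[k]`` is the (rotation, translation) pair carrying
    protomer 0 onto protomer k; for ideal rings it is the rotation by
    2 pi k / n about ``axis`` through ``center``.
    """

    n: int
    axis: np.ndarray
    center: np.ndarray
    label_sites: np.ndarray  # (n, 3)
    label_radius: float
    protomer_transforms: list[tuple[np.ndarray, np.ndarray]] = field(
        default_factory=list
    )


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    cc = 1.0 - c
    return np.array([
        [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
        [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
        [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
    ])


def build_ideal_ring(
    n: int,
    radius: float,
    axis=(0.0, 0.0, 1.0),
    center=(0.0, 0.0, 0.0),
) -> RingAssembly:
    """n label sites equally spaced on a circle of the given radius (Å)."""
    if n < 1:
        raise ValueError("protomer count must be >= 1")
    if radius <= 0:
        raise ValueError("label radius must be positive")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    center = np.asarray(center, dtype=float)
    # seed point: any unit vector perpendicular to the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ axis) * axis
    u /= np.linalg.norm(u)
    site0 = center + radius * u
    transforms = []
    sites = np.empty((n, 3))
    for k in range(n):
        rot = _rotation_about_axis(axis, 2.0 * np.pi * k / n)
        trans = center - rot @ center
        transforms.append((rot, trans))
        sites[k] = rot @ site0 + trans
    return RingAssembly(n, axis, center, sites, float(radius), transforms)


def distance_classes(assembly: RingAssembly, merge_tol: float = 0.01) -> DistanceClassSet:
    """All n(n-1)/2 pairwise label distances merged into classes.

    Distances closer than ``merge_tol`` (Å) fall into one class reported at
    their mean. For an ideal ring this yields floor(n/2) classes with
    multiplicity n (k < n/2) and n/2 (k = n/2, n even).
    """
    if merge_tol <= 0:
        raise ValueError("merge_tol must be positive")
    return pairwise_distance_classes(assembly.label_sites, merge_tol)


def pairwise_distance_classes(points: np.ndarray, merge_tol: float) -> DistanceClassSet:
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    dists = sorted(
        float(np.linalg.norm(pts[i] - pts[j]))
        for i in range(n)
        for j in range(i + 1, n)
    )
    classes: list[tuple[float, int]] = []
    bucket: list[float] = []
    for d in dists:
        if bucket and d - bucket[0] > merge_tol:
            classes.append((float(np.mean(bucket)), len(bucket)))
            bucket = []
        bucket.append(d)
    if bucket:
        classes.append((float(np.mean(bucket)), len(bucket)))
    return DistanceClassSet(classes)


def label_site_coordinate(s: Structure, chain: str, residue: int) -> np.ndarray:
    """CA position of the labeled residue (point-label approximation).

    A nitroxide side chain places the unpaired electron ~2-4 Å off the
    backbone; downstream matching tolerances absorb that offset.
    """
    return s.atom_coord(chain, residue, "CA")


_CHAIN_NAMES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def assemble_on_template(
    monomer: Structure,
    template: Structure,
    mappings: dict[str, ResidueMapping] | ResidueMapping,
    monomer_chain: str | None = None,
    atom_set: str = "CA",
) -> tuple[Structure, dict[str, float]]:
    """Place one copy of ``monomer`` on every polymer chain of ``template``.

    Each copy is superposed (iterative Kabsch) onto its template chain; the
    returned assembly carries the copies as chains A, B, C, ... together
    with the per-chain superposition RMSD.
    """
    import biotite.structure as bst

    template_chains = [
        c for c in template.chain_ids if (~template.chain(c).atoms.hetero).any()
    ]
    if len(template_chains) < 2:
        raise ValueError("template must have at least 2 polymer chains")
    if monomer_chain is None:
        monomer_chain = monomer.chain_ids[0]
    parts, rmsds = [], {}
    for out_id, tch in zip(_CHAIN_NAMES, template_chains):
        if isinstance(mappings, ResidueMapping):
            mapping = ResidueMapping([
                ((ca, ra), (tch, rb)) for (ca, ra), (_, rb) in mappings.pairs
            ])
        else:
            mapping = mappings[tch]
        try:
            fit = superpose_structures(monomer, template.chain(tch), mapping, atom_set)
        except ValueError as exc:
            raise ValueError(f"superposition failed on chain {tch}: {exc}") from exc
        placed = monomer.transformed(fit.rotation, fit.translation).atoms.copy()
        placed.chain_id = np.full(placed.array_length(), out_id)
        parts.append(placed)
        rmsds[out_id] = fit.rmsd
    merged = parts[0]
    for p in parts[1:]:
        merged = merged + p
    return Structure(f"{monomer.id}_x{len(parts)}", merged), rmsds


def assembly_label_classes(
    assembly: Structure, label_residue: int, merge_tol: float = 1.0
) -> DistanceClassSet:
    """Distance classes between the label CA sites of every chain.

    Template-derived assemblies are not exactly symmetric, hence the looser
    default merge tolerance (1 Å) than for ideal rings.
    """
    sites = np.array([
        label_site_coordinate(assembly, c, label_residue)
        for c in assembly.chain_ids
    ])
    return pairwise_distance_classes(sites, merge_tol)


def interface_contacts(
    assembly: Structure, chain_a: str, chain_b: str, cutoff: float = 4.5
):
    """Residue pairs with any interatomic distance < cutoff across two chains."""
    a = assembly.chain(chain_a).atoms
    b = assembly.chain(chain_b).atoms
    tree = cKDTree(b.coord)
    pairs = set()
    for i, hits in enumerate(tree.query_ball_point(a.coord, cutoff)):
        for j in hits:
            pairs.add((
                (chain_a, int(a.res_id[i]), str(a.res_name[i])),
                (chain_b, int(b.res_id[j]), str(b.res_name[j])),
            ))
    return sorted(pairs)
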
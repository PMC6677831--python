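"""Structural determinants of rhodopsin oligomerization propensity.

Three features separate the oligomerization classes of light-driven
bacterial pumps:

* the 3-omega motif — a pi-stacked triad of aromatic side chains, one each
  from helix A, helix B and the B-C loop, tethering the loop outward;
* B-C loop orientation — whether the loop tip points over the helical
  bundle (inward, BR-like) or toward the periphery (flipped, XR-like);
* extension of the interface helices A, B and G relative to a reference.

Group 1 (no extension) covers the exclusively trimer-forming rhodopsins;
group 2 (extension only) the proteorhodopsin-like pentamer/hexamer
formers; group 3 (extension + 3-omega + flipped loop) the XR-type
pentamer formers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import Structure, map_chains, superpose_structures

__all__ = [
    "HelixAnnotation",
    "MotifReport",
    "detect_3omega",
    "bc_loop_orientation",
    "helix_extension",
    "assign_group",
]

_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass
class HelixAnnotation:
    """One transmembrane helix: id 'A'..'G', chain, inclusive residue range."""

    helix_id: str
    chain: str
    first: int
    last: int

    def __post_init__(self) -> None:
        if self.first >= self.last:
            raise ValueError(f"helix {self.helix_id}: first must be < last")

    def residues(self) -> range:
        return range(self.first, self.last + 1)


@dataclass
class MotifReport:
    three_omega: bool = False
    triad: tuple | None = None  # ((chain, res, name) x3)
    triad_distances: tuple[float, float, float] | None = None
    bc_loop: str | None = None  # "inward" | "flipped"
    bc_loop_margin: float | None = None  # tip radius minus bundle radius, Å
    helix_extension_A: float | None = None
    helix_extension_B: float | None = None
    helix_extension_G: float | None = None
    extended_helices: bool | None = None
    group: str | None = None


def _helix(helices: list[HelixAnnotation], helix_id: str) -> HelixAnnotation:
    for h in helices:
        if h.helix_id == helix_id:
            return h
    raise ValueError(f"helix {helix_id} not annotated")


def _ring_centroid(s: Structure, chain: str, res_id: int) -> np.ndarray | None:
    a = s.atoms
    mask = (a.chain_id == chain) & (a.res_id == res_id)
    if not mask.any():
        return None
    res_name = str(a.res_name[np.flatnonzero(mask)[0]])
    names = _RING_ATOMS.get(res_name)
    if names is None:
        return None
    coords = []
    for nm in names:
        hit = mask & (a.atom_name == nm)
        if not hit.any():
            return None  # incomplete ring: skip residue
        coords.append(a.coord[np.flatnonzero(hit)[0]])
    return np.mean(coords, axis=0)


def _aromatics_in_range(s: Structure, chain: str, residues) -> list[tuple[int, np.ndarray]]:
    a = s.atoms
    out = []
    for r in residues:
        mask = (a.chain_id == chain) & (a.res_id == r) & (a.atom_name == "CA")
        if not mask.any():
            continue
        if str(a.res_name[np.flatnonzero(mask)[0]]) not in _RING_ATOMS:
            continue
        cen = _ring_centroid(s, chain, r)
        if cen is not None:
            out.append((r, cen))
    return out


def detect_3omega(
    s: Structure,
    helices: list[HelixAnnotation],
    centroid_cutoff: float = 7.0,
) -> MotifReport:
    """Search for the aromatic helix-A / helix-B / B-C-loop triad.

    All three pairwise ring-centroid distances must be within
    ``centroid_cutoff`` (7 Å default covers offset pi-stacking); the triad
    with the smallest distance sum is reported.
    """
    ha, hb, hc = (_helix(helices, i) for i in "ABC")
    loop = range(hb.last + 1, hc.first)
    cands = {
        "A": _aromatics_in_range(s, ha.chain, ha.residues()),
        "B": _aromatics_in_range(s, hb.chain, hb.residues()),
        "loop": _aromatics_in_range(s, hb.chain, loop),
    }
    best = None
    for ra, ca in cands["A"]:
        for rb, cb in cands["B"]:
            for rl, cl in cands["loop"]:
                d = (
                    float(np.linalg.norm(ca - cb)),
                    float(np.linalg.norm(cb - cl)),
                    float(np.linalg.norm(ca - cl)),
                )
                if max(d) > centroid_cutoff:
                    continue
                if best is None or sum(d) < sum(best[1]):
                    best = (((ha.chain, ra), (hb.chain, rb), (hb.chain, rl)), d)
    report = MotifReport()
    if best is not None:
        report.three_omega = True
        report.triad, report.triad_distances = best
    return report


def _bundle_frame(s: Structure, helices: list[HelixAnnotation]):
    """Principal axis and centroid of all helix CA atoms."""
    coords = np.vstack([
        s.ca_coords(h.chain, [r for r in h.residues() if _has_ca(s, h.chain, r)])
        for h in helices
    ])
    center = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - center)
    axis = vt[0]
    return center, axis, coords


def _has_ca(s: Structure, chain: str, res_id: int) -> bool:
    a = s.atoms
    return bool(((a.chain_id == chain) & (a.res_id == res_id) & (a.atom_name == "CA")).any())


def bc_loop_orientation(
    s: Structure,
    helices: list[HelixAnnotation],
    radial_margin: float = 2.0,
) -> tuple[str, float]:
    """Classify the B-C loop tip as "inward" or "flipped".

    The tip (loop midpoint CA) is compared radially, about the bundle
    principal axis, with helix CA atoms at the same axial height; "flipped"
    if the tip lies more than ``radial_margin`` Å outside that local bundle
    radius. Returns (orientation, margin).
    """
    hb, hc = _helix(helices, "B"), _helix(helices, "C")
    loop = [r for r in range(hb.last + 1, hc.first) if _has_ca(s, hb.chain, r)]
    if len(loop) < 3:
        raise ValueError("B-C loop must have at least 3 residues")
    tip_res = loop[len(loop) // 2]
    tip = s.atom_coord(hb.chain, tip_res, "CA")
    center, axis, helix_coords = _bundle_frame(s, helices)

    def radial_and_axial(points):
        rel = np.atleast_2d(points) - center
        h = rel @ axis
        rad = np.linalg.norm(rel - np.outer(h, axis), axis=1)
        return rad, h

    tip_rad, tip_h = radial_and_axial(tip)
    rads, hs = radial_and_axial(helix_coords)
    nearby = np.abs(hs - tip_h[0]) < 5.0
    bundle_radius = float(rads[nearby].mean()) if nearby.any() else float(rads.mean())
    margin = float(tip_rad[0] - bundle_radius)
    return ("flipped" if margin >= radial_margin else "inward"), margin


def helix_extension(
    s: Structure,
    helices: list[HelixAnnotation],
    reference: Structure,
    ref_helices: list[HelixAnnotation],
    helix_ids: tuple[str, ...] = ("A", "B", "G"),
) -> dict[str, float]:
    """Axial-extent difference (Å) of each helix versus the reference.

    The mobile structure is superposed onto the reference over an
    alignment-derived CA mapping; each helix's extent is the span of its CA
    projections onto the reference bundle axis, and the extension is the
    mobile extent minus the reference extent.
    """
    for hid in helix_ids:
        _helix(helices, hid), _helix(ref_helices, hid)
    chain = _helix(helices, helix_ids[0]).chain
    ref_chain = _helix(ref_helices, helix_ids[0]).chain
    mapping = map_chains(s, chain, reference, ref_chain)
    fit = superpose_structures(s, reference, mapping, atom_set="CA")
    moved = s.transformed(fit.rotation, fit.translation)
    _, axis, _ = _bundle_frame(reference, ref_helices)

    def extent(struct: Structure, h: HelixAnnotation) -> float:
        res = [r for r in h.residues() if _has_ca(struct, h.chain, r)]
        proj = struct.ca_coords(h.chain, res) @ axis
        return float(proj.max() - proj.min())

    return {
        hid: extent(moved, _helix(helices, hid))
        - extent(reference, _helix(ref_helices, hid))
        for hid in helix_ids
    }


def assign_group(report: MotifReport) -> str:
    """Map the three binary features to oligomerization group 1, 2 or 3.

    extension / 3-omega / flipped loop ->
      no extension, no motif        -> "1" (trimer formers)
      extension, no motif           -> "2" (proteorhodopsin-like)
      extension, motif, flipped     -> "3" (XR-type)
      motif without extension, or motif without the flipped loop
                                    -> "unclassified" (contradictory: the
                                       motif sits on the extended segments
                                       and tethers the loop outward)
    """
    for name in ("extended_helices", "three_omega", "bc_loop"):
        if getattr(report, name) is None:
            raise ValueError(f"feature {name} not computed")
    ext = bool(report.extended_helices)
    motif = bool(report.three_omega)
    flipped = report.bc_loop == "flipped"
    if motif and not (ext and flipped):
        return "unclassified"
    if not ext:
        return "1"
    if not motif:
        return "2"
    return "3"
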
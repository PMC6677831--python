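"""Synthetic fixtures for every pipeline stage.

Generates (a) toy seven-helix bundle structures with a designated label
residue on the cytoplasmic A-B loop, an inward or flipped B-C loop, and
optionally extended interface helices and an aromatic pi-stacking triad;
(b) Cn ring assemblies of a monomer with a chosen label-site radius;
(c) DEER datasets with known multi-Gaussian ground truth; and (d) protein
families evolved by uniform (Poisson-model) substitution along a known
tree. All generators are deterministic under an explicit seed.

The toy bundles use ideal alpha-helix CA geometry (2.3 Å helical radius,
100 deg twist and 1.5 Å rise per residue) with CB stubs, so structural
detectors can run on them; they do not emulate side-chain packing, real
loop conformations, or a membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
import dendropy

from .structio import Structure
from .motif_analysis import HelixAnnotation
from .deer_forward import (
    DeerTrace,
    DistanceDistribution,
    add_noise,
    apply_background,
    default_r_grid,
    default_t_grid,
    simulate_form_factor,
)
from .phylo import AlignedSequences

__all__ = [
    "ToyBundleSpec",
    "ToyBundle",
    "DeerDatasetSpec",
    "make_toy_bundle",
    "make_ring_assembly",
    "ring_deer_spec",
    "make_deer_dataset",
    "evolve_sequences",
    "random_additive_tree",
]

_RISE = 1.5  # Å per residue along the helix axis
_TWIST = np.deg2rad(100.0)  # per residue
_CA_RADIUS = 2.3  # Å, CA helical radius

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET",
    "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER",
    "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR", "H": "HIS",
}
# random toy sequences avoid aromatics so the only pi-stacking triad is the
# one placed deliberately
_TOY_ALPHABET = "ACDEGIKLMNQRSTV"


@dataclass
class ToyBundleSpec:
    n_helices: int = 7
    helix_length: int = 22  # residues
    bundle_radius: float = 11.0  # Å, helix axes from bundle axis
    loop_tip: str = "inward"  # B-C loop: "inward" | "flipped"
    extend_helices: bool = False  # elongate helices A, B, G
    extension_residues: int = 7  # ~2 ideal turns, 10.5 Å of rise
    aromatic_triad: bool = False  # place the helixA/helixB/loop triad
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loop_tip not in ("inward", "flipped"):
            raise ValueError("loop_tip must be 'inward' or 'flipped'")
        axis_gap = 2.0 * self.bundle_radius * np.sin(np.pi / self.n_helices)
        if axis_gap < 2.0 * (_CA_RADIUS + 0.5):
            raise ValueError("bundle radius too small: helices overlap")


@dataclass
class ToyBundle:
    structure: Structure
    helices: list[HelixAnnotation]
    label_chain: str
    label_residue: int  # on the cytoplasmic A-B loop
    triad_residues: tuple[int, int, int] | None = None


def _helix_ca_trace(
    center_xy: np.ndarray, z0: float, direction: float, n_res: int, phase: float
) -> np.ndarray:
    """Ideal helix CA coordinates, axis vertical through center_xy."""
    i = np.arange(n_res)
    ang = phase + direction * _TWIST * i
    z = z0 + direction * _RISE * i
    return np.column_stack([
        center_xy[0] + _CA_RADIUS * np.cos(ang),
        center_xy[1] + _CA_RADIUS * np.sin(ang),
        z,
    ])


def _arc(p0: np.ndarray, p1: np.ndarray, n: int, bulge: np.ndarray) -> np.ndarray:
    """n interior CA points between p0 and p1, bowed along ``bulge``."""
    ts = np.linspace(0.0, 1.0, n + 2)[1:-1]
    pts = np.outer(1 - ts, p0) + np.outer(ts, p1)
    return pts + np.outer(np.sin(np.pi * ts), bulge)


def _hexagon(center: np.ndarray, normal: np.ndarray, radius: float = 1.4) -> np.ndarray:
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ normal) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = np.linspace(0, 2 * np.pi, 7)[:-1]
    return center + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


_RING_NAMES = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}


def make_toy_bundle(spec: ToyBundleSpec) -> ToyBundle:
    """Build a deterministic toy TM bundle satisfying the structure invariants."""
    rng = np.random.default_rng(spec.seed)
    nh = spec.n_helices
    helix_ids = [chr(ord("A") + i) for i in range(nh)]
    extended = {"A", "B", "G"} if spec.extend_helices else set()

    # per-helix CA traces; helix i alternates direction, A runs
    # extracellular (-z) to cytoplasmic (+z)
    half = 0.5 * _RISE * (spec.helix_length - 1)
    traces: dict[str, np.ndarray] = {}
    for i, hid in enumerate(helix_ids):
        ang = 2 * np.pi * i / nh
        cxy = spec.bundle_radius * np.array([np.cos(ang), np.sin(ang)])
        n_res = spec.helix_length + (
            spec.extension_residues if hid in extended else 0
        )
        direction = 1.0 if i % 2 == 0 else -1.0
        z0 = -half if direction > 0 else half
        traces[hid] = _helix_ca_trace(cxy, z0, direction, n_res, phase=0.7 * i)

    # assemble chain: helix A, A-B loop (label), helix B, B-C loop, C, ...
    residues: list[tuple[int, str, dict[str, np.ndarray]]] = []
    helices: list[HelixAnnotation] = []
    res_id = 0
    label_residue = None

    def add_residue(name: str, atoms: dict[str, np.ndarray]) -> int:
        nonlocal res_id
        res_id += 1
        residues.append((res_id, name, atoms))
        return res_id

    def random_name() -> str:
        return _ONE_TO_THREE[_TOY_ALPHABET[rng.integers(len(_TOY_ALPHABET))]]

    def ca_cb(ca: np.ndarray, name: str) -> dict[str, np.ndarray]:
        atoms = {"CA": ca}
        if name != "GLY":
            out = ca[:2] / max(np.linalg.norm(ca[:2]), 1e-6)
            atoms["CB"] = ca + 1.53 * np.array([out[0], out[1], 0.0])
        return atoms

    for i, hid in enumerate(helix_ids):
        first = None
        for ca in traces[hid]:
            name = random_name()
            rid = add_residue(name, ca_cb(ca, name))
            first = first or rid
        helices.append(HelixAnnotation(hid, "A", first, res_id))
        if i == len(helix_ids) - 1:
            break
        # loop to the next helix
        p0, p1 = traces[hid][-1], traces[helix_ids[i + 1]][0]
        cytoplasmic = p0[2] > 0
        n_loop = 3 if hid == "A" else 5 if hid == "B" else 3
        bulge = np.array([0.0, 0.0, 3.0 if cytoplasmic else -3.0])
        pts = _arc(p0, p1, n_loop, bulge)
        if hid == "B":
            # B-C loop: place the tip radially per the requested orientation
            tip = pts[len(pts) // 2].copy()
            tip_radius = 2.0 if spec.loop_tip == "inward" else spec.bundle_radius + 8.0
            xy = tip[:2]
            xy_dir = xy / max(np.linalg.norm(xy), 1e-6)
            pts[len(pts) // 2, :2] = tip_radius * xy_dir
        for j, ca in enumerate(pts):
            if hid == "A" and j == len(pts) // 2:
                label_residue = add_residue("GLY", {"CA": ca})
            else:
                name = random_name()
                add_residue(name, ca_cb(ca, name))

    triad = None
    if spec.aromatic_triad:
        triad = _place_triad(residues, helices, spec)

    structure = _residues_to_structure(residues, "toy_bundle")
    return ToyBundle(structure, helices, "A", label_residue, triad)


def _place_triad(residues, helices, spec: ToyBundleSpec):
    """Turn one helix-A, one helix-B and one B-C-loop residue into an
    aromatic with ring atoms whose centroids sit mutually ~5 Å apart."""
    by_id = {rid: k for k, (rid, _, _) in enumerate(residues)}
    ha = next(h for h in helices if h.helix_id == "A")
    hb = next(h for h in helices if h.helix_id == "B")
    hc = next(h for h in helices if h.helix_id == "C")
    # extracellular ends: helix A starts there, helix B ends there
    res_a = ha.first + 1
    res_b = hb.last - 1
    res_loop = (hb.last + 1 + hc.first - 1) // 2 + 1  # a loop residue off the tip
    ca_a = residues[by_id[res_a]][2]["CA"]
    ca_b = residues[by_id[res_b]][2]["CA"]
    mid = 0.5 * (ca_a + ca_b) + np.array([0.0, 0.0, -2.0])
    centroids = {
        res_a: mid + np.array([2.5, 0.0, 0.0]),
        res_b: mid + np.array([-2.5, 0.0, 0.0]),
        res_loop: mid + np.array([0.0, 0.0, -4.0]),
    }
    names = {res_a: "PHE", res_b: "TRP", res_loop: "TYR"}
    for rid, cen in centroids.items():
        k = by_id[rid]
        old_id, _, atoms = residues[k]
        name = names[rid]
        ring = _hexagon(cen, np.array([0.0, 0.0, 1.0]))
        new_atoms = {"CA": atoms["CA"]}
        ring_names = _RING_NAMES[name]
        for j, nm in enumerate(ring_names):
            new_atoms[nm] = ring[j % 6] + (
                np.array([0.0, 0.0, 0.3]) if j >= 6 else 0.0
            )
        residues[k] = (old_id, name, new_atoms)
    return (res_a, res_b, res_loop)


def _residues_to_structure(residues, struct_id: str, chain: str = "A") -> Structure:
    n_atoms = sum(len(atoms) for _, _, atoms in residues)
    arr = bst.AtomArray(n_atoms)
    coords = np.empty((n_atoms, 3))
    k = 0
    for rid, name, atoms in residues:
        for atom_name, xyz in atoms.items():
            arr.chain_id[k] = chain
            arr.res_id[k] = rid
            arr.res_name[k] = name
            arr.atom_name[k] = atom_name
            arr.element[k] = atom_name[0]
            arr.hetero[k] = False
            coords[k] = xyz
            k += 1
    arr.coord = coords
    arr.set_annotation("occupancy", np.ones(n_atoms))
    return Structure(struct_id, arr)


_CHAIN_NAMES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def make_ring_assembly(
    monomer: Structure,
    n: int,
    radius: float,
    label_chain: str = "A",
    label_residue: int | None = None,
    seed: int = 0,
    jitter: float = 0.0,
) -> Structure:
    """Cn ring of ``n`` monomer copies with the label CA at the given radius.

    The monomer is translated so its label site sits at (radius, 0, 0) and
    replicated by rotations of 2 pi k / n about z. ``jitter`` displaces each
    copy rigidly by an isotropic Gaussian translation (Å), emulating an
    imperfectly symmetric assembly while keeping protomers intact.
    """
    if n < 2:
        raise ValueError("ring needs n >= 2 protomers")
    if label_residue is None:
        raise ValueError("label_residue is required")
    rng = np.random.default_rng(seed)
    site = monomer.atom_coord(label_chain, label_residue, "CA")
    shift = np.array([radius, 0.0, 0.0]) - site
    base = monomer.atoms.copy()
    base.coord = base.coord + shift
    parts = []
    for k in range(n):
        ang = 2 * np.pi * k / n
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        copy = base.copy()
        copy.coord = base.coord @ rot.T
        if jitter > 0:
            copy.coord = copy.coord + rng.normal(0.0, jitter, 3)
        copy.chain_id = np.full(copy.array_length(), _CHAIN_NAMES[k])
        parts.append(copy)
    merged = parts[0]
    for p in parts[1:]:
        merged = merged + p
    return Structure(f"{monomer.id}_ring{n}", merged)


@dataclass
class DeerDatasetSpec:
    """Ground truth and acquisition settings for a synthetic DEER trace."""

    components: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(19.0, 1.5, 0.5), (29.0, 1.5, 0.5)]
    )
    modulation_depth: float = 0.3
    background_rate: float = 0.05  # µs^-1
    t_max: float = 2.5  # µs
    t_step: float = 0.008  # µs (8 ns)
    snr: float = 50.0  # inf for noiseless
    seed: int = 1
    r_step: float = 0.5  # Å

    def __post_init__(self) -> None:
        w = sum(w for _, _, w in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")


def ring_deer_spec(
    n: int,
    radius: float,
    seed: int = 1,
    sigma: float = 1.0,
    snr: float = 50.0,
) -> DeerDatasetSpec:
    """Dataset spec whose ground truth is an ideal Cn ring's chord classes.

    Each chord class becomes a Gaussian weighted by its pair multiplicity.
    sigma defaults to 1 Å — the coordinate-spread scale of label points on
    a rigid assembly — narrower than the 1.5 Å used for experimental-peak
    emulation, where label rotamer disorder dominates.
    """
    from .oligomer_geometry import build_ideal_ring, distance_classes

    classes = distance_classes(build_ideal_ring(n, radius))
    total = classes.total_pairs
    comps = [(d, sigma, m / total) for d, m in classes.classes]
    return DeerDatasetSpec(components=comps, snr=snr, seed=seed)


def make_deer_dataset(spec: DeerDatasetSpec) -> tuple[DeerTrace, DistanceDistribution]:
    """Noisy trace plus its ground-truth distribution for recovery tests."""
    r = default_r_grid(spec.r_step)
    truth = DistanceDistribution.from_gaussians(r, spec.components)
    t = default_t_grid(spec.t_max, spec.t_step)
    trace = simulate_form_factor(truth, t, spec.modulation_depth)
    trace = apply_background(trace, spec.background_rate)
    if np.isfinite(spec.snr):
        trace = add_noise(trace, spec.snr, spec.seed)
    return trace, truth


def evolve_sequences(
    tree: dendropy.Tree, root_length: int, seed: int
) -> AlignedSequences:
    """Evolve a gap-free protein family along a tree with branch lengths in
    substitutions/site, under uniform substitution over the 20 amino acids
    (the model whose pairwise distances the Poisson correction inverts)."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    root_seq = rng.integers(0, 20, size=root_length)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    names, rows = [], []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            seq = root_seq
        else:
            parent_seq = seqs[id(node.parent_node)]
            b = node.edge.length or 0.0
            seq = parent_seq.copy()
            n_subs = rng.poisson(b, size=root_length)
            for site in np.flatnonzero(n_subs):
                for _ in range(n_subs[site]):
                    # jump to a uniformly random different residue
                    seq[site] = (seq[site] + 1 + rng.integers(19)) % 20
            seqs[id(node)] = seq
        if node.is_leaf():
            names.append(node.taxon.label if node.taxon else f"leaf{len(names)}")
            rows.append("".join(alphabet[seq]))
    return AlignedSequences(names, rows)


def random_additive_tree(
    n_leaves: int, seed: int, min_branch: float = 0.1, max_branch: float = 1.0
) -> dendropy.Tree:
    """Random unrooted binary tree with branch lengths uniform in
    [min_branch, max_branch]; its path-length matrix is exactly additive."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"T{i}" for i in range(n_leaves)])
    tree = dendropy.Tree(taxon_namespace=taxa)

    def blen() -> float:
        return float(rng.uniform(min_branch, max_branch))

    # start from a 3-leaf star, then split random edges
    tree.seed_node.taxon = None
    leaves = []
    for i in range(3):
        nd = dendropy.Node(taxon=taxa.get_taxon(f"T{i}"))
        nd.edge.length = blen()
        tree.seed_node.add_child(nd)
        leaves.append(nd)
    for i in range(3, n_leaves):
        edges = [
            nd.edge for nd in tree.preorder_node_iter() if nd is not tree.seed_node
        ]
        edge = edges[rng.integers(len(edges))]
        child = edge.head_node
        parent = child.parent_node
        mid = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(mid)
        split = rng.uniform(0.2, 0.8) * edge.length
        mid.edge.length = edge.length - split
        mid.add_child(child)
        child.edge.length = split
        leaf = dendropy.Node(taxon=taxa.get_taxon(f"T{i}"))
        leaf.edge.length = blen()
        mid.add_child(leaf)
    return tree
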
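# oligodeer

Determining the oligomeric state of a membrane protein from pulsed-EPR
distance measurements, ring geometry, structural motifs and sequence
phylogenetics.

Many microbial rhodopsins — seven-transmembrane, retinal-binding light-driven
pumps — assemble into homo-oligomers (trimers like bacteriorhodopsin,
pentamers like KR2, hexamers like blue proteorhodopsin), and the oligomeric
state can switch with conditions such as pH. A single spin label placed at an
equivalent site on every protomer turns the question "how many protomers?"
into a geometry problem: for labels on a Cn-symmetric ring of radius *R*, the
pairwise label–label distances fall into ⌊n/2⌋ chord classes

&nbsp;&nbsp;&nbsp;&nbsp;d&#8342; = 2 R sin(kπ/n),&nbsp;&nbsp;k = 1 … ⌊n/2⌋,

so a monomer gives no intermolecular distance, a trimer one class, a pentamer
two, a hexamer three. Double electron–electron resonance (DEER/PELDOR)
measures these distances as a distribution P(r) recovered from the dipolar
evolution signal

&nbsp;&nbsp;&nbsp;&nbsp;V(t) = (1 − λ + λ ∫ K(t, r) P(r) dr) · e<sup>−k·t</sup>,
&nbsp;&nbsp;&nbsp;&nbsp;K(t, r) = ∫₀¹ cos((3u² − 1)·2π·ν(r)·t) du,
&nbsp;&nbsp;&nbsp;&nbsp;ν(r) = 52.04 MHz·nm³ / r³,

an ill-posed inversion solved here by non-negative Tikhonov regularization.
Matching the recovered peak positions against each candidate's predicted
chord set (exact minimum-cost assignment plus a penalty for unexplained
peaks) decides the oligomeric state. For *Gloeobacter* rhodopsin labeled on
the A–B loop, two peaks at 19 and 29 Å match the pentamer prediction
(~18 and ~29 Å) and reject trimer (~37 Å) and hexamer (~16/28/31 Å).

The package covers the full workflow:

| module | what it does |
| --- | --- |
| `structio` | PDB read/write, sequence-alignment residue mapping, Kabsch superposition with outlier rejection, polar contacts |
| `oligomer_geometry` | ideal Cn label rings, chord distance classes, template-based oligomer assembly, interface contacts |
| `deer_forward` | dipolar kernel (Fresnel closed form), form-factor simulation, background, noise |
| `deer_inverse` | background correction, non-negative Tikhonov inversion, GCV / L-curve regularization selection, peak extraction |
| `classifier` | peak-to-prediction assignment costs and oligomer ranking |
| `motif_analysis` | 3-omega aromatic triad, B-C loop orientation, helix extension, oligomerization group 1/2/3 |
| `phylo` | Poisson-corrected distances, Neighbor-Joining, Newick I/O |
| `synthetic_data` | toy 7-TM bundles, Cn assemblies, DEER datasets with known truth, evolved sequence families |
| `cli` | `oligodeer` command-line entry point |

## Worked example

```python
from oligodeer.oligomer_geometry import build_ideal_ring, distance_classes
from oligodeer.synthetic_data import DeerDatasetSpec, make_deer_dataset
from oligodeer.deer_inverse import invert_trace
from oligodeer.classifier import classify

# predicted chord classes for the three candidate ring geometries
for name, n, R in [("trimer", 3, 21.36), ("pentamer", 5, 15.31), ("hexamer", 6, 16.0)]:
    cl = distance_classes(build_ideal_ring(n, R))
    print(name, [(round(d, 1), m) for d, m in cl.classes])

# a synthetic DEER experiment at the measured peak positions
trace, truth = make_deer_dataset(DeerDatasetSpec(seed=1))
res = invert_trace(trace)
print("k_bg = %.4f, lambda = %.4f" % (res["k_bg"], res["modulation_depth"]))
print("peaks:", [round(p.position, 1) for p in res["peaks"]])

report = classify([p.position for p in res["peaks"]])
for cand, match in report.ranking:
    print("%-9s n=%d cost=%.2f" % (cand.label, cand.n, match.cost))
```

prints

```
trimer [(37.0, 3)]
pentamer [(18.0, 5), (29.1, 5)]
hexamer [(16.0, 6), (27.7, 6), (32.0, 3)]
k_bg = 0.0476, lambda = 0.3043
peaks: [19.0, 29.0]
pentamer  n=5 cost=1.12
hexamer   n=6 cost=14.29
trimer    n=3 cost=18.00
monomer   n=1 cost=20.00
```

The chord classes are the theoretical distance sets for each oligomer. The
simulated trace (modulation depth 0.3, background 0.05 µs⁻¹, SNR 50) is
background-corrected — the fitted rate and depth land on the ground truth —
and inverted; the recovered peaks sit at 19 and 29 Å. The assignment cost is
the summed |observed − predicted| over matched peaks plus 10 Å per
unexplained peak or unexplained in-window prediction, so the pentamer wins
by an order of magnitude.

The same steps are available from the shell:

```sh
oligodeer predict-distances --n 5 --radius 15.31
oligodeer simulate-deer --seed 1 --out trace.tsv
oligodeer invert-deer --trace trace.tsv --alpha auto
oligodeer classify --peaks 19,29
```

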
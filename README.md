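# aspholib

Atom-specific persistent homology (ASPH) features for protein
flexibility analysis and C&alpha; B-factor prediction.

## The problem

The crystallographic B-factor (Debye&ndash;Waller factor) of an atom
measures how much thermal motion attenuates its X-ray scattering, and is
the standard per-atom proxy for protein flexibility.  Persistent
homology summarises the multi-scale topology (components, loops,
cavities) of an atom cloud, but is inherently *global*: on its own it
says nothing about an individual atom.  ASPH localises it.  For a
C&alpha; atom *i* and an element-specific atom subset
P<sub>k</sub> &isin; {CC, CN, CO}, take every subset atom strictly
within a cutoff r<sub>c</sub> = 11 &Aring; of the centre:

&nbsp;&nbsp;R<sub>ik</sub> = { r<sub>jk</sub> : &Vert;r<sub>ik</sub> &minus; r<sub>jk</sub>&Vert; &lt; r<sub>c</sub> },

and its *conjugated* cloud R&#770;<sub>ik</sub> = R<sub>ik</sub> &#8726; {r<sub>ik</sub>}.
Both clouds are filtered with a Vietoris&ndash;Rips complex, either over
Euclidean distances or over the correlation-kernel filtration matrix

&nbsp;&nbsp;M<sub>nm</sub> = 1 &minus; &Phi;(&Vert;r<sub>n</sub> &minus; r<sub>m</sub>&Vert;; &eta;, &kappa;)

with exponential &Phi; = exp(&minus;(d/&eta;)<sup>&kappa;</sup>) or Lorentz
&Phi; = 1/(1 + (d/&eta;)<sup>&nu;</sup>) kernels.  The Bottleneck or
Wasserstein distance between the two conjugated persistence diagrams
(dimension 0 or 1) is a scalar signature of the centre atom; sweeping
kernels, diagram-plane transforms, metrics, dimensions and element pairs
yields a 60-component feature vector per C&alpha;, plus an (8, 10, 3)
multiscale "persistence image" tensor over a grid of
&eta; &isin; {1,&hellip;,5,10,15,20} and &kappa; &isin; {1,&hellip;,10}.
These features feed per-protein linear least-squares fitting, a
gradient-boosted tree regressor, a small convolutional network, and a
consensus of the two, evaluated by the Pearson correlation between
predicted and experimental B-factors under leave-one-protein-out
cross-validation.

The package is aimed at structural bioinformaticians who want per-atom
topological descriptors from PDB files, and includes a synthetic-data
module (manifold samples with known Betti numbers, pseudo-proteins with
recoverable B-factor laws) so every stage is testable without any
download.

## Worked example

```python
import aspholib as al

protein = al.make_pseudo_protein(12, seed=0)   # synthetic 12-residue chain
s = protein.structure
ca = s.calphas[5]                              # C-alpha of residue 6

vec = al.topo_feature_vector(s, ca)            # the 60 ASPH features
print(vec.shape)                               # (60,)
print(al.packing_density(s, ca))               # 21 heavy atoms within 11 A

img = al.ph_image(s, ca)                       # multiscale image tensor
print(img.shape)                               # (8, 10, 3)
```

A few of the 60 named features for this residue (names encode
kernel/transform, metric B or W, homology dimension, element pair):

```
lor21v5_B0_CC          0.001501
exp10k1_B0_CC          0.165767
exp2k1refl_W0_CC       0.537455
exp2k1rot30_W1_CC      0.000000
```

The Lorentz kernel at &eta; = 21 &Aring; barely separates atoms inside an
11 &Aring; ball, so removing one atom moves the dimension-0 diagram very
little (0.0015); the sharper &eta; = 2 exponential kernel resolves the
local contact structure and the same removal costs 0.54 in Wasserstein
distance after reflecting the diagram.  Zero dimension-1 entries mean
the centre atom did not take part in any persistent loop at that scale.

The same pipeline runs from the shell:

```sh
aspholib synth --n-proteins 5 --n-residues 30 --seed 0 --out pdbs/
aspholib features pdbs/ --out features.csv
aspholib fit features.csv          # per-protein least-squares PCC
aspholib loo features.csv --seed 0 # blind leave-one-protein-out GBT
```

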